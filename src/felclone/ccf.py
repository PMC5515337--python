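"""Tumor cell fraction (CCF) estimation and clonal/subclonal labels.

For a mutation observed at variant allele fraction ``vaf`` in a sample
with tumor purity ``p``, local total copy number ``c`` in the tumor and
mutation multiplicity ``m`` (mutant copies per tumor cell), the fraction
of tumor cells carrying the mutation is

    ccf = vaf * (p*c + 2*(1 - p)) / (p * m)

assuming a diploid normal component.  The point estimate is wrapped in a
95% interval obtained from the exact (Clopper-Pearson) binomial interval
on the VAF, pushed through the same linear multiplier — a deliberately
simple, deterministic propagation rather than a joint purity/ploidy
posterior.  A mutation is labeled clonal when the interval's upper bound
reaches the ``clonal_threshold`` (default 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .datamodel import ValidationError

DEFAULT_CLONAL_THRESHOLD = 0.9


@dataclass(frozen=True)
class CcfEstimate:
    """Per-mutation tumor-cell-fraction estimate and clonality label."""

    mutation_key: str
    lesion_id: str
    vaf: float
    purity: float
    local_cn: int
    multiplicity: int
    ccf_raw: float          # formula value before clamping
    ccf: float              # clamped to [0, 1]
    ci_low: float
    ci_high: float
    label: str              # "clonal" | "subclonal"


def estimate_ccf(vaf: float, purity: float, local_cn: int,
                 multiplicity: int) -> float:
    """The CCF formula value (unclamped).

    >>> estimate_ccf(0.25, 0.5, 2, 1)
    1.0
    """
    _check_args(purity, local_cn, multiplicity)
    if not 0 <= vaf <= 1:
        raise ValidationError(f"vaf {vaf} outside [0,1]")
    return vaf * (purity * local_cn + 2.0 * (1.0 - purity)) / (
        purity * multiplicity)


def estimate_multiplicity(vaf: float, purity: float, local_cn: int) -> int:
    """Integer mutant-copy number most consistent with the observed VAF.

    Rounds the implied mutant copies per tumor cell and clamps to
    ``[1, max(local_cn, 1)]``.
    """
    _check_args(purity, local_cn, 1)
    implied = vaf * (purity * local_cn + 2.0 * (1.0 - purity)) / purity
    return int(min(max(round(implied), 1), max(local_cn, 1)))


def classify_clonality(alt_count: int, depth: int, purity: float,
                       local_cn: int = 2,
                       clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
                       multiplicity: int | None = None,
                       mutation_key: str = "", lesion_id: str = "",
                       level: float = 0.95) -> CcfEstimate:
    """Estimate CCF with a binomial 95% interval and label clonality.

    The VAF interval is exact binomial (Clopper-Pearson); both endpoints
    are multiplied by the same purity/copy-number factor as the point
    estimate and clamped to [0, 1].  ``multiplicity`` defaults to the
    value inferred by :func:`estimate_multiplicity`.
    """
    if depth <= 0:
        raise ValidationError("depth must be positive")
    if not 0 <= alt_count <= depth:
        raise ValidationError(f"alt_count {alt_count} outside [0, {depth}]")
    vaf = alt_count / depth
    if multiplicity is None:
        multiplicity = estimate_multiplicity(vaf, purity, local_cn)
    _check_args(purity, local_cn, multiplicity)
    factor = (purity * local_cn + 2.0 * (1.0 - purity)) / (
        purity * multiplicity)
    lo, hi = proportion_confint(alt_count, depth, alpha=1.0 - level,
                                method="beta")
    lo = 0.0 if lo != lo else float(lo)  # NaN at alt_count == 0
    ccf_raw = vaf * factor
    ccf = min(max(ccf_raw, 0.0), 1.0)
    ci_low = min(max(lo * factor, 0.0), 1.0)
    ci_high = min(max(float(hi) * factor, 0.0), 1.0)
    label = "clonal" if ci_high >= clonal_threshold else "subclonal"
    return CcfEstimate(mutation_key=mutation_key, lesion_id=lesion_id,
                       vaf=vaf, purity=purity, local_cn=local_cn,
                       multiplicity=multiplicity, ccf_raw=ccf_raw, ccf=ccf,
                       ci_low=ci_low, ci_high=ci_high, label=label)


def _check_args(purity: float, local_cn: int, multiplicity: int) -> None:
    if not 0 < purity <= 1:
        raise ValidationError(
            f"purity must be in (0, 1], got {purity}")
    if local_cn < 0:
        raise ValidationError(f"negative local copy number {local_cn}")
    if not 1 <= multiplicity <= max(local_cn, 1):
        raise ValidationError(
            f"multiplicity {multiplicity} outside [1, {max(local_cn, 1)}]")
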