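"""Copy-number breakpoint identity scoring between lesion pairs.

Two clonally related lesions inherit copy-number transitions from their
common ancestor, so their segment boundaries coincide (up to segmentation
jitter) more often than expected between unrelated tumors.  The analysis:

1. extract breakpoints from each segment profile, discarding boundaries
   inside telomeric/centromeric exclusion windows (those arise from
   arm-level events and assay edge artifacts rather than shared clonal
   history);
2. count matched breakpoints between two lesions — a maximum one-to-one
   matching in which breakpoints pair only if they lie on the same
   chromosome within a position tolerance (default 1 Mb);
3. summarize as a partial identity score, the Dice-style ratio
   ``2 * matched / (n_a + n_b)`` in [0, 1];
4. calibrate a relatedness cutoff from the score distribution of pairs of
   lesions from *different* patients (unrelated by construction), taking
   the upper limit of a 95% interval; a pair scoring above the cutoff is
   called clonally related.

An optional rarity-weighted score variant down-weights breakpoints in
recurrently rearranged bins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import norm

from .datamodel import (Breakpoint, CalibrationError, ExclusionRegions,
                        SegmentProfile, ValidationError)

DEFAULT_TOLERANCE = 1_000_000  # bp
DEFAULT_LEVEL = 0.95


def make_exclusion_regions(genome: dict[str, int],
                           centromeres: dict[str, int] | None = None,
                           telomere_width: int = 3_000_000,
                           centromere_width: int = 3_000_000
                           ) -> ExclusionRegions:
    """Fixed-width telomeric and pericentromeric windows (BED convention).

    ``telomere_width`` bases at each chromosome end and
    ``centromere_width`` bases on each side of the centromere midpoint.
    """
    intervals: list[tuple[str, int, int]] = []
    for chrom, length in genome.items():
        intervals.append((chrom, 0, min(telomere_width, length)))
        if length > telomere_width:
            intervals.append((chrom, length - telomere_width, length))
        cen = (centromeres or {}).get(chrom)
        if cen is not None:
            intervals.append((chrom, max(cen - centromere_width, 0),
                              min(cen + centromere_width, length)))
    return ExclusionRegions(intervals=tuple(intervals))


def extract_breakpoints(profile: SegmentProfile,
                        excl: ExclusionRegions | None = None
                        ) -> list[Breakpoint]:
    """Filtered breakpoints of a profile.

    Boundaries between adjacent same-chromosome segments with differing
    copy number, minus any that fall inside an exclusion window.
    Chromosome termini never yield breakpoints, so a whole-chromosome
    loss contributes none.
    """
    bps = profile.breakpoints()
    if excl is None:
        return bps
    return [bp for bp in bps if not excl.contains(bp.chrom, bp.boundary_pos)]


def matched_breakpoint_pairs(a: list[Breakpoint], b: list[Breakpoint],
                             tolerance: int = DEFAULT_TOLERANCE
                             ) -> list[tuple[int, int]]:
    """One maximum one-to-one matching as (index in a, index in b) pairs.

    Breakpoints may pair only when on the same chromosome with positions
    within ``tolerance`` bases.  The maximum-cardinality bipartite
    matching is computed per chromosome (Hopcroft-Karp).  The matching
    size is unique; among equally sized matchings the deterministic
    algorithm on sorted inputs fixes the returned pairing.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    pairs: list[tuple[int, int]] = []
    chroms = sorted({bp.chrom for bp in a} & {bp.chrom for bp in b})
    for chrom in chroms:
        left = [i for i, bp in enumerate(a) if bp.chrom == chrom]
        right = [j for j, bp in enumerate(b) if bp.chrom == chrom]
        g = nx.Graph()
        g.add_nodes_from((0, i) for i in left)
        g.add_nodes_from((1, j) for j in right)
        for i in left:
            for j in right:
                if abs(a[i].boundary_pos - b[j].boundary_pos) <= tolerance:
                    g.add_edge((0, i), (1, j))
        matching = nx.bipartite.hopcroft_karp_matching(
            g, top_nodes=[(0, i) for i in left])
        pairs.extend(sorted((u[1], v[1]) for u, v in matching.items()
                            if u[0] == 0))
    return pairs


def match_breakpoints(a: list[Breakpoint], b: list[Breakpoint],
                      tolerance: int = DEFAULT_TOLERANCE) -> int:
    """Size of the maximum one-to-one breakpoint matching (see
    :func:`matched_breakpoint_pairs`)."""
    return len(matched_breakpoint_pairs(a, b, tolerance))


@dataclass(frozen=True)
class IdentityScoreResult:
    """Partial identity score for one lesion pair."""

    lesion_pair: tuple[str, str]
    matched_breakpoints: int
    n_a: int
    n_b: int
    score: float
    weighted: bool = False


def _bin_weight(bp: Breakpoint, weights: dict, bin_size: int) -> float:
    return weights.get((bp.chrom, bp.boundary_pos // bin_size), 1.0)


def partial_identity_score(a: list[Breakpoint], b: list[Breakpoint],
                           tolerance: int = DEFAULT_TOLERANCE,
                           weights: dict | None = None,
                           bin_size: int = 1_000_000,
                           lesion_pair: tuple[str, str] = ("a", "b")
                           ) -> IdentityScoreResult:
    """Dice-style breakpoint identity score ``2*matched / (n_a + n_b)``.

    Returns 0.0 when both breakpoint sets are empty.  With ``weights``
    (a map from ``(chrom, position // bin_size)`` to a rarity weight),
    matched and total counts are replaced by weight sums, so rarer
    breakpoints carry more evidence.
    """
    pairs = matched_breakpoint_pairs(a, b, tolerance)
    matched = len(pairs)
    if weights is None:
        num = 2.0 * matched
        den = float(len(a) + len(b))
    else:
        w_a = [_bin_weight(bp, weights, bin_size) for bp in a]
        w_b = [_bin_weight(bp, weights, bin_size) for bp in b]
        num = sum(w_a[i] + w_b[j] for i, j in pairs)
        den = float(sum(w_a) + sum(w_b))
    score = num / den if den > 0 else 0.0
    return IdentityScoreResult(lesion_pair=lesion_pair,
                               matched_breakpoints=matched,
                               n_a=len(a), n_b=len(b),
                               score=float(min(max(score, 0.0), 1.0)),
                               weighted=weights is not None)


@dataclass(frozen=True)
class NullCalibration:
    """Relatedness cutoff calibrated on unrelated-pair scores."""

    unrelated_scores: tuple[float, ...]
    mean: float
    sd: float
    cutoff: float
    method: str             # "normal_ci" | "percentile"
    level: float = DEFAULT_LEVEL


def calibrate_cutoff(unrelated_scores: list[float],
                     method: str = "normal_ci",
                     level: float = DEFAULT_LEVEL) -> NullCalibration:
    """Upper limit of the null score distribution used as cutoff.

    ``normal_ci``: mean + z * sd of the unrelated scores, with z the
    two-sided upper quantile (1.96 at level 0.95); needs >= 3 scores.
    ``percentile``: empirical quantile at (1 + level) / 2; needs >= 20
    scores for the tail to be estimable.
    """
    scores = np.asarray(unrelated_scores, dtype=float)
    if method == "normal_ci":
        if scores.size < 3:
            raise CalibrationError(
                f"normal_ci needs >= 3 unrelated scores, got {scores.size}")
        mean = float(scores.mean())
        sd = float(scores.std(ddof=1))
        cutoff = mean + float(norm.ppf((1 + level) / 2)) * sd
    elif method == "percentile":
        if scores.size < 20:
            raise CalibrationError(
                f"percentile needs >= 20 unrelated scores, got {scores.size}")
        mean = float(scores.mean())
        sd = float(scores.std(ddof=1))
        cutoff = float(np.quantile(scores, (1 + level) / 2))
    else:
        raise ValidationError(f"unknown calibration method '{method}'")
    return NullCalibration(unrelated_scores=tuple(float(s) for s in scores),
                           mean=mean, sd=sd, cutoff=float(cutoff),
                           method=method, level=level)


@dataclass(frozen=True)
class PairRelatedness:
    """Breakpoint-identity verdict for one lesion pair.

    ``status`` is ``"ok"`` when both lesions are informative, or
    ``"non_informative"`` when either profile has no filtered breakpoints
    (e.g. a flat profile with minimal copy-number alterations), or
    ``"no_reference"`` when no null could be calibrated — ``verdict`` is
    None in the latter two cases rather than a silent False.
    """

    result: IdentityScoreResult
    calibration: NullCalibration | None
    verdict: bool | None
    status: str


def pair_relatedness(a: SegmentProfile, b: SegmentProfile,
                     reference_profiles: list[SegmentProfile],
                     excl: ExclusionRegions | None = None,
                     tolerance: int = DEFAULT_TOLERANCE,
                     method: str = "normal_ci",
                     level: float = DEFAULT_LEVEL,
                     include_query_vs_reference: bool = True
                     ) -> PairRelatedness:
    """Score one lesion pair against a null of cross-patient comparisons.

    The null combines every reference-vs-reference pair and, by default,
    each query lesion against every reference profile (all unrelated by
    construction).  Verdict: related iff score strictly exceeds the
    calibrated cutoff.
    """
    bp_a = extract_breakpoints(a, excl)
    bp_b = extract_breakpoints(b, excl)
    result = partial_identity_score(bp_a, bp_b, tolerance,
                                    lesion_pair=(a.lesion_id, b.lesion_id))
    if not reference_profiles:
        return PairRelatedness(result=result, calibration=None,
                               verdict=None, status="no_reference")
    ref_bps = [extract_breakpoints(p, excl) for p in reference_profiles]
    null_scores = [partial_identity_score(x, y, tolerance).score
                   for x, y in itertools.combinations(ref_bps, 2)]
    if include_query_vs_reference:
        for query in (bp_a, bp_b):
            null_scores.extend(
                partial_identity_score(query, r, tolerance).score
                for r in ref_bps)
    try:
        calibration = calibrate_cutoff(null_scores, method=method,
                                       level=level)
    except CalibrationError:
        return PairRelatedness(result=result, calibration=None,
                               verdict=None, status="no_reference")
    if not bp_a or not bp_b:
        return PairRelatedness(result=result, calibration=calibration,
                               verdict=None, status="non_informative")
    return PairRelatedness(result=result, calibration=calibration,
                           verdict=result.score > calibration.cutoff,
                           status="ok")
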