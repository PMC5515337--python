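"""Chance-sharing probability test for identical hotspot mutations.

Two lesions from the same patient that carry the *same* recurrent hotspot
mutation (e.g. MED12 Gly44Val) may either descend from one founder clone
or have acquired the mutation independently.  Under independence, the
probability that two unrelated lesions both carry mutation m is

    p_m = f_m**2

where f_m is the per-lesion prevalence of m in a reference cohort of
unrelated tumors.  A small p_m (below a significance level alpha, default
0.05) argues for clonal relatedness.  When several mutations are shared,
their probabilities multiply (independence across hotspots).  Probabilities
are always computed from raw cohort counts, never from rounded percentages:
(14/177)**2 = 0.00626 and 0.08**2 = 0.0064 both print as 0.006 at three
decimals, but only the former is the count-based estimator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .datamodel import FrequencyTable, MutationCall, ValidationError

DEFAULT_ALPHA = 0.05


def chance_sharing_probability(key: str, freq: FrequencyTable) -> float:
    """Probability that two unrelated lesions both carry mutation ``key``.

    Returns ``f_m**2`` with ``f_m`` the cohort prevalence; mutations
    absent from the table have prevalence 0 and probability 0.

    >>> from felclone.io import load_cohort_a
    >>> round(chance_sharing_probability("MED12:c.131G>T", load_cohort_a()), 3)
    0.006
    """
    f = freq.frequency(key)
    return f * f


@dataclass(frozen=True)
class SharedMutationEvidence:
    """Shared-hotspot evidence for one unordered lesion pair.

    ``per_mutation_probability`` carries the chance-sharing probability of
    each shared mutation; mutations without a reference frequency are
    listed with probability 1.0 (no evidential weight).
    ``combined_probability`` is their product (1.0 for an empty
    intersection) and the pair is ``significant`` when it falls below
    ``alpha``.
    """

    lesion_pair: tuple[str, str]
    shared_mutations: tuple[str, ...]
    per_mutation_probability: dict[str, float] = field(default_factory=dict)
    combined_probability: float = 1.0
    alpha: float = DEFAULT_ALPHA
    significant: bool = False


def pair_evidence(lesion_a: list[MutationCall], lesion_b: list[MutationCall],
                  freq: FrequencyTable,
                  alpha: float = DEFAULT_ALPHA) -> SharedMutationEvidence:
    """Evaluate shared-mutation evidence between two lesions.

    The shared set is the intersection of mutation identity keys.  Each
    shared mutation contributes ``chance_sharing_probability`` if it has a
    reference frequency, otherwise 1.0; the combined probability is the
    product.  An empty intersection yields probability 1.0 (no evidence).
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    ids = sorted({m.lesion_id for m in lesion_a} |
                 {m.lesion_id for m in lesion_b}) or ["a", "b"]
    name_a = lesion_a[0].lesion_id if lesion_a else ids[0]
    name_b = lesion_b[0].lesion_id if lesion_b else (
        ids[-1] if ids[-1] != name_a else "b")
    keys_a = {m.key for m in lesion_a}
    keys_b = {m.key for m in lesion_b}
    shared = tuple(sorted(keys_a & keys_b))
    per_mut = {k: (chance_sharing_probability(k, freq) if k in freq else 1.0)
               for k in shared}
    combined = math.prod(per_mut.values()) if per_mut else 1.0
    return SharedMutationEvidence(
        lesion_pair=(name_a, name_b), shared_mutations=shared,
        per_mutation_probability=per_mut, combined_probability=combined,
        alpha=alpha, significant=combined < alpha)


def relatedness_graph(lesions: dict[str, list[MutationCall]],
                      freq: FrequencyTable, alpha: float = DEFAULT_ALPHA,
                      bonferroni: bool = False
                      ) -> list[SharedMutationEvidence]:
    """Shared-hotspot evidence for every unordered pair of lesions.

    ``bonferroni=True`` divides alpha by the number of pairs before
    flagging significance (off by default; per-pair probabilities are
    reported either way).
    """
    names = list(lesions)
    if len(names) != len(set(names)):
        raise ValidationError("duplicate lesion ids")
    if len(names) < 2:
        raise ValidationError("need at least two lesions")
    n_pairs = len(names) * (len(names) - 1) // 2
    eff_alpha = alpha / n_pairs if bonferroni else alpha
    out = []
    for a, b in itertools.combinations(names, 2):
        ev = pair_evidence(lesions[a], lesions[b], freq, alpha=eff_alpha)
        # lesion lists may be empty; pin the pair names explicitly
        out.append(SharedMutationEvidence(
            lesion_pair=(a, b), shared_mutations=ev.shared_mutations,
            per_mutation_probability=ev.per_mutation_probability,
            combined_probability=ev.combined_probability,
            alpha=eff_alpha, significant=ev.significant))
    return out
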