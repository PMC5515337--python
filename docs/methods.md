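# Methods

## Problem setting

A patient with several synchronous fibroepithelial lesions (FELs) —
fibroadenomas (FAs) and phyllodes tumors (PTs) — poses a clonality
question: which lesions, if any, descend from one founder clone?
Direct phylogenetics is rarely possible from targeted panels, so the
field relies on two weaker but robust signals: sharing of an *identical*
recurrent hotspot mutation, and coincidence of copy-number breakpoints.
`felclone` implements both, a simplified per-mutation tumor-cell-fraction
(CCF) model to separate clonal from subclonal mutations, and a seeded
generator of synthetic cohorts for validation.

## Chance-sharing test for identical hotspots

Let allele *m* (identified by gene + cDNA change, e.g. `MED12:c.131G>T`)
have count *k_m* in a reference cohort of *N* unrelated tumors, so the
per-lesion prevalence is *f_m = k_m / N*. Under the null of independent
origin, two lesions both carry *m* with probability

    p_m = f_m^2 .

A pair sharing a set *S* of mutations gets combined probability
*∏_{m∈S} p_m* (independence across hotspots), compared against a
significance level α = 0.05. Design choices:

* probabilities are computed from raw counts, never from rounded
  percentages — (14/177)² = 0.00626 and 0.08² = 0.0064 both print as
  0.006 at three decimals, but only the former is the count-based
  estimator;
* shared mutations absent from the reference table are listed in the
  evidence but contribute probability 1.0 (no weight), rather than a
  fabricated frequency;
* no multiplicity correction across pairs by default (per-pair
  probabilities are reported); a Bonferroni flag over the number of
  pairs is available;
* the test is one-directional: a small *p* argues for relatedness, a
  large *p* is simply absence of evidence. Pairs with distinct alleles
  (e.g. Gly44Asp vs Gly44Cys) yield an empty intersection and
  probability 1.0.

The bundled tables pool published FA and PT cohorts: cohort A
(98 FA + 79 PT, N = 177; Gly44Val 14, Gly44Asp 29) and cohort B
(100 FA + 76 PT, N = 176; Gly44Val 13, Gly44Asp 37). Note that under
cohort B, Gly44Val gives (13/176)² = 0.0055, which rounds to 0.005 —
reports that derive it from the rounded 7% prevalence print 0.006
instead; we keep the count-based value.

## Tumor cell fraction and clonality labels

For a mutation with variant allele fraction *v = alt/depth* in a sample
of purity *ρ*, local total copy number *c* (diploid normal assumed) and
mutant multiplicity *m*,

    CCF = v · (ρc + 2(1 − ρ)) / (ρ m) .

Multiplicity, when not supplied, is the rounded implied mutant copy
number clamped to [1, max(c, 1)]. Uncertainty: an exact
(Clopper–Pearson) binomial 95% interval on *v* is multiplied by the same
factor and clamped to [0, 1]; this linear propagation is deterministic
and ignores purity/ploidy uncertainty by design — a joint likelihood
model of purity and karyotype is explicitly out of scope, and purity is
a required input. A mutation is labeled **clonal** when the interval's
upper bound reaches the threshold 0.9 (configurable `clonal_threshold`;
the convention that a mutation compatible with presence in ~all tumor
cells is clonal). Degenerate inputs: depth 0 and purity 0 are errors;
alt = 0 yields interval [0, upper]. Sex chromosomes are treated as
diploid-normal by default, which is correct for X-linked genes (MED12)
in a female patient; a per-chromosome override is available through the
local copy number argument.

## Breakpoint partial identity score

Breakpoints are boundaries between adjacent same-chromosome segments
with different total copy number; chromosome termini are never
breakpoints, so whole-chromosome and whole-arm events contribute only
their interstitial edges. Boundaries falling in exclusion windows
(default: 3 Mb at each telomere and ±3 Mb around each centromere, hg19
coordinates bundled) are removed, because they arise from arm-level
events and assay edge effects rather than from shareable clonal history.

Matching between two filtered breakpoint sets is a **maximum one-to-one
bipartite matching** (Hopcroft–Karp, per chromosome) where breakpoints
may pair only on the same chromosome within a position tolerance
(default 1 Mb, the bin resolution of targeted-panel segmentation). A
nearest-first greedy pairing was considered and rejected: it is not
maximum on interleaved instances (a = {0, 6}, b = {5, 11}, tolerance 5
gives greedy 1 vs maximum 2), whereas the matching *size* of the exact
algorithm is unique and deterministic. The test suite checks the
implementation against an exhaustive dynamic-programming oracle on all
instances up to 10×10.

The score is the Dice-style ratio

    S = 2 · matched / (n_a + n_b)  ∈ [0, 1],

0 when either set is empty. An optional rarity-weighted variant replaces
counts by sums of user-supplied per-bin weights, down-weighting
recurrently rearranged regions. The published per-patient score values
for this analysis family depend on the original rarity weighting and the
study's segment data, neither of which is printed; the score here is
therefore validated by construction (symmetry, bounds, monotonicity,
matching optimality, null calibration) rather than against a single
reference value.

**Cutoff calibration.** Unrelated-pair scores are collected from
cross-patient comparisons (all reference-vs-reference pairs plus each
query lesion against every reference). The cutoff is the upper limit of
a 95% interval: `normal_ci` (default) uses mean + 1.96·sd of the score
distribution; `percentile` uses the empirical 97.5% quantile (≥ 20
scores required). Both are exposed because interval constructions differ
between studies; with the sparse, zero-inflated nulls typical of FELs
the two can differ, and the percentile method is the safer choice when
the null is large. A pair is called related on *strict* inequality
(score > cutoff). A lesion with no filtered breakpoints (flat profile)
makes the comparison **non-informative** rather than negative.

## Verdict combination

Per lesion pair: **related** if the hotspot test is significant OR the
identity score exceeds the cutoff (the two lines are mutually
reinforcing; concordant positives are annotated); **non_informative** if
neither line could be evaluated (no mutation data and flat/missing
profiles); otherwise **unrelated**. The rule is a pure function of the
two evidence objects and is unit-tested with stubbed inputs.

## Synthetic cohort generator

The generator emulates the study design — a patient with five
synchronous lesions of which two disjoint pairs are clonally related —
with one seeded random stream (numpy Generator; per-patient substreams
via `SeedSequence.spawn`), so fixed seeds give byte-identical outputs.

* **Hotspot carriage is population-faithful.** Every founder clone and
  every independent lesion carries each tabulated allele independently
  with probability *f_m*, so lesion-level allele frequencies match the
  reference spectrum and two unrelated lesions share allele *m* with
  probability exactly *f_m²* — the rate the chance-sharing test assumes.
  A clone that draws no tabulated allele receives a unique untabulated
  founder hotspot (shared by its lesions, no frequency evidence), as
  with rare alleles missing from published counts. Drawing founders
  *proportionally* to *f* instead would make two clones of one patient
  collide on the same allele far more often than real MED12 allele
  diversity allows (with a two-allele table, 56% of the time) and was
  rejected.
* **Breakpoints.** Unrelated lesions draw Poisson(`breakpoints_per_lesion`,
  default 3) breakpoints uniformly over the genome (≥ 5 Mb from
  chromosome ends and centromeres, so default exclusion windows never
  clip them); related pairs share `shared_breakpoint_count` (default 3,
  the count observed in the motivating case) ancestral breakpoints
  jittered per lesion by ≤ `tolerance_jitter` (default 100 kb) plus a
  reduced private load — FELs carry few copy-number alterations, and
  flat profiles are common. Segments are reconstructed so that internal
  boundaries are exactly the drawn breakpoints (copy number alternates
  away from and back to 2).
* **Read counts.** Expected VAF = ρ·m·CCF / (ρc + 2(1−ρ)) with the
  local copy number taken from the lesion's own profile; depth ~
  Poisson(`mean_depth`, default 1000, matching panel-level coverage);
  alt ~ Binomial(depth, VAF). Purity ~ Uniform(0.4, 0.9). Private
  mutations arrive at Poisson rate 2 per lesion from a panel of genes
  recurrently mutated in FELs, 60% clonal.

What the generator does **not** model: subclonal copy-number states,
allele-specific copy number, FFPE artifacts, sequencing error, mutation
calling sensitivity, more than two lesions per clone, or phylogenetic
structure deeper than founder/private. Passing recovery tests therefore
demonstrates the statistical machinery under the stated model, not
robustness to those real-data complications.

## Problem sizes and statistical tolerances

Simulation-backed checks use deliberately desk-scale runs: 1,000
simulated mutations for CCF interval coverage (asserted ≥ 93%, the
binomial tolerance below the nominal 95%); 1,000 fresh unrelated pairs
for null-exceedance (≤ 5%); 200 patients (400 related / 1,600 unrelated
pairs) for end-to-end recovery. Recovery is asserted at sensitivity
≥ 0.9 and false-positive rate ≤ 0.05; note the false-positive rate of
the combined procedure is dominated by the chance-sharing test's
intrinsic rate Σ f_m² ≈ 0.033 under the default spectrum, so the margin
to 0.05 is real but Monte-Carlo noise at these sizes is roughly ±0.005
(one sd). All stochastic tests fix their seeds.

## Known limitations

* The CCF interval understates total uncertainty (purity and ploidy are
  treated as known).
* The chance-sharing test conditions on the tabulated alleles only;
  lesions sharing an allele absent from the reference table receive no
  evidential weight even though such sharing is often biologically
  compelling.
* With sparse copy-number profiles the calibrated null can be degenerate
  (all unrelated scores 0), making the cutoff 0 and the copy-number
  verdict sensitive to any single chance match; the pipeline reports the
  null summary so users can judge.
* Exclusion windows are fixed-width; real telomeric/centromeric gaps
  vary by chromosome and assay.
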