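# felclone

Clonal relatedness analysis for synchronous fibroepithelial lesions
(FELs) of the breast — fibroadenomas (FAs) and phyllodes tumors (PTs).

When a patient presents with several FELs at once, the clinically
important question is whether they arose independently or descend from a
common founder clone (e.g., whether a malignant phyllodes tumor grew out
of a co-existing fibroadenoma). `felclone` answers this with the two
complementary statistics used in molecular pathology, plus the plumbing
around them:

1. **Shared-hotspot chance-sharing test.** FELs are driven by highly
   recurrent MED12 exon-2 hotspot mutations. If allele *m* has
   per-lesion prevalence *f<sub>m</sub>* = count/cohort size in a
   reference cohort of unrelated tumors, two unrelated lesions both
   carry *m* with probability *p<sub>m</sub> = f<sub>m</sub>²*. Lesions
   sharing an identical allele with *p* < α (default 0.05) are called
   clonally related; multiple shared mutations combine by product.
2. **Tumor cell fraction (CCF).** For a mutation at variant allele
   fraction *v* in a sample of purity *ρ* with local total copy number
   *c* and mutant multiplicity *m*:
   *CCF = v·(ρc + 2(1−ρ)) / (ρm)*, with an exact (Clopper–Pearson)
   binomial 95% interval on *v* pushed through the same multiplier.
   A mutation is clonal when the interval's upper bound reaches 0.9.
3. **Breakpoint partial-identity score.** Clonally related lesions
   inherit copy-number transitions from their ancestor. After removing
   telomeric/centromeric boundaries, breakpoints of two lesions are
   matched one-to-one (same chromosome, within 1 Mb by default) and
   summarized as *S = 2·matched / (n_a + n_b)* ∈ [0, 1]. The
   relatedness cutoff is the upper limit of a 95% interval of the score
   distribution over cross-patient (unrelated) comparisons; a pair with
   *S* above the cutoff is called related.

A seeded synthetic-cohort generator emulates the study design
(multi-lesion patients with founder hotspots, purity-diluted binomial
read counts, shared jittered breakpoints, unrelated reference profiles)
so every stage is testable with known ground truth.

## Worked example: five synchronous ipsilateral lesions

The package bundles a worked example modeled on a patient with three
FAs, one benign and one malignant PT in the same breast (mutation
identities and lesion topology from the published case; read counts and
segment coordinates are synthetic stand-ins). Reference frequency
tables are bundled: cohort A pools 98 FAs + 79 PTs (n=177, Gly44Val
14/177, Gly44Asp 29/177), cohort B pools 100 FAs + 76 PTs (n=176).

```python
from felclone import chance_sharing_probability, load_cohort_a, relatedness_graph
from felclone.io import load_five_lesion_case

cohort = load_cohort_a()
print(round(chance_sharing_probability("MED12:c.131G>T", cohort), 3))  # 0.006
print(round(chance_sharing_probability("MED12:c.131G>A", cohort), 3))  # 0.027

case = load_five_lesion_case()
lesions = {}
for m in case["mutations"]:
    lesions.setdefault(m.lesion_id, []).append(m)
for ev in relatedness_graph(lesions, cohort, alpha=0.05):
    if ev.significant:
        print(ev.lesion_pair, round(ev.combined_probability, 3))
# ('FA2', 'BenignPT') 0.006
# ('FA3', 'MalignantPT') 0.027
```

Exactly 2 of the 10 lesion pairs are significant: the benign PT shares
Gly44Val (c.131G>T) with FA2 and the malignant PT shares Gly44Asp
(c.131G>A) with FA3 — each too rare a coincidence to arise twice
independently at the 0.05 level.

The same example through the full pipeline, including copy-number
evidence (the reference SEG provides unrelated profiles for the null):

```sh
felclone simulate --seed 13 --n-patients 0 --n-reference 22 --outdir reference
felclone run --config config.yaml
```

`report/pairs.tsv` then contains one verdict per pair, e.g.:

```
lesion_a  lesion_b     shared_mutations  combined_probability  identity_score  matched_breakpoints  verdict  notes
BenignPT  FA2          MED12:c.131G>T    0.006256              0.0             0                    related  copy-number comparison non-informative (flat or missing profile)
FA3       MalignantPT  MED12:c.131G>A    0.026844              0.545455        3                    related  concordant mutation and copy-number evidence
```

FA3 and the malignant PT share 3 non-telomeric, non-centromeric
breakpoints (identity score 0.545 against a near-zero unrelated null),
independently corroborating the shared-hotspot call; the benign PT has a
flat copy-number profile, so its comparison is non-informative and the
verdict rests on the mutation evidence alone. `report/ccf.tsv` lists
per-mutation CCFs — the hotspots are clonal in every lesion except FA2,
and the CCND2 (FA3) and second SETD2 (malignant PT) mutations are
subclonal.

## Scope

The package takes mutation calls (TSV/MAF-like, or a VCF subset) and
copy-number segments (SEG) as given: no alignment, variant calling,
re-segmentation, or purity/ploidy estimation is performed (purity is a
required input), and the CCF model is a deliberate deterministic
simplification rather than a joint purity/ploidy likelihood. See
`docs/methods.md` for the model details and limitations.
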