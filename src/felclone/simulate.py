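"""Synthetic multi-lesion patients and unrelated reference cohorts.

The generator emulates the statistical structure the clonality analysis
relies on, at the scale of the motivating study design: a patient with
several synchronous ipsilateral fibroepithelial lesions, some of which
descend from a shared founder clone.

* Related lesion pairs descend from a founder clone that carries each
  tabulated hotspot allele with its cohort prevalence f_m (so allele
  carriage in every lesion, clonal or not, matches the reference
  spectrum and two unrelated lesions share allele m with probability
  exactly f_m**2, the rate the chance-sharing test assumes).  A clone
  that draws none of the tabulated alleles receives a unique
  untabulated founder hotspot instead — shared by its two lesions but
  carrying no frequency evidence, as with rare hotspot alleles absent
  from published counts.
* Related pairs additionally share ``shared_breakpoint_count``
  copy-number breakpoints, jittered between the two lesions by at most
  ``tolerance_jitter`` bases to mimic segmentation noise.
* Unrelated lesions draw each hotspot independently at its cohort
  prevalence and place their breakpoints uniformly at random, so any
  sharing is chance.
* Read support is binomial: each mutation's expected variant allele
  fraction follows purity * multiplicity * ccf /
  (purity * local_cn + 2 * (1 - purity)) with the local copy number taken
  from the lesion's own simulated segment profile; depth is Poisson
  around ``mean_depth``.
* Private (non-founder) mutations occur at a Poisson background rate per
  lesion, drawn from a panel of genes recurrently mutated in
  fibroepithelial lesions; 60% are clonal, the rest subclonal.

All randomness flows from a single seed through ``numpy.random``
generators spawned per patient, so a fixed seed reproduces byte-identical
output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (ConfigError, FrequencyTable, MutationCall, Segment,
                        SegmentProfile)
from .io import (load_centromeres, load_cohort_a, load_genome,
                 write_mutation_table, write_seg)

# Known hotspot annotations (hg19-approximate loci).
_HOTSPOTS = {
    "MED12:c.131G>T": ("Gly44Val", "chrX", 70339329, "G", "T"),
    "MED12:c.131G>A": ("Gly44Asp", "chrX", 70339329, "G", "A"),
    "MED12:c.130G>T": ("Gly44Cys", "chrX", 70339328, "G", "T"),
}

# Genes recurrently mutated in fibroepithelial lesions, used for private
# (non-founder) events.
_PRIVATE_GENES = (
    ("FGFR2", "chr10", 123279677, False),
    ("KDM6A", "chrX", 44969287, False),
    ("KMT2D", "chr12", 49425114, False),
    ("SETD2", "chr3", 47125000, False),
    ("CCND2", "chr12", 4399000, False),
    ("TERT", "chr5", 1295228, True),
)

_BASES = ("A", "C", "G", "T")

# Breakpoints are placed at least this far from chromosome ends and
# centromeres so the default 3 Mb exclusion windows never clip simulated
# clonal signal.
_PLACEMENT_MARGIN = 5_000_000


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the motivating case series: five lesions per patient
    of which two disjoint pairs are clonally related
    (``related_pair_fraction`` of the floor(L/2) possible disjoint
    pairs), targeted-panel depth around 1000x, three clonally shared
    breakpoints per related pair on a background of few private
    copy-number changes, as is typical for fibroepithelial lesions.
    """

    seed: int = 0
    n_patients: int = 1
    lesions_per_patient: int = 5
    related_pair_fraction: float = 1.0
    hotspot_spectrum: FrequencyTable | None = None
    background_mutation_rate: float = 2.0
    purity_range: tuple[float, float] = (0.4, 0.9)
    mean_depth: int = 1000
    breakpoints_per_lesion: float = 3.0   # mean count per unrelated lesion
    shared_breakpoint_count: int = 3
    tolerance_jitter: int = 100_000
    clonal_private_fraction: float = 0.6
    genome: dict[str, int] = field(default_factory=dict)
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genome:
            self.genome = load_genome()
            self.centromeres = load_centromeres()
        if self.hotspot_spectrum is None:
            self.hotspot_spectrum = load_cohort_a()
        for chrom, length in self.genome.items():
            if length <= 0:
                raise ConfigError(f"zero-length chromosome {chrom}")
        for name, p in (("related_pair_fraction",
                         self.related_pair_fraction),
                        ("clonal_private_fraction",
                         self.clonal_private_fraction)):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        lo, hi = self.purity_range
        if not 0 < lo <= hi <= 1:
            raise ConfigError(f"invalid purity_range {self.purity_range}")
        if self.lesions_per_patient < 1:
            raise ConfigError("need at least one lesion per patient")


@dataclass
class PatientSim:
    """One simulated patient: lesions with mutation calls, segment
    profiles, purities and ground-truth pair labels."""

    patient_id: str
    mutations: list[MutationCall]
    profiles: dict[str, SegmentProfile]
    purity: dict[str, float]
    truth: list[tuple[str, str, bool]]   # (lesion_a, lesion_b, related)


def _placeable_chromosomes(config: SimulationConfig
                           ) -> tuple[list[str], np.ndarray]:
    chroms, spans = [], []
    for chrom, length in config.genome.items():
        if length > 2 * _PLACEMENT_MARGIN:
            chroms.append(chrom)
            spans.append(length - 2 * _PLACEMENT_MARGIN)
    if not chroms:
        raise ConfigError("no chromosome long enough to place breakpoints")
    spans = np.asarray(spans, dtype=float)
    return chroms, spans / spans.sum()


def _draw_breakpoint_positions(n: int, config: SimulationConfig,
                               rng: np.random.Generator
                               ) -> list[tuple[str, int]]:
    chroms, probs = _placeable_chromosomes(config)
    out: list[tuple[str, int]] = []
    while len(out) < n:
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        length = config.genome[chrom]
        pos = int(rng.integers(_PLACEMENT_MARGIN,
                               length - _PLACEMENT_MARGIN))
        cen = config.centromeres.get(chrom)
        if cen is not None and abs(pos - cen) < _PLACEMENT_MARGIN:
            continue
        out.append((chrom, pos))
    return out


def _profile_from_breakpoints(lesion_id: str,
                              positions: list[tuple[str, int]],
                              config: SimulationConfig,
                              rng: np.random.Generator) -> SegmentProfile:
    """Segments whose internal boundaries are exactly ``positions``.

    Copy number starts diploid on each chromosome and alternates away
    from/back to 2 at each boundary so that adjacent segments always
    differ.
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    segments: list[Segment] = []
    for chrom in sorted(config.genome):
        length = config.genome[chrom]
        bounds = sorted(set(by_chrom.get(chrom, [])))
        cn = 2
        start = 1
        for b in bounds:
            segments.append(Segment(chrom, start, b, cn))
            cn = 2 if cn != 2 else int(rng.choice((1, 3)))
            start = b + 1
        segments.append(Segment(chrom, start, length, cn))
    return SegmentProfile.from_segments(lesion_id, segments,
                                        genome_build="synthetic")

def _random_cdna(rng: np.random.Generator) -> tuple[str, str, str]:
    pos = int(rng.integers(100, 5000))
    ref, alt = rng.choice(len(_BASES), size=2, replace=False)
    ref, alt = _BASES[ref], _BASES[alt]
    return f"c.{pos}{ref}>{alt}", ref, alt


def _simulate_reads(ccf: float, purity: float, local_cn: int,
                    config: SimulationConfig,
                    rng: np.random.Generator) -> tuple[int, int]:
    multiplicity = 1
    vaf = purity * multiplicity * ccf / (
        purity * local_cn + 2.0 * (1.0 - purity))
    depth = max(int(rng.poisson(config.mean_depth)), 1)
    alt = int(rng.binomial(depth, min(vaf, 1.0)))
    return alt, depth


def _hotspot_call(key: str, lesion_id: str, ccf: float, purity: float,
                  profile: SegmentProfile, config: SimulationConfig,
                  rng: np.random.Generator) -> MutationCall:
    gene, cdna = key.split(":", 1)
    if key in _HOTSPOTS:
        protein, chrom, pos, ref, alt_allele = _HOTSPOTS[key]
    elif gene == "MED12":
        protein, chrom, pos = "", "chrX", 70339300
        ref, alt_allele = "G", "A"
    else:
        protein, chrom, pos = "", "chr1", int(rng.integers(10**7, 10**8))
        ref, alt_allele = "G", "A"
    local_cn = profile.copy_number_at(chrom, pos)
    alt, depth = _simulate_reads(ccf, purity, local_cn, config, rng)
    return MutationCall(lesion_id=lesion_id, gene=gene,
                        protein_change=protein, cdna_change=cdna,
                        chrom=chrom, pos=pos, ref_allele=ref,
                        alt_allele=alt_allele, alt_count=alt, depth=depth)


def _private_calls(lesion_id: str, purity: float, profile: SegmentProfile,
                   config: SimulationConfig,
                   rng: np.random.Generator) -> list[MutationCall]:
    calls = []
    for _ in range(int(rng.poisson(config.background_mutation_rate))):
        gene, chrom, base_pos, promoter = _PRIVATE_GENES[
            int(rng.integers(len(_PRIVATE_GENES)))]
        pos = base_pos + int(rng.integers(0, 5000))
        cdna, ref, alt_allele = _random_cdna(rng)
        clonal = rng.random() < config.clonal_private_fraction
        ccf = 1.0 if clonal else float(rng.uniform(0.2, 0.6))
        local_cn = profile.copy_number_at(chrom, pos)
        alt, depth = _simulate_reads(ccf, purity, local_cn, config, rng)
        calls.append(MutationCall(
            lesion_id=lesion_id, gene=gene, protein_change="",
            cdna_change=cdna, chrom=chrom, pos=pos, ref_allele=ref,
            alt_allele=alt_allele, alt_count=alt, depth=depth,
            is_promoter=promoter))
    return calls


def _spectrum_items(config: SimulationConfig) -> list[tuple[str, float]]:
    spec = config.hotspot_spectrum
    return [(key, spec.frequency(key)) for key in sorted(spec.entries)]


def simulate_patient(config: SimulationConfig,
                     rng: np.random.Generator | None = None,
                     patient_id: str = "P1") -> PatientSim:
    """Simulate one multi-lesion patient.

    The first ``2 * round(related_pair_fraction * floor(L/2))`` lesions
    form disjoint clonally related pairs; remaining lesions are
    independent.  Each founder clone carries every tabulated hotspot
    allele independently at its cohort prevalence (or one unique
    untabulated founder when it draws none), so hotspot carriage is
    population-faithful in every lesion.  Related pairs additionally
    share ``shared_breakpoint_count`` breakpoints whose positions differ
    between the two lesions by at most ``tolerance_jitter`` bases;
    clonal lesions carry a correspondingly reduced private breakpoint
    load (part of their copy-number repertoire is ancestral).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.lesions_per_patient
    lesion_ids = [f"{patient_id}_L{i + 1}" for i in range(L)]
    n_pairs = round(config.related_pair_fraction * (L // 2))
    clone_of: dict[str, int] = {}
    for k in range(n_pairs):
        clone_of[lesion_ids[2 * k]] = k
        clone_of[lesion_ids[2 * k + 1]] = k

    items = _spectrum_items(config)
    founders: dict[int, list[str]] = {}
    shared_bps: dict[int, list[tuple[str, int]]] = {}
    for k in range(n_pairs):
        carried = [key for key, f in items if rng.random() < f]
        if not carried:
            # rare founder allele outside the published counts
            cdna, _, _ = _random_cdna(rng)
            carried = [f"MED12:{cdna}"]
        founders[k] = carried
        shared_bps[k] = _draw_breakpoint_positions(
            config.shared_breakpoint_count, config, rng)

    purity = {lid: float(rng.uniform(*config.purity_range))
              for lid in lesion_ids}
    private_bp_rate = {
        True: max(config.breakpoints_per_lesion
                  - config.shared_breakpoint_count, 0.5),
        False: config.breakpoints_per_lesion,
    }
    mutations: list[MutationCall] = []
    profiles: dict[str, SegmentProfile] = {}
    for lid in lesion_ids:
        n_private = int(rng.poisson(private_bp_rate[lid in clone_of]))
        positions = _draw_breakpoint_positions(n_private, config, rng)
        if lid in clone_of:
            j = config.tolerance_jitter
            for chrom, pos in shared_bps[clone_of[lid]]:
                jit = int(rng.integers(-j, j + 1)) if j > 0 else 0
                positions.append((chrom, pos + jit))
        profile = _profile_from_breakpoints(lid, positions, config, rng)
        profiles[lid] = profile
        if lid in clone_of:
            for key in founders[clone_of[lid]]:
                mutations.append(_hotspot_call(
                    key, lid, 1.0, purity[lid], profile, config, rng))
        else:
            for key, f in items:
                if rng.random() < f:
                    mutations.append(_hotspot_call(
                        key, lid, 1.0, purity[lid], profile, config, rng))
        mutations.extend(_private_calls(lid, purity[lid], profile,
                                        config, rng))

    truth = [(a, b, a in clone_of and b in clone_of
              and clone_of[a] == clone_of[b])
             for a, b in itertools.combinations(lesion_ids, 2)]
    return PatientSim(patient_id=patient_id, mutations=mutations,
                      profiles=profiles, purity=purity, truth=truth)


def simulate_cohort(config: SimulationConfig) -> list[PatientSim]:
    """Simulate ``config.n_patients`` independent patients.

    Each patient gets its own generator spawned from the master seed, so
    the cohort is reproducible and patients are independent streams.
    """
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    return [simulate_patient(config, rng=np.random.default_rng(seq),
                             patient_id=f"P{i + 1}")
            for i, seq in enumerate(seqs)]


def simulate_reference_cohort(config: SimulationConfig,
                              n_profiles: int = 22,
                              rng: np.random.Generator | None = None
                              ) -> list[SegmentProfile]:
    """Independent single-lesion segment profiles from distinct patients.

    Stands in for an external cohort of unrelated tumors used to
    calibrate the breakpoint-identity null: no founder events, every
    cross-pair is unrelated by construction.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            (config.seed, 0x5EF)))
    profiles = []
    for i in range(n_profiles):
        n = int(rng.poisson(config.breakpoints_per_lesion))
        positions = _draw_breakpoint_positions(n, config, rng)
        profiles.append(_profile_from_breakpoints(
            f"REF{i + 1}", positions, config, rng))
    return profiles


def write_patient(sim: PatientSim, outdir) -> dict[str, Path]:
    """Write one patient's mutation TSV, SEG file and truth labels."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": outdir / f"{sim.patient_id}_mutations.tsv",
        "segments": outdir / f"{sim.patient_id}_segments.seg",
        "truth": outdir / f"{sim.patient_id}_truth.tsv",
        "purity": outdir / f"{sim.patient_id}_purity.tsv",
    }
    write_mutation_table(sim.mutations, paths["mutations"])
    write_seg(sim.profiles.values(), paths["segments"])
    with open(paths["truth"], "w") as fh:
        fh.write("lesion_a\tlesion_b\trelated\n")
        for a, b, rel in sim.truth:
            fh.write(f"{a}\t{b}\t{int(rel)}\n")
    with open(paths["purity"], "w") as fh:
        fh.write("lesion_id\tpurity\n")
        for lid, p in sim.purity.items():
            fh.write(f"{lid}\t{p:.6f}\n")
    return paths
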