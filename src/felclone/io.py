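"""Readers and writers for mutation tables, SEG files, frequency tables,
BED exclusion files, and a minimal VCF subset, plus loaders for the
packaged reference data."""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .datamodel import (Breakpoint, ExclusionRegions, FormatError,
                        FrequencyTable, MutationCall, Segment,
                        SegmentProfile, ValidationError)

# Accepted header aliases (lower-cased) for the mutation table; the
# canonical names are the keys of MutationCall.
_MUTATION_ALIASES = {
    "lesion_id": {"lesion_id", "lesion", "sample", "sample_id",
                  "tumor_sample_barcode"},
    "gene": {"gene", "hugo_symbol"},
    "protein_change": {"protein_change", "hgvsp_short", "hgvsp", "aa_change"},
    "cdna_change": {"cdna_change", "hgvsc", "cdna"},
    "chrom": {"chrom", "chromosome", "chr"},
    "pos": {"pos", "position", "start_position", "start"},
    "ref_allele": {"ref_allele", "ref", "reference_allele"},
    "alt_allele": {"alt_allele", "alt", "tumor_seq_allele2"},
    "alt_count": {"alt_count", "t_alt_count", "mutant_reads", "alt_reads"},
    "depth": {"depth", "t_depth", "coverage", "total_reads"},
    "is_promoter": {"is_promoter", "promoter"},
}
_MUTATION_REQUIRED = ("lesion_id", "gene", "cdna_change", "alt_count",
                     "depth")

_SEG_ALIASES = {
    "sample": {"id", "sample", "sample_id"},
    "chrom": {"chrom", "chromosome", "chr"},
    "start": {"loc.start", "start", "loc_start"},
    "end": {"loc.end", "end", "loc_end"},
    "value": {"seg.mean", "seg_mean", "value", "total_cn", "cn"},
}


def _map_columns(columns: Iterable[str], aliases: dict[str, set[str]],
                 required: Iterable[str], path) -> dict[str, str]:
    lower = {str(c).strip().lower(): c for c in columns}
    mapping = {}
    for canon, names in aliases.items():
        for name in names:
            if name in lower:
                mapping[canon] = lower[name]
                break
    for canon in required:
        if canon not in mapping:
            raise FormatError(
                f"{path}: missing required column '{canon}' "
                f"(accepted names: {sorted(aliases[canon])})")
    return mapping


def read_mutation_table(path) -> list[MutationCall]:
    """Read a tab- or comma-delimited somatic mutation table.

    The header must name at least the lesion, gene, cDNA change, mutant
    read count and depth (MAF-style aliases such as ``Tumor_Sample_Barcode``
    or ``t_alt_count`` are accepted).  Rows whose read support violates
    ``alt_count <= depth`` are rejected with the offending line number.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", skipinitialspace=True,
                     dtype=str)
    cols = _map_columns(df.columns, _MUTATION_ALIASES, _MUTATION_REQUIRED,
                        path)
    calls: list[MutationCall] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1

        def get(canon, default=""):
            col = cols.get(canon)
            if col is None:
                return default
            val = row[col]
            return default if pd.isna(val) else str(val).strip()

        try:
            alt_count = int(get("alt_count"))
            depth = int(get("depth"))
            pos = int(get("pos", "0") or 0)
        except ValueError as exc:
            raise FormatError(f"{path}:{line}: non-integer count "
                              f"({exc})") from exc
        promoter = get("is_promoter", "0").lower() in {"1", "true", "yes"}
        try:
            calls.append(MutationCall(
                lesion_id=get("lesion_id"), gene=get("gene"),
                protein_change=get("protein_change"),
                cdna_change=get("cdna_change"), chrom=get("chrom"),
                pos=pos, ref_allele=get("ref_allele"),
                alt_allele=get("alt_allele"), alt_count=alt_count,
                depth=depth, is_promoter=promoter))
        except ValidationError as exc:
            raise FormatError(f"{path}:{line}: {exc}") from exc
    return calls


def write_mutation_table(calls: Iterable[MutationCall], path) -> None:
    rows = [{"lesion_id": c.lesion_id, "gene": c.gene,
             "protein_change": c.protein_change,
             "cdna_change": c.cdna_change, "chrom": c.chrom, "pos": c.pos,
             "ref_allele": c.ref_allele, "alt_allele": c.alt_allele,
             "alt_count": c.alt_count, "depth": c.depth,
             "is_promoter": int(c.is_promoter)} for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _seg_value_to_cn(value: float, seg_value: str) -> int:
    if seg_value == "integer_cn":
        cn = round(float(value))
    elif seg_value == "log2_ratio":
        # log2(CN/2) back to integer total copy number
        cn = round(2 * 2 ** float(value))
    else:
        raise FormatError(f"unknown seg_value dialect '{seg_value}'")
    return int(cn)


def read_seg(path, seg_value: str = "integer_cn",
             genome_build: str = "") -> dict[str, SegmentProfile]:
    """Read a SEG file into one :class:`SegmentProfile` per sample.

    The value column is interpreted as integer total copy number by
    default; ``seg_value='log2_ratio'`` maps log2 ratios to integers via
    ``round(2 * 2**value)``.  Overlapping segments raise a validation
    error naming the offending pair.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = _map_columns(df.columns, _SEG_ALIASES, _SEG_ALIASES, path)
    profiles: dict[str, SegmentProfile] = {}
    for sample, sub in df.groupby(cols["sample"], sort=True):
        segs = [Segment(str(r[cols["chrom"]]), int(r[cols["start"]]),
                        int(r[cols["end"]]),
                        _seg_value_to_cn(r[cols["value"]], seg_value))
                for _, r in sub.iterrows()]
        profiles[str(sample)] = SegmentProfile.from_segments(
            str(sample), segs, genome_build=genome_build)
    return profiles


def write_seg(profiles: Iterable[SegmentProfile], path) -> None:
    rows = []
    for prof in profiles:
        for seg in prof.segments:
            rows.append({"ID": prof.lesion_id, "chrom": seg.chrom,
                         "loc.start": seg.start, "loc.end": seg.end,
                         "seg.mean": seg.total_cn})
    pd.DataFrame(rows, columns=["ID", "chrom", "loc.start", "loc.end",
                                "seg.mean"]).to_csv(path, sep="\t",
                                                    index=False)


def read_frequency_table(path, cohort_label: str | None = None
                         ) -> FrequencyTable:
    """Read a delimited frequency table: mutation key, count, cohort size.

    Every row must carry the same cohort size; a count exceeding it is a
    validation error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = {str(c).strip().lower(): c for c in df.columns}
    for needed in ("mutation", "count", "n_total"):
        if needed not in cols:
            raise FormatError(f"{path}: missing required column '{needed}'")
    n_values = set(int(v) for v in df[cols["n_total"]])
    if len(n_values) > 1:
        raise FormatError(f"{path}: inconsistent cohort sizes {n_values}")
    n_total = n_values.pop() if n_values else 0
    entries = {str(r[cols["mutation"]]).strip(): int(r[cols["count"]])
               for _, r in df.iterrows()}
    return FrequencyTable(cohort_label=cohort_label or path.stem,
                          n_total=n_total or 1, entries=entries)


def read_bed(path) -> ExclusionRegions:
    """Read a BED file (0-based half-open) of excluded windows."""
    intervals = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: BED line with <3 fields: {line!r}")
        intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return ExclusionRegions(intervals=tuple(intervals))


def write_bed(regions: ExclusionRegions, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_vcf(path, lesion_id: str | None = None) -> list[MutationCall]:
    """Read somatic calls from a VCF (CHROM/POS/REF/ALT with AD or DP).

    Each sample column yields its own calls; ``lesion_id`` restricts to
    one sample.  Gene/cDNA annotations are not parsed, so mutation
    identity falls back to genomic coordinates.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    wanted = ([lesion_id] if lesion_id else samples)
    for s in wanted:
        if s not in samples:
            raise FormatError(f"{path}: sample '{s}' not in VCF header")
    calls: list[MutationCall] = []
    for var in vcf:
        ad = var.format("AD")
        dp = var.format("DP")
        for alt_i, alt in enumerate(var.ALT):
            for s in wanted:
                si = samples.index(s)
                if ad is not None:
                    alt_count = int(ad[si][alt_i + 1])
                    depth = int(sum(x for x in ad[si] if x >= 0))
                elif dp is not None:
                    alt_count, depth = 0, int(dp[si])
                else:
                    continue
                if depth <= 0:
                    continue
                calls.append(MutationCall(
                    lesion_id=s, gene="", cdna_change="",
                    chrom=str(var.CHROM), pos=int(var.POS),
                    ref_allele=str(var.REF), alt_allele=str(alt),
                    alt_count=alt_count, depth=depth))
    return calls


# ---------------------------------------------------------------------------
# Packaged reference data

def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("felclone") / "data" / name))


def load_cohort_a() -> FrequencyTable:
    """Pooled reference cohort of 98 fibroadenomas + 79 phyllodes tumors
    (n=177) with MED12 exon-2 hotspot counts Gly44Val 14 and Gly44Asp 29."""
    return read_frequency_table(_data_path("cohort_a.csv"),
                                cohort_label="cohort_A (98 FA + 79 PT)")


def load_cohort_b() -> FrequencyTable:
    """Pooled reference cohort of 100 fibroadenomas + 76 phyllodes tumors
    (n=176) with MED12 exon-2 hotspot counts Gly44Val 13 and Gly44Asp 37."""
    return read_frequency_table(_data_path("cohort_b.csv"),
                                cohort_label="cohort_B (100 FA + 76 PT)")


def load_genome(build: str = "hg19") -> dict[str, int]:
    """Chromosome lengths (22 autosomes + X) for the given build."""
    df = pd.read_csv(_data_path(f"{build}_chromosomes.tsv"), sep="\t")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def load_centromeres(build: str = "hg19") -> dict[str, int]:
    """Approximate centromere midpoints for the given build."""
    df = pd.read_csv(_data_path(f"{build}_chromosomes.tsv"), sep="\t")
    return dict(zip(df["chrom"].astype(str), df["centromere"].astype(int)))


def load_five_lesion_case() -> dict:
    """The packaged five-lesion worked example (three fibroadenomas, one
    benign and one malignant phyllodes tumor from a single breast).

    Mutation identities and the lesion topology follow the published
    case; read counts, purities and segment coordinates are synthetic
    stand-ins constructed at realistic panel depths (the per-locus counts
    of the original figure are not machine-readable), hence the
    ``synthetic_`` fixture filenames.
    """
    import yaml

    mutations = read_mutation_table(
        _data_path("synthetic_five_lesion_mutations.tsv"))
    profiles = read_seg(_data_path("synthetic_five_lesion_segments.seg"),
                        genome_build="hg19")
    with open(_data_path("five_lesion_purity.yaml")) as fh:
        purity = yaml.safe_load(fh)
    return {"mutations": mutations, "profiles": profiles, "purity": purity}
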