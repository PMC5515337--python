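"""Core domain types for multi-lesion clonality analysis.

The analysis operates on four kinds of input: per-lesion somatic mutation
calls with read support, per-lesion total copy-number segment profiles,
reference cohort frequency tables for recurrent hotspot mutations, and
genomic exclusion regions (telomeric/centromeric windows).

Coordinate conventions follow each format's standard: mutations and
copy-number segments are 1-based inclusive; exclusion regions use the BED
convention (0-based, half-open).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple


class FelcloneError(Exception):
    """Base class for all package errors."""


class FormatError(FelcloneError):
    """A file could not be parsed (missing column, bad value)."""


class ValidationError(FelcloneError):
    """Parsed data violates a model invariant."""


class CalibrationError(FelcloneError):
    """Too few null scores to calibrate a cutoff."""


class ConfigError(FelcloneError):
    """Invalid pipeline or simulation configuration."""


def mutation_key(gene: str | None, cdna_change: str | None,
                 chrom: str | None = None, pos: int | None = None,
                 ref: str | None = None, alt: str | None = None) -> str:
    """Canonical identity key for a somatic mutation.

    Shared mutations between lesions are identified by gene plus cDNA
    change (e.g. ``MED12:c.131G>T`` vs ``MED12:c.131G>A`` are distinct
    events at the same codon).  When no cDNA annotation is available the
    genomic coordinates serve as fallback key.
    """
    if gene and cdna_change:
        return f"{gene}:{cdna_change}"
    if chrom is not None and pos is not None and ref and alt:
        return f"{chrom}:{pos}:{ref}>{alt}"
    raise ValidationError(
        "mutation needs either (gene, cdna_change) or (chrom, pos, ref, alt)")


@dataclass(frozen=True)
class MutationCall:
    """One somatic mutation observed in one lesion.

    ``alt_count``/``depth`` give the read support at the locus; the variant
    allele fraction (VAF) is their ratio.  ``is_promoter`` marks non-coding
    regulatory hotspots such as the TERT promoter -124C>T.
    """

    lesion_id: str
    gene: str
    protein_change: str = ""
    cdna_change: str = ""
    chrom: str = ""
    pos: int = 0
    ref_allele: str = ""
    alt_allele: str = ""
    alt_count: int = 0
    depth: int = 1
    is_promoter: bool = False

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValidationError(
                f"{self.lesion_id}/{self.gene}: depth must be positive "
                f"(got {self.depth})")
        if self.alt_count < 0 or self.alt_count > self.depth:
            raise ValidationError(
                f"{self.lesion_id}/{self.gene}: alt_count {self.alt_count} "
                f"outside [0, depth={self.depth}]")
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos}")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth

    @property
    def key(self) -> str:
        return mutation_key(self.gene, self.cdna_change, self.chrom,
                            self.pos or None, self.ref_allele,
                            self.alt_allele)


class Segment(NamedTuple):
    """One copy-number segment, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    total_cn: int


@dataclass(frozen=True)
class Breakpoint:
    """Boundary between adjacent segments with differing total copy number.

    ``boundary_pos`` is the end coordinate of the left segment.  Chromosome
    termini are not breakpoints: a whole-chromosome loss produces none.
    """

    chrom: str
    boundary_pos: int
    left_cn: int
    right_cn: int

    def __post_init__(self) -> None:
        if self.left_cn == self.right_cn:
            raise ValidationError(
                f"{self.chrom}:{self.boundary_pos}: not a breakpoint "
                f"(equal copy number {self.left_cn})")


@dataclass(frozen=True)
class SegmentProfile:
    """Ordered, merged copy-number segments for one lesion."""

    lesion_id: str
    segments: tuple[Segment, ...]
    genome_build: str = ""

    @classmethod
    def from_segments(cls, lesion_id: str, segments: Iterable[Segment],
                      genome_build: str = "") -> "SegmentProfile":
        """Sort, validate and merge raw segments into a canonical profile.

        Segments are sorted by (chrom, start); overlap within a chromosome
        is an error; consecutive same-chromosome runs with equal copy
        number are merged into a single segment spanning the run.
        """
        segs = sorted((Segment(str(c), int(s), int(e), int(cn))
                       for c, s, e, cn in segments),
                      key=lambda s: (s.chrom, s.start, s.end))
        merged: list[Segment] = []
        for seg in segs:
            if seg.end < seg.start:
                raise ValidationError(
                    f"{lesion_id} {seg.chrom}:{seg.start}-{seg.end}: "
                    "end < start")
            if seg.total_cn < 0:
                raise ValidationError(
                    f"{lesion_id} {seg.chrom}: negative copy number")
            if merged and merged[-1].chrom == seg.chrom:
                prev = merged[-1]
                if seg.start <= prev.end:
                    raise ValidationError(
                        f"{lesion_id}: overlapping segments "
                        f"{prev.chrom}:{prev.start}-{prev.end} and "
                        f"{seg.chrom}:{seg.start}-{seg.end}")
                if seg.total_cn == prev.total_cn:
                    merged[-1] = prev._replace(end=seg.end)
                    continue
            merged.append(seg)
        return cls(lesion_id=lesion_id, segments=tuple(merged),
                   genome_build=genome_build)

    def breakpoints(self) -> list[Breakpoint]:
        """Internal boundaries between adjacent differing-CN segments."""
        out: list[Breakpoint] = []
        for left, right in zip(self.segments, self.segments[1:]):
            if left.chrom == right.chrom and left.total_cn != right.total_cn:
                out.append(Breakpoint(chrom=left.chrom,
                                      boundary_pos=left.end,
                                      left_cn=left.total_cn,
                                      right_cn=right.total_cn))
        return out

    def copy_number_at(self, chrom: str, pos: int, default: int = 2) -> int:
        """Total copy number of the segment overlapping ``chrom:pos``.

        Positions outside any segment fall back to ``default`` (normal
        diploid), matching how targeted panels leave uncovered regions
        uncalled.
        """
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos <= seg.end:
                return seg.total_cn
        return default

    def is_flat(self, neutral_cn: int = 2) -> bool:
        """True when the profile has no copy-number alterations."""
        return all(s.total_cn == neutral_cn for s in self.segments)


@dataclass(frozen=True)
class FrequencyTable:
    """Reference cohort counts for recurrent hotspot mutations.

    ``entries`` maps a mutation key to the number of cohort cases carrying
    it; ``n_total`` is the cohort size.  The per-lesion prevalence of
    mutation m is f_m = count_m / n_total.
    """

    cohort_label: str
    n_total: int
    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError("cohort size must be positive")
        for key, count in self.entries.items():
            if count < 0 or count > self.n_total:
                raise ValidationError(
                    f"{self.cohort_label}: count {count} for {key} outside "
                    f"[0, n_total={self.n_total}]")

    def frequency(self, key: str) -> float:
        """Prevalence f_m of a mutation; 0.0 for keys not in the table."""
        return self.entries.get(key, 0) / self.n_total

    def __contains__(self, key: str) -> bool:
        return key in self.entries


@dataclass(frozen=True)
class ExclusionRegions:
    """Genomic windows (BED convention) whose breakpoints are discarded.

    Typically 3 Mb windows at each telomere and around each centromere;
    intervals are 0-based half-open.
    """

    intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValidationError(
                    f"empty exclusion interval {chrom}:{start}-{end}")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        # merge overlaps so the bisect lookup below stays correct
        index: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            merged: list[tuple[int, int]] = []
            for start, end in sorted(ivs):
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            index[chrom] = merged
        object.__setattr__(self, "_index", index)

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 1-based position ``pos`` falls in an excluded window."""
        ivs = getattr(self, "_index").get(chrom)
        if not ivs:
            return False
        p0 = pos - 1  # convert to 0-based
        i = bisect.bisect_right(ivs, (p0, float("inf")))
        return i > 0 and ivs[i - 1][0] <= p0 < ivs[i - 1][1]
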