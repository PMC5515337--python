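"""End-to-end per-patient relatedness analysis.

Combines the two evidence lines into one verdict per lesion pair:

* the shared-hotspot chance-sharing test (mutation evidence), and
* the breakpoint partial-identity score against a null calibrated on
  cross-patient comparisons (copy-number evidence).

A pair is called ``related`` when either line is positive (they are
mutually reinforcing; a significant shared hotspot suffices even when the
copy-number comparison is non-informative, as happens against a flat
profile).  ``non_informative`` is reserved for pairs with neither
mutation data nor an informative copy-number comparison; everything else
is ``unrelated``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .breakpoints import (DEFAULT_LEVEL, DEFAULT_TOLERANCE,
                          IdentityScoreResult, NullCalibration,
                          calibrate_cutoff, extract_breakpoints,
                          make_exclusion_regions, partial_identity_score)
from .ccf import DEFAULT_CLONAL_THRESHOLD, CcfEstimate, classify_clonality
from .datamodel import (CalibrationError, ConfigError, ExclusionRegions,
                        FrequencyTable, MutationCall, SegmentProfile)
from .hotspot import DEFAULT_ALPHA, SharedMutationEvidence, pair_evidence
from .io import (load_centromeres, load_cohort_a, load_cohort_b,
                 load_genome, read_bed, read_frequency_table,
                 read_mutation_table, read_seg)

logger = logging.getLogger("felclone")


@dataclass(frozen=True)
class RelatednessResult:
    """Combined verdict for one lesion pair."""

    lesion_pair: tuple[str, str]
    hotspot_evidence: SharedMutationEvidence
    identity_evidence: IdentityScoreResult | None
    calibration: NullCalibration | None
    identity_status: str        # "ok" | "non_informative" | "no_segments"
    verdict: str                # "related" | "unrelated" | "non_informative"
    notes: str = ""


def combine_verdict(hotspot: SharedMutationEvidence,
                    identity: IdentityScoreResult | None,
                    calibration: NullCalibration | None,
                    identity_status: str,
                    has_mutation_data: bool) -> tuple[str, str]:
    """Verdict rule: related iff hotspot significant OR score > cutoff."""
    notes = []
    identity_positive = (identity_status == "ok" and identity is not None
                         and calibration is not None
                         and identity.score > calibration.cutoff)
    if hotspot.significant and identity_positive:
        notes.append("concordant mutation and copy-number evidence")
        return "related", "; ".join(notes)
    if hotspot.significant:
        if identity_status == "non_informative":
            notes.append("copy-number comparison non-informative "
                         "(flat or missing profile)")
        return "related", "; ".join(notes)
    if identity_positive:
        notes.append("copy-number evidence only")
        return "related", "; ".join(notes)
    if identity_status != "ok" and not has_mutation_data:
        return "non_informative", "no informative evidence line"
    if identity_status == "non_informative":
        notes.append("copy-number comparison non-informative")
    return "unrelated", "; ".join(notes)


def analyze_patient(mutations: list[MutationCall],
                    profiles: dict[str, SegmentProfile] | None,
                    purity: dict[str, float],
                    freq: FrequencyTable,
                    reference_profiles: list[SegmentProfile] | None = None,
                    excl: ExclusionRegions | None = None,
                    alpha: float = DEFAULT_ALPHA,
                    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
                    tolerance: int = DEFAULT_TOLERANCE,
                    method: str = "normal_ci",
                    level: float = DEFAULT_LEVEL,
                    lesion_ids: list[str] | None = None
                    ) -> tuple[list[RelatednessResult], list[CcfEstimate]]:
    """Full analysis of one patient's lesions.

    Lesions are taken from the union of ids seen in the mutation table,
    the segment profiles and ``lesion_ids``.  The breakpoint-identity
    null is calibrated once from the reference profiles (all
    cross-reference pairs plus each lesion against every reference).
    """
    by_lesion: dict[str, list[MutationCall]] = {}
    for m in mutations:
        by_lesion.setdefault(m.lesion_id, []).append(m)
    ids = sorted(set(by_lesion) | set(profiles or {}) | set(lesion_ids or []))
    if len(ids) < 2:
        raise ConfigError(f"need at least two lesions, got {ids}")

    # CCF table
    ccf_rows: list[CcfEstimate] = []
    for lid in ids:
        for m in by_lesion.get(lid, []):
            p = purity.get(lid)
            if p is None:
                raise ConfigError(f"no purity for lesion '{lid}'")
            if profiles and lid in profiles and m.chrom:
                local_cn = profiles[lid].copy_number_at(m.chrom, m.pos)
            else:
                local_cn = 2
                if profiles and lid in profiles:
                    logger.warning("%s %s: no segment overlap, assuming "
                                   "local CN 2", lid, m.key)
            ccf_rows.append(classify_clonality(
                m.alt_count, m.depth, p, local_cn,
                clonal_threshold=clonal_threshold,
                mutation_key=m.key, lesion_id=lid))

    # Null calibration for breakpoint identity
    lesion_bps = {}
    ref_bps: list = []
    ref_null: list[float] = []
    if profiles:
        lesion_bps = {lid: extract_breakpoints(profiles[lid], excl)
                      for lid in ids if lid in profiles}
        if reference_profiles:
            ref_bps = [extract_breakpoints(p, excl)
                       for p in reference_profiles]
            ref_null = [partial_identity_score(x, y, tolerance).score
                        for x, y in itertools.combinations(ref_bps, 2)]

    results: list[RelatednessResult] = []
    for a, b in itertools.combinations(ids, 2):
        hot = pair_evidence(by_lesion.get(a, []), by_lesion.get(b, []),
                            freq, alpha=alpha)
        hot = dataclasses.replace(hot, lesion_pair=(a, b))
        identity = None
        calibration = None
        status = "no_segments"
        if a in lesion_bps and b in lesion_bps:
            identity = partial_identity_score(
                lesion_bps[a], lesion_bps[b], tolerance,
                lesion_pair=(a, b))
            if ref_bps:
                null_scores = list(ref_null)
                for query in (lesion_bps[a], lesion_bps[b]):
                    null_scores.extend(
                        partial_identity_score(query, r, tolerance).score
                        for r in ref_bps)
                try:
                    calibration = calibrate_cutoff(null_scores,
                                                   method=method,
                                                   level=level)
                    status = ("ok" if lesion_bps[a] and lesion_bps[b]
                              else "non_informative")
                except CalibrationError:
                    status = "no_segments"
            else:
                status = "no_segments"
        has_mut = bool(by_lesion.get(a)) and bool(by_lesion.get(b))
        verdict, notes = combine_verdict(hot, identity, calibration,
                                         status, has_mut)
        results.append(RelatednessResult(
            lesion_pair=(a, b), hotspot_evidence=hot,
            identity_evidence=identity, calibration=calibration,
            identity_status=status, verdict=verdict, notes=notes))
    return results, ccf_rows


_FREQ_SHORTCUTS = {"cohort_A": load_cohort_a, "cohort_B": load_cohort_b}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
        cfg.setdefault("_base_dir", str(Path(config).parent))
        return cfg
    return dict(config)


def run_pipeline(config) -> dict[str, Path]:
    """Run the full analysis from a YAML config (path or mapping).

    Config keys: ``mutations`` (TSV path, required), ``purity`` (mapping
    lesion id -> tumor cell content, or path to a two-column TSV/YAML,
    required), ``frequency_table`` (path or the shortcuts ``cohort_A`` /
    ``cohort_B``; default cohort_A), ``segments`` and
    ``reference_segments`` (SEG paths, optional), ``exclusion_bed``
    (optional; default 3 Mb telomere/centromere windows for
    ``genome_build``), ``genome_build`` (required when segments are
    given), ``outdir`` (required), plus thresholds ``alpha``,
    ``clonal_threshold``, ``tolerance``, ``cutoff_method``,
    ``cutoff_level``, ``seg_value``.

    Writes ``pairs.tsv``/``pairs.json``, ``ccf.tsv`` and ``run_info.json``
    into ``outdir``; outputs are written only after the whole analysis
    succeeds, so a failure leaves no partial report.
    """
    cfg = _load_config(config)
    base = Path(cfg.get("_base_dir", "."))

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    if "mutations" not in cfg or "outdir" not in cfg or "purity" not in cfg:
        raise ConfigError("config needs 'mutations', 'purity' and 'outdir'")
    mutations = read_mutation_table(_resolve(cfg["mutations"]))

    freq_spec = cfg.get("frequency_table", "cohort_A")
    if freq_spec in _FREQ_SHORTCUTS:
        freq = _FREQ_SHORTCUTS[freq_spec]()
    else:
        freq = read_frequency_table(_resolve(freq_spec))

    purity_spec = cfg["purity"]
    if isinstance(purity_spec, dict):
        purity = {str(k): float(v) for k, v in purity_spec.items()}
    else:
        with open(_resolve(purity_spec)) as fh:
            purity = {str(k): float(v)
                      for k, v in yaml.safe_load(fh).items()}

    profiles = None
    reference_profiles = None
    excl = None
    seg_value = cfg.get("seg_value", "integer_cn")
    if cfg.get("segments"):
        build = cfg.get("genome_build")
        if not build:
            raise ConfigError("'genome_build' is required when segment "
                              "files are supplied")
        profiles = read_seg(_resolve(cfg["segments"]), seg_value=seg_value,
                            genome_build=build)
        if cfg.get("reference_segments"):
            reference_profiles = list(read_seg(
                _resolve(cfg["reference_segments"]), seg_value=seg_value,
                genome_build=build).values())
        if cfg.get("exclusion_bed"):
            excl = read_bed(_resolve(cfg["exclusion_bed"]))
        else:
            excl = make_exclusion_regions(load_genome(build),
                                          load_centromeres(build))

    results, ccf_rows = analyze_patient(
        mutations, profiles, purity, freq,
        reference_profiles=reference_profiles, excl=excl,
        alpha=float(cfg.get("alpha", DEFAULT_ALPHA)),
        clonal_threshold=float(cfg.get("clonal_threshold",
                                       DEFAULT_CLONAL_THRESHOLD)),
        tolerance=int(cfg.get("tolerance", DEFAULT_TOLERANCE)),
        method=cfg.get("cutoff_method", "normal_ci"),
        level=float(cfg.get("cutoff_level", DEFAULT_LEVEL)))

    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"pairs_tsv": outdir / "pairs.tsv",
             "pairs_json": outdir / "pairs.json",
             "ccf_tsv": outdir / "ccf.tsv",
             "run_info": outdir / "run_info.json"}

    pair_rows = []
    for r in results:
        ev = r.hotspot_evidence
        pair_rows.append({
            "lesion_a": r.lesion_pair[0], "lesion_b": r.lesion_pair[1],
            "shared_mutations": ",".join(ev.shared_mutations),
            "combined_probability": round(ev.combined_probability, 6),
            "hotspot_significant": ev.significant,
            "identity_score": (round(r.identity_evidence.score, 6)
                               if r.identity_evidence else None),
            "matched_breakpoints": (r.identity_evidence.matched_breakpoints
                                    if r.identity_evidence else None),
            "cutoff": (round(r.calibration.cutoff, 6)
                       if r.calibration else None),
            "identity_status": r.identity_status,
            "verdict": r.verdict, "notes": r.notes})

    with open(paths["pairs_tsv"], "w") as fh:
        cols = list(pair_rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in pair_rows:
            fh.write("\t".join("" if row[c] is None else str(row[c])
                               for c in cols) + "\n")
    with open(paths["pairs_json"], "w") as fh:
        json.dump(pair_rows, fh, indent=2)
        fh.write("\n")

    with open(paths["ccf_tsv"], "w") as fh:
        fh.write("lesion_id\tmutation\tvaf\tpurity\tlocal_cn\t"
                 "multiplicity\tccf\tci_low\tci_high\tlabel\n")
        for c in ccf_rows:
            fh.write(f"{c.lesion_id}\t{c.mutation_key}\t{c.vaf:.6f}\t"
                     f"{c.purity:.4f}\t{c.local_cn}\t{c.multiplicity}\t"
                     f"{c.ccf:.6f}\t{c.ci_low:.6f}\t{c.ci_high:.6f}\t"
                     f"{c.label}\n")

    public_cfg = {k: v for k, v in cfg.items() if not k.startswith("_")}
    cfg_hash = hashlib.sha256(
        json.dumps(public_cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(paths["run_info"], "w") as fh:
        json.dump({"felclone_version": __version__,
                   "config_sha256": cfg_hash,
                   "frequency_table": freq.cohort_label,
                   "n_pairs": len(results)}, fh, indent=2)
        fh.write("\n")
    logger.info("wrote %d pair verdicts to %s", len(results),
                paths["pairs_tsv"])
    return paths

def cohort_performance(sim_config, n_reference: int = 22,
                       alpha: float = DEFAULT_ALPHA,
                       tolerance: int = DEFAULT_TOLERANCE,
                       method: str = "normal_ci",
                       level: float = DEFAULT_LEVEL,
                       excl: ExclusionRegions | None = None) -> dict:
    """Relatedness recovery on a simulated cohort with known truth.

    Simulates ``sim_config.n_patients`` patients plus one shared
    reference cohort, runs the hotspot test and the breakpoint-identity
    comparison on every within-patient lesion pair, and scores verdicts
    against the ground-truth labels.  Returns sensitivity (related pairs
    called related) and false-positive rate (unrelated pairs called
    related), with counts.
    """
    from .simulate import simulate_cohort, simulate_reference_cohort

    if excl is None:
        excl = make_exclusion_regions(sim_config.genome,
                                      sim_config.centromeres)
    freq = sim_config.hotspot_spectrum
    refs = simulate_reference_cohort(sim_config, n_profiles=n_reference)
    ref_bps = [extract_breakpoints(p, excl) for p in refs]
    null_scores = [partial_identity_score(x, y, tolerance).score
                   for x, y in itertools.combinations(ref_bps, 2)]
    calibration = calibrate_cutoff(null_scores, method=method, level=level)

    tp = fn = fp = tn = 0
    for sim in simulate_cohort(sim_config):
        by_lesion: dict[str, list[MutationCall]] = {}
        for m in sim.mutations:
            by_lesion.setdefault(m.lesion_id, []).append(m)
        bps = {lid: extract_breakpoints(prof, excl)
               for lid, prof in sim.profiles.items()}
        for a, b, related in sim.truth:
            hot = pair_evidence(by_lesion.get(a, []), by_lesion.get(b, []),
                                freq, alpha=alpha)
            score = partial_identity_score(bps[a], bps[b], tolerance).score
            called = hot.significant or score > calibration.cutoff
            if related and called:
                tp += 1
            elif related:
                fn += 1
            elif called:
                fp += 1
            else:
                tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    fpr = fp / (fp + tn) if fp + tn else float("nan")
    return {"sensitivity": sens, "false_positive_rate": fpr,
            "n_related": tp + fn, "n_unrelated": fp + tn,
            "cutoff": calibration.cutoff,
            "null_median": float(__import__("numpy").median(null_scores))}
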