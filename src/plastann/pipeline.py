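"""Batch annotation pipeline: search -> boundary detection -> QC -> output.

``annotate_target`` runs the whole per-target chain: homology search and
best-hit clustering, GBDA start/stop resolution, IBDA intron handling,
short-exon-1 rescue, RNA terminus refinement, IR detection and coverage QC.
``run_batch`` applies it to a directory of target FASTA files against a
directory of reference GenBank files, writing one annotated GenBank per
target plus a consolidated warning log. The annotation path contains no
randomness: identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

from ._seq import revcomp, translate
from .gbda import GbdaParams, find_start, find_stop, probe_search, refine_rna_boundaries, refine_terminus, upstream_stop_bound
from .genbank_io import (
    FORWARD,
    REVERSE,
    FeatureLocation,
    PlastomeRecord,
    read_fasta_target,
    records_from_dir,
    validate_reference,
    write_genbank,
)
from .ibda import (
    INTRON_LOST,
    INTRON_PRESENT,
    classify_interhsp,
    locate_pcg_intron_boundaries,
    locate_trna_intron_boundaries,
    split_codon_nt,
    trna_intron_lost,
)
from .ir_qc import IrAnnotation, detect_ir, flag_pseudogenes
from .locate import (
    DEFAULT_EXON1_WINDOW_NT,
    PreliminaryLocus,
    SkippedGene,
    locate_genes,
    locate_short_exon1,
    needs_exon1_rescue,
    order_loci,
)
from .reference_db import ReferenceDatabase, build_reference_db
from .search import SearchConfig

# warning types mirrored into the log
W_LOW_IDENTITY = "low_identity_skip"
W_NON_ATG = "non_atg_start"
W_STRATEGY_CD = "strategy_c_or_d"
W_INTRON_LOSS = "intron_loss"
W_BOUNDARY_FALLBACK = "boundary_fallback"
W_COVERAGE = "coverage_flag"
W_RUNAWAY = "runaway_orf"
W_EXON1 = "exon1_not_found"
W_OTHER = "note"


@dataclasses.dataclass
class AnnotationConfig:
    search: SearchConfig = dataclasses.field(default_factory=SearchConfig)
    gbda: GbdaParams = dataclasses.field(default_factory=GbdaParams)
    min_ir_length: int = 1000
    qcoverage_min: float = 0.5
    qcoverage_max: float = 2.0
    exon1_window: int = DEFAULT_EXON1_WINDOW_NT
    exon1_mismatches: int = 0
    circular: bool = False

    def __post_init__(self) -> None:
        if self.qcoverage_min >= self.qcoverage_max:
            raise ValueError("qcoverage minimum must be below the maximum")


@dataclasses.dataclass
class GeneAnnotation:
    """A finished annotation for one gene copy on the target."""

    gene_name: str
    category: str  # "PCG" | "tRNA" | "rRNA"
    copy_index: int
    location: FeatureLocation  # forward-axis coordinates
    source_reference: str
    reference_length: int
    start_strategy: str | None = None  # GBDA strategy for PCGs
    start_codon: str | None = None
    intron_status: str | None = None  # "intron_present" | "intron_lost" | None
    warnings: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class TargetLog:
    target_id: str
    total_reference_genes: int = 0
    total_annotated: int = 0
    missing_gene_names: list[str] = dataclasses.field(default_factory=list)
    skipped: list[SkippedGene] = dataclasses.field(default_factory=list)
    warnings: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    ir: IrAnnotation | None = None
    error: str | None = None

    def add(self, wtype: str, message: str) -> None:
        self.warnings.append((wtype, message))

    def warning_types(self) -> set[str]:
        return {t for t, _ in self.warnings}


@dataclasses.dataclass
class RunLog:
    targets: list[TargetLog] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------


def _coding_strand(target: PlastomeRecord, strand: int) -> str:
    return target.sequence if strand == FORWARD else revcomp(target.sequence)


def _cs_segments_to_location(
    segments_cs: Sequence[tuple[int, int]], strand: int, L: int
) -> FeatureLocation:
    """cs segments (ascending, 5'->3') to a forward-axis FeatureLocation."""
    if strand == FORWARD:
        segs = tuple(segments_cs)
    else:
        segs = tuple((L - b, L - a) for a, b in segments_cs)
    return FeatureLocation(segs, strand)


def _trim_overlaps(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Trim each interval's 5' end up to the previous 3' end, keeping frame."""
    out = [intervals[0]]
    for a, b in intervals[1:]:
        prev_end = out[-1][1]
        if a < prev_end:
            a += 3 * (-(-(prev_end - a) // 3))  # ceil to a codon step
        if a < b:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# per-category annotation
# ---------------------------------------------------------------------------


def _pcg_single_exon(
    cs: str, a: int, b: int, entry, params: GbdaParams, log: TargetLog, gene: str
) -> tuple[list[tuple[int, int]], dict]:
    res = find_start(cs, a, entry.aa_sequence, params)
    stop_end, stop_warn = find_stop(cs, a)
    warnings = list(res.warnings) + stop_warn
    if stop_warn:
        log.add(W_RUNAWAY, f"{gene}: {stop_warn[0]}")
    if res.strategy in ("c", "d"):
        log.add(W_STRATEGY_CD, f"{gene}: start resolved by strategy ({res.strategy})")
    if res.start_codon != "ATG":
        log.add(W_NON_ATG, f"{gene}: non-ATG start codon {res.start_codon}")
    if stop_end - 3 < b - 3 and stop_end <= b:
        warnings.append("stop codon inside HSP (possible pseudogene)")
    start = res.start if res.start < stop_end else a
    meta = {
        "start_strategy": res.strategy,
        "start_codon": res.start_codon,
        "warnings": warnings,
    }
    return [(start, stop_end)], meta


def _pcg_rescue_exon1(
    cs: str,
    hsp2_5p: int,
    entry,
    cfg: AnnotationConfig,
    log: TargetLog,
    gene: str,
) -> tuple[list[tuple[int, int]], dict]:
    """Annotate a short-exon-1 gene from its exon-2 HSP."""
    params = cfg.gbda
    ref_e1_len = entry.exon_lengths[0]
    ref_e1_nt = entry.nt_sequence[:ref_e1_len]
    ref_e2_len = entry.exon_lengths[1]
    split = split_codon_nt(ref_e2_len)
    warnings: list[str] = []

    region_start, _ = upstream_stop_bound(cs, hsp2_5p)
    region_end = min(len(cs), hsp2_5p + 3 * params.search_depth_aa)
    exon2_aa = entry.exon_aa[1] if entry.exon_aa else entry.aa_sequence
    found = probe_search(cs, region_start, region_end, exon2_aa, params)
    if found is not None:
        first_codon, _shift = found
    else:
        first_codon = hsp2_5p
        warnings.append("exon2 probe not found; HSP 5' end used")
        log.add(W_BOUNDARY_FALLBACK, f"{gene}: exon2 probe not found")
    e2_start = first_codon - split
    stop_end, stop_warn = find_stop(cs, first_codon)
    warnings += stop_warn
    if stop_warn:
        log.add(W_RUNAWAY, f"{gene}: {stop_warn[0]}")

    match = locate_short_exon1(
        cs, e2_start, ref_e1_nt, cfg.exon1_window, cfg.exon1_mismatches
    )
    if match is None:
        warnings.append("short first exon not found upstream; exon 2 only")
        log.add(W_EXON1, f"{gene}: short first exon not found in upstream window")
        meta = {
            "start_strategy": None,
            "start_codon": None,
            "warnings": warnings,
            "intron_status": None,
        }
        return [(e2_start, stop_end)], meta
    e1 = match
    start_codon = cs[e1[0] : e1[0] + 3]
    if start_codon != "ATG":
        warnings.append(f"non-ATG start codon {start_codon}")
        log.add(W_NON_ATG, f"{gene}: non-ATG start codon {start_codon}")
    total = (e1[1] - e1[0]) + (stop_end - e2_start)
    if total % 3 != 0:
        warnings.append("joined exon1+exon2 length not a multiple of 3")
        log.add(W_BOUNDARY_FALLBACK, f"{gene}: exon1 rescue breaks the reading frame")
    meta = {
        "start_strategy": "a",
        "start_codon": start_codon,
        "warnings": warnings,
        "intron_status": INTRON_PRESENT,
    }
    return [e1, (e2_start, stop_end)], meta


def _annotate_pcg(
    locus: PreliminaryLocus,
    target: PlastomeRecord,
    cfg: AnnotationConfig,
    log: TargetLog,
) -> GeneAnnotation | None:
    L = target.length
    cs = _coding_strand(target, locus.strand)
    entry = locus.reference_entry
    gene = locus.gene_name
    params = cfg.gbda
    intervals = _trim_overlaps([h.cs_interval(L) for h in locus.hsp_cluster])
    qspans = [(h.q_start, h.q_end) for h in locus.hsp_cluster]
    meta: dict
    intron_status = None

    if not entry.has_intron:
        a = intervals[0][0]
        b = intervals[-1][1]
        segments, meta = _pcg_single_exon(cs, a, b, entry, params, log, gene)
    else:
        junction_aa = entry.exon_lengths[0] // 3  # 2-exon query junction
        if len(intervals) == 1:
            (a, b) = intervals[0]
            q0, q1 = qspans[0]
            if q0 + 4 <= junction_aa and q1 >= junction_aa + 4:
                # one HSP spans the exon junction: the intron is lost
                segments, meta = _pcg_single_exon(cs, a, b, entry, params, log, gene)
                intron_status = INTRON_LOST
                log.add(W_INTRON_LOSS, f"{gene}: intron loss (single CDS annotated)")
            elif needs_exon1_rescue(entry) and q0 >= max(0, junction_aa - 2):
                segments, meta = _pcg_rescue_exon1(cs, a, entry, cfg, log, gene)
                intron_status = meta.pop("intron_status", INTRON_PRESENT)
            else:
                segments, meta = _pcg_single_exon(cs, a, b, entry, params, log, gene)
                meta["warnings"].append("expected intron partner HSP missing")
                log.add(W_OTHER, f"{gene}: expected intron partner HSP missing")
        else:
            # pairwise over consecutive HSPs; merge pairs whose intron is lost
            merged: list[list] = [[intervals[0], 0]]
            exon_calls = []
            warnings: list[str] = []
            for i in range(1, len(intervals)):
                prev_iv, prev_exon = merged[-1]
                cur_iv = intervals[i]
                hsp1_3p = prev_iv[0] + 3 * ((prev_iv[1] - prev_iv[0]) // 3)
                status = classify_interhsp(cs, hsp1_3p, cur_iv[0])
                if status == INTRON_LOST:
                    merged[-1] = [(prev_iv[0], cur_iv[1]), i]
                    intron_status = INTRON_LOST
                    log.add(
                        W_INTRON_LOSS, f"{gene}: intron loss (single CDS annotated)"
                    )
                    continue
                exon_idx_1 = prev_exon if prev_exon < len(entry.exon_aa) else -1
                exon_idx_2 = min(i, len(entry.exon_aa) - 1)
                call = locate_pcg_intron_boundaries(
                    cs,
                    hsp1_3p,
                    cur_iv[0],
                    entry.exon_aa[exon_idx_1],
                    entry.exon_aa[exon_idx_2],
                    entry.exon_lengths[exon_idx_1],
                    entry.exon_lengths[exon_idx_2],
                    params,
                )
                warnings += call.warnings
                if call.boundary_strategy == "fallback_b":
                    log.add(W_BOUNDARY_FALLBACK, f"{gene}: intron probe fallback")
                exon_calls.append((merged[-1][0], cur_iv, call))
                merged.append([cur_iv, i])
                if intron_status is None:
                    intron_status = INTRON_PRESENT
            if not exon_calls:
                # every junction collapsed: single CDS
                a = merged[0][0][0]
                b = merged[-1][0][1]
                segments, meta = _pcg_single_exon(cs, a, b, entry, params, log, gene)
            else:
                first_iv = exon_calls[0][0]
                res = find_start(cs, first_iv[0], entry.aa_sequence, params)
                if res.strategy in ("c", "d"):
                    log.add(
                        W_STRATEGY_CD,
                        f"{gene}: start resolved by strategy ({res.strategy})",
                    )
                if res.start_codon != "ATG":
                    log.add(W_NON_ATG, f"{gene}: non-ATG start codon {res.start_codon}")
                last_call = exon_calls[-1][2]
                scan_from = last_call.exon2_start + last_call.split_codon_nt
                stop_end, stop_warn = find_stop(cs, scan_from)
                if stop_warn:
                    log.add(W_RUNAWAY, f"{gene}: {stop_warn[0]}")
                warnings += res.warnings + stop_warn
                segments = []
                pos = res.start
                for _, _, call in exon_calls:
                    segments.append((pos, call.exon1_end))
                    pos = call.exon2_start
                segments.append((pos, stop_end))
                joined = "".join(cs[a:b] for a, b in segments)
                if len(joined) % 3 == 0 and "*" in translate(joined[:-3]):
                    warnings.append(
                        "internal stop in joined exons (possible pseudogene)"
                    )
                meta = {
                    "start_strategy": res.strategy,
                    "start_codon": res.start_codon,
                    "warnings": warnings,
                }

    if any(a >= b for a, b in segments):
        log.add(W_OTHER, f"{gene}: degenerate segments; annotation dropped")
        return None
    return GeneAnnotation(
        gene_name=gene,
        category="PCG",
        copy_index=locus.copy_index,
        location=_cs_segments_to_location(segments, locus.strand, L),
        source_reference=entry.source_record,
        reference_length=entry.length,
        start_strategy=meta.get("start_strategy"),
        start_codon=meta.get("start_codon"),
        intron_status=intron_status,
        warnings=meta.get("warnings", []),
    )


def _annotate_rna(
    locus: PreliminaryLocus,
    target: PlastomeRecord,
    cfg: AnnotationConfig,
    log: TargetLog,
) -> GeneAnnotation | None:
    L = target.length
    cs = _coding_strand(target, locus.strand)
    entry = locus.reference_entry
    gene = locus.gene_name
    params = cfg.gbda
    intervals = _trim_overlaps([h.cs_interval(L) for h in locus.hsp_cluster])
    warnings: list[str] = []
    intron_status = None

    if not entry.has_intron:
        a, b = intervals[0][0], intervals[-1][1]
        b5, b3, warns = refine_rna_boundaries(cs, a, b, entry.nt_sequence, params)
        if warns:
            log.add(W_BOUNDARY_FALLBACK, f"{gene}: {warns[0]}")
        segments = [(b5, b3)]
        warnings += warns
    else:
        e1_len = entry.exon_lengths[0]
        ref_e1 = entry.nt_sequence[:e1_len]
        ref_e2 = entry.nt_sequence[e1_len:]
        w = params.rna_window_nt
        if len(intervals) >= 2:
            h1, h2 = locus.hsp_cluster[0], locus.hsp_cluster[1]
            gap = intervals[1][0] - intervals[0][1]
            q_gap = h2.q_start - h1.q_end
            lost = trna_intron_lost(gap, q_gap)
        else:
            q0, q1 = locus.hsp_cluster[0].q_start, locus.hsp_cluster[0].q_end
            lost = q0 + 10 <= e1_len and q1 >= e1_len + 10
        if lost:
            a, b = intervals[0][0], intervals[-1][1]
            warnings.append("intron lost; joined exons annotated as one gene")
            log.add(W_INTRON_LOSS, f"{gene}: intron loss")
            b5, off5 = refine_terminus(cs, a, ref_e1[:w], True, params)
            b3, off3 = refine_terminus(cs, b, ref_e2[-w:], False, params)
            if b5 is None or b3 is None or b5 >= b3:
                b5, b3 = a, b
                warnings.append("terminus probes not found; HSP ends kept")
                log.add(W_BOUNDARY_FALLBACK, f"{gene}: terminus probes not found")
            segments = [(b5, b3)]
            intron_status = INTRON_LOST
        elif len(intervals) >= 2:
            call = locate_trna_intron_boundaries(
                cs, intervals[0], intervals[1], ref_e1, ref_e2, params
            )
            warnings += call.warnings
            if call.warnings:
                log.add(W_BOUNDARY_FALLBACK, f"{gene}: {call.warnings[0]}")
            segments = list(call.exon_locations)
            intron_status = INTRON_PRESENT
        else:
            a, b = intervals[0]
            warnings.append("expected intron partner HSP missing")
            log.add(W_OTHER, f"{gene}: expected intron partner HSP missing")
            segments = [(a, b)]

    if any(a >= b for a, b in segments):
        log.add(W_OTHER, f"{gene}: degenerate segments; annotation dropped")
        return None
    return GeneAnnotation(
        gene_name=gene,
        category=entry.category,
        copy_index=locus.copy_index,
        location=_cs_segments_to_location(segments, locus.strand, L),
        source_reference=entry.source_record,
        reference_length=entry.length,
        intron_status=intron_status,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# target-level orchestration
# ---------------------------------------------------------------------------


def annotate_target(
    db: ReferenceDatabase,
    target: PlastomeRecord,
    cfg: AnnotationConfig | None = None,
) -> tuple[list[GeneAnnotation], TargetLog]:
    """Annotate one target plastome against the reference database."""
    cfg = cfg or AnnotationConfig()
    log = TargetLog(target_id=target.record_id)
    loci, skipped, missing = locate_genes(db, target, cfg.search)
    log.skipped = skipped
    for s in skipped:
        log.add(
            W_LOW_IDENTITY,
            f"{s.gene_name}: best identity {s.best_identity:.1f}% below "
            f"threshold {cfg.search.identity_threshold_pcg:.0f}%; not annotated",
        )

    annotations: list[GeneAnnotation] = []
    for locus in order_loci(loci):
        if locus.category == "PCG":
            ann = _annotate_pcg(locus, target, cfg, log)
        else:
            ann = _annotate_rna(locus, target, cfg, log)
        if ann is not None:
            annotations.append(ann)

    for flag in flag_pseudogenes(
        annotations, db, cfg.qcoverage_min, cfg.qcoverage_max
    ):
        msg = (
            f"{flag.gene_name} (copy {flag.copy_index}): query coverage "
            f"{flag.coverage:.2f} {flag.bound_violated}"
        )
        log.add(W_COVERAGE, msg)
        for ann in annotations:
            if (
                ann.gene_name == flag.gene_name
                and ann.copy_index == flag.copy_index
            ):
                ann.warnings.append(f"query coverage {flag.coverage:.2f} "
                                    f"({flag.bound_violated})")

    log.ir = detect_ir(target, cfg.min_ir_length, cfg.circular)
    annotated_names = {a.gene_name for a in annotations}
    log.missing_gene_names = sorted(
        set(missing) | (db.gene_names - annotated_names - {s.gene_name for s in skipped})
    )
    log.total_reference_genes = len(db.gene_names)
    log.total_annotated = len(annotations)
    return annotations, log


def write_log(runlog: RunLog, path: str | Path) -> None:
    """Write the consolidated human-readable warning/statistics log."""
    lines = [
        "plastann warning log",
        "gene counting: the reference total counts unique gene names; the "
        "annotated total counts annotated gene copies (IR duplicates count "
        "separately)",
        "",
    ]
    for tl in runlog.targets:
        lines.append(f"=== target: {tl.target_id} ===")
        if tl.error:
            lines.append(f"error: {tl.error}")
            lines.append("")
            continue
        for wtype, msg in tl.warnings:
            lines.append(f"warning [{wtype}]: {msg}")
        if tl.ir is not None:
            if tl.ir.found:
                lines.append(
                    f"inverted repeat: IRa {tl.ir.ira[0] + 1}..{tl.ir.ira[1]}, "
                    f"IRb {tl.ir.irb[0] + 1}..{tl.ir.irb[1]} "
                    f"({tl.ir.length} nt, {tl.ir.identity:.1f}% identity)"
                )
            else:
                lines.append("inverted repeat: none found")
        lines.append(
            f"total number of genes in the reference plastome(s): "
            f"{tl.total_reference_genes}"
        )
        lines.append(f"total number of genes annotated: {tl.total_annotated}")
        missing = ", ".join(tl.missing_gene_names) or "none"
        lines.append(f"genes not annotated: {missing}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def run_batch(
    reference_dir: str | Path,
    target_dir: str | Path,
    out_dir: str | Path,
    cfg: AnnotationConfig | None = None,
    log_path: str | Path | None = None,
) -> int:
    """Annotate every target FASTA against every reference GenBank.

    Produces one GenBank per target (same basename) and one consolidated
    warning log. A per-file failure is logged and the batch continues;
    the exit status is nonzero only on global failure (no usable references
    or an unreadable directory).
    """
    cfg = cfg or AnnotationConfig()
    reference_dir, target_dir = Path(reference_dir), Path(target_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    references = records_from_dir(reference_dir)
    if not references:
        raise FileNotFoundError(f"no reference GenBank files in {reference_dir}")
    runlog = RunLog()
    for ref in references:
        for issue in validate_reference(ref):
            tl = TargetLog(target_id=f"reference {ref.record_id}")
            tl.error = issue
            runlog.targets.append(tl)
    db = build_reference_db(references)
    target_paths = sorted(
        p
        for p in target_dir.iterdir()
        if p.suffix.lower() in (".fasta", ".fa", ".fas")
    )
    for path in target_paths:
        try:
            target = read_fasta_target(path)
            target.topology = "circular" if cfg.circular else "linear"
            annotations, tl = annotate_target(db, target, cfg)
            write_genbank(target, annotations, out_dir / (path.stem + ".gb"), tl.ir)
        except Exception as exc:
            tl = TargetLog(target_id=path.stem, error=str(exc))
        runlog.targets.append(tl)
    write_log(runlog, log_path or out_dir / "warning.log")
    return 0
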