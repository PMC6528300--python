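"""Reverse query-subject homology search.

Reference genes are the *query*, the unannotated target plastome the
*subject*: nucleotide search locates rRNA/tRNA genes, translated protein
search locates protein-coding genes on the six-frame translated target.
Each hit is a local-alignment HSP on the forward axis of the target.

Two interchangeable backends implement the same contract:

``builtin``
    A deterministic in-process aligner: exact k-mer seeds, clustering by
    diagonal (per strand / reading frame), ungapped X-drop extension, percent
    identity measured over the full clustered span. Substitution-tolerant but
    gap-free, which is what the synthetic fixtures produce.
``external``
    Shells out to NCBI BLAST+ (``blastn`` / ``tblastn``) and maps its
    1-based inclusive tabular output (outfmt 6) onto the internal 0-based
    half-open convention.
"""

from __future__ import annotations

import dataclasses
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

from ._seq import revcomp, translate
from .genbank_io import FORWARD, REVERSE, PlastomeRecord
from .reference_db import ReferenceGeneEntry

NT_MODE = "nucleotide"
AA_MODE = "protein"

# builtin aligner knobs (not part of the public configuration surface)
_K_NT = 11
_K_AA = 4
_MIN_SPAN_NT = 20  # discard HSPs shorter than this (query units)
_MIN_SPAN_AA = 10
_MAX_SEED_GAP_NT = 60  # hard split of diagonal runs at larger query gaps
_MAX_SEED_GAP_AA = 60
_SOFT_GAP_NT = 30  # longer seed gaps must be bridged by real similarity
_SOFT_GAP_AA = 25
_BRIDGE_MIN_IDENTITY = 0.40
# steep mismatch penalties keep the X-drop extension from drifting into
# unrelated sequence (an intron, a spacer) on chance matches
_SCORES_NT = (1, -2, 6)  # match, mismatch, X-drop
_SCORES_AA = (1, -2, 6)


@dataclasses.dataclass
class Hsp:
    """One high-scoring segment pair (query = reference gene, subject = target)."""

    gene_name: str
    reference_id: str
    mode: str  # NT_MODE or AA_MODE
    q_start: int  # query coords, 0-based half-open (aa for protein mode)
    q_end: int
    s_start: int  # subject nt coords on the forward axis, 0-based half-open
    s_end: int
    strand: int  # subject strand of the hit
    frame: int  # reading-frame offset 0-2 on the subject coding strand (protein)
    percent_identity: float
    aligned_length: int
    entry: ReferenceGeneEntry | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("HSP coordinates must be non-empty intervals")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity outside [0, 100]")

    def cs_interval(self, target_length: int) -> tuple[int, int]:
        """Subject interval on the coding strand of the hit."""
        if self.strand == FORWARD:
            return self.s_start, self.s_end
        return target_length - self.s_end, target_length - self.s_start


@dataclasses.dataclass
class SearchConfig:
    identity_threshold_pcg: float = 40.0  # percent; PCGs below it are skipped
    evalue: float = 1e-5
    max_intron_span: int = 10_000  # nt; HSP clustering proximity cap
    backend: str = "builtin"  # "builtin" | "external"
    extras: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold_pcg <= 100:
            raise ValueError("identity threshold must be in (0, 100]")


class BackendUnavailableError(RuntimeError):
    """Raised when the external search tool cannot be run."""


# ---------------------------------------------------------------------------
# builtin backend
# ---------------------------------------------------------------------------


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _extend_ungapped(
    q: str, s: str, qs: int, qe: int, diag: int,
    scores: tuple[int, int, int] = _SCORES_NT,
) -> tuple[int, int]:
    """Extend [qs, qe) outward along ``diag`` (s_pos = q_pos + diag)."""
    match, mismatch, xdrop = scores
    best = cur = 0
    i = qs - 1
    new_qs = qs
    while i >= 0 and i + diag >= 0:
        cur += match if q[i] == s[i + diag] else mismatch
        if cur > best:
            best, new_qs = cur, i
        elif best - cur >= xdrop:
            break
        i -= 1
    best = cur = 0
    j = qe
    new_qe = qe
    while j < len(q) and j + diag < len(s):
        cur += match if q[j] == s[j + diag] else mismatch
        if cur > best:
            best, new_qe = cur, j + 1
        elif best - cur >= xdrop:
            break
        j += 1
    return new_qs, new_qe


def _seed_hsps(
    q: str,
    s: str,
    index: dict[str, list[int]],
    k: int,
    max_gap: int,
    soft_gap: int,
    min_span: int,
    scores: tuple[int, int, int],
) -> list[tuple[int, int, int, float]]:
    """(qs, qe, diag, identity%) for each clustered, extended diagonal run.

    Seeds on one diagonal are chained into a run; a gap above ``soft_gap``
    is only bridged when the intervening sequence keeps a minimal identity,
    so an isolated chance seed far from a real alignment starts its own
    (usually sub-threshold) run instead of stretching the real one.
    """
    by_diag: dict[int, list[int]] = {}
    for i in range(len(q) - k + 1):
        for j in index.get(q[i : i + k], ()):
            by_diag.setdefault(j - i, []).append(i)
    out = []
    for diag, qpos in sorted(by_diag.items()):
        qpos.sort()
        runs: list[list[int]] = [[qpos[0]]]
        for i in qpos[1:]:
            prev = runs[-1][-1]
            gap = i - prev
            split = gap > max_gap
            if not split and gap > soft_gap:
                bridge = range(prev + k, i)
                matches = sum(q[p] == s[p + diag] for p in bridge)
                split = matches < _BRIDGE_MIN_IDENTITY * len(bridge)
            if split:
                runs.append([])
            runs[-1].append(i)
        for run in runs:
            qs, qe = run[0], run[-1] + k
            qs, qe = _extend_ungapped(q, s, qs, qe, diag, scores)
            span = qe - qs
            if span < min_span:
                continue
            matches = sum(q[i] == s[i + diag] for i in range(qs, qe))
            out.append((qs, qe, diag, 100.0 * matches / span))
    return out


def _merge_contained(raw: list[Hsp]) -> list[Hsp]:
    """Drop HSPs whose query interval is contained in a better same-strand HSP."""
    raw = sorted(
        raw, key=lambda h: (-(h.q_end - h.q_start), -h.percent_identity, h.s_start)
    )
    kept: list[Hsp] = []
    for h in raw:
        contained = any(
            k.strand == h.strand
            and k.q_start <= h.q_start
            and h.q_end <= k.q_end
            and k.s_start <= h.s_start
            and h.s_end <= k.s_end
            for k in kept
        )
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.s_start, h.q_start))
    return kept


class BuiltinBackend:
    """Pure in-process aligner fulfilling the search contract."""

    def search_nucleotide(
        self,
        entries: Sequence[ReferenceGeneEntry],
        target: PlastomeRecord,
        cfg: SearchConfig,
    ) -> list[Hsp]:
        subject = target.sequence
        index = _kmer_index(subject, _K_NT)
        hsps: list[Hsp] = []
        for entry in entries:
            raw: list[Hsp] = []
            for strand in (FORWARD, REVERSE):
                q = entry.nt_sequence if strand == FORWARD else revcomp(
                    entry.nt_sequence
                )
                n = len(q)
                for qs, qe, diag, ident in _seed_hsps(
                    q, subject, index, _K_NT, _MAX_SEED_GAP_NT, _SOFT_GAP_NT,
                    _MIN_SPAN_NT, _SCORES_NT,
                ):
                    if strand == FORWARD:
                        q0, q1 = qs, qe
                    else:
                        q0, q1 = n - qe, n - qs
                    raw.append(
                        Hsp(
                            gene_name=entry.gene_name,
                            reference_id=entry.source_record,
                            mode=NT_MODE,
                            q_start=q0,
                            q_end=q1,
                            s_start=diag + qs,
                            s_end=diag + qe,
                            strand=strand,
                            frame=0,
                            percent_identity=ident,
                            aligned_length=qe - qs,
                            entry=entry,
                        )
                    )
            hsps.extend(_merge_contained(raw))
        return hsps

    def search_protein(
        self,
        entries: Sequence[ReferenceGeneEntry],
        target: PlastomeRecord,
        cfg: SearchConfig,
    ) -> list[Hsp]:
        L = target.length
        frames: list[tuple[int, int, str, dict[str, list[int]]]] = []
        for strand in (FORWARD, REVERSE):
            cs = target.sequence if strand == FORWARD else revcomp(target.sequence)
            for f in range(3):
                prot = translate(cs[f:])
                frames.append((strand, f, prot, _kmer_index(prot, _K_AA)))
        hsps: list[Hsp] = []
        for entry in entries:
            q = entry.aa_sequence
            raw: list[Hsp] = []
            for strand, f, prot, index in frames:
                for qs, qe, diag, ident in _seed_hsps(
                    q, prot, index, _K_AA, _MAX_SEED_GAP_AA, _SOFT_GAP_AA,
                    _MIN_SPAN_AA, _SCORES_AA,
                ):
                    cs_start = f + 3 * (diag + qs)
                    cs_end = f + 3 * (diag + qe)
                    if strand == FORWARD:
                        s0, s1 = cs_start, cs_end
                    else:
                        s0, s1 = L - cs_end, L - cs_start
                    raw.append(
                        Hsp(
                            gene_name=entry.gene_name,
                            reference_id=entry.source_record,
                            mode=AA_MODE,
                            q_start=qs,
                            q_end=qe,
                            s_start=s0,
                            s_end=s1,
                            strand=strand,
                            frame=f,
                            percent_identity=ident,
                            aligned_length=qe - qs,
                            entry=entry,
                        )
                    )
            hsps.extend(_merge_contained(raw))
        return hsps


# ---------------------------------------------------------------------------
# external BLAST+ adapter
# ---------------------------------------------------------------------------

_OUTFMT = "6 qseqid pident length qstart qend sstart send"


class BlastBackend:
    """Adapter around the NCBI BLAST+ ``blastn``/``tblastn`` binaries."""

    def __init__(self, blastn: str = "blastn", tblastn: str = "tblastn") -> None:
        self.blastn = blastn
        self.tblastn = tblastn

    def _require(self, exe: str) -> str:
        path = shutil.which(exe)
        if path is None:
            raise BackendUnavailableError(
                f"{exe} not found on PATH; use backend='builtin' instead"
            )
        return path

    def _run(
        self,
        exe: str,
        entries: Sequence[ReferenceGeneEntry],
        target: PlastomeRecord,
        cfg: SearchConfig,
        mode: str,
        extra_args: Sequence[str],
    ) -> list[Hsp]:
        exe = self._require(exe)
        with tempfile.TemporaryDirectory(prefix="plastann_blast_") as tmp:
            qpath = Path(tmp) / "query.fasta"
            spath = Path(tmp) / "subject.fasta"
            with open(qpath, "w") as fh:
                for i, e in enumerate(entries):
                    seq = e.aa_sequence if mode == AA_MODE else e.nt_sequence
                    fh.write(f">e{i}\n{seq}\n")
            with open(spath, "w") as fh:
                fh.write(f">target\n{target.sequence}\n")
            cmd = [
                exe,
                "-query",
                str(qpath),
                "-subject",
                str(spath),
                "-evalue",
                str(cfg.evalue),
                "-outfmt",
                _OUTFMT,
                *extra_args,
            ]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise BackendUnavailableError(
                    f"{exe} failed ({proc.returncode}): {proc.stderr.strip()}"
                )
            hsps = []
            L = target.length
            for line in proc.stdout.splitlines():
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 7:
                    continue
                idx = int(cols[0][1:])
                entry = entries[idx]
                pident, length = float(cols[1]), int(cols[2])
                qstart, qend = int(cols[3]), int(cols[4])
                sstart, send = int(cols[5]), int(cols[6])
                if sstart <= send:
                    strand, s0, s1 = FORWARD, sstart - 1, send
                    frame = (sstart - 1) % 3
                else:
                    strand, s0, s1 = REVERSE, send - 1, sstart
                    frame = (L - sstart) % 3
                hsps.append(
                    Hsp(
                        gene_name=entry.gene_name,
                        reference_id=entry.source_record,
                        mode=mode,
                        q_start=qstart - 1,
                        q_end=qend,
                        s_start=s0,
                        s_end=s1,
                        strand=strand,
                        frame=frame if mode == AA_MODE else 0,
                        percent_identity=pident,
                        aligned_length=length,
                        entry=entry,
                    )
                )
            hsps.sort(key=lambda h: (h.gene_name, h.s_start, h.q_start))
            return hsps

    def search_nucleotide(self, entries, target, cfg) -> list[Hsp]:
        return self._run(
            self.blastn,
            entries,
            target,
            cfg,
            NT_MODE,
            ["-task", "blastn", "-dust", "no"],
        )

    def search_protein(self, entries, target, cfg) -> list[Hsp]:
        return self._run(
            self.tblastn,
            entries,
            target,
            cfg,
            AA_MODE,
            ["-db_gencode", "11", "-seg", "no"],
        )


def get_backend(cfg: SearchConfig):
    if cfg.backend == "builtin":
        return BuiltinBackend()
    if cfg.backend == "external":
        return BlastBackend()
    raise ValueError(f"unknown search backend {cfg.backend!r}")


def search_nucleotide(
    entries: Sequence[ReferenceGeneEntry],
    target: PlastomeRecord,
    cfg: SearchConfig,
) -> list[Hsp]:
    return get_backend(cfg).search_nucleotide(entries, target, cfg)


def search_protein(
    entries: Sequence[ReferenceGeneEntry],
    target: PlastomeRecord,
    cfg: SearchConfig,
) -> list[Hsp]:
    return get_backend(cfg).search_protein(entries, target, cfg)


# ---------------------------------------------------------------------------
# best-hit selection and per-copy clustering
# ---------------------------------------------------------------------------


def _chain(cluster: list[Hsp]) -> list[Hsp]:
    """Best collinear chain of HSPs within one proximity cluster.

    Keeps the highest-scoring subset whose query and subject orders agree
    (5'->3' in gene orientation), discarding stray off-diagonal hits that
    happen to fall between a gene's exons.
    """
    if len(cluster) <= 1:
        return cluster
    strand = cluster[0].strand
    # coding-strand order: ascending s_start on forward, descending s_end on
    # reverse (both equal ascending position on the coding strand)
    hsps = sorted(
        cluster,
        key=lambda h: (h.q_start, h.s_start if strand == FORWARD else -h.s_end),
    )

    def w(h: Hsp) -> float:
        return h.aligned_length * h.percent_identity

    # X-drop extension can fray an HSP end well into an intron, so
    # neighbouring exon HSPs may overlap in query and subject; nucleotide
    # HSPs (short tRNA exons) get slack proportional to their size
    nt_mode = cluster[0].mode == NT_MODE

    def compatible(a: Hsp, b: Hsp) -> bool:
        if nt_mode:
            slack = max(12, min(a.aligned_length, b.aligned_length) // 2)
            s_slack = slack
        else:
            slack, s_slack = 4, 12
        if b.q_start < a.q_end - slack:
            return False
        if strand == FORWARD:
            return b.s_start >= a.s_end - s_slack
        return b.s_end <= a.s_start + s_slack

    n = len(hsps)
    score = [w(h) for h in hsps]
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            if compatible(hsps[i], hsps[j]) and score[i] + w(hsps[j]) > score[j]:
                score[j] = score[i] + w(hsps[j])
                prev[j] = i
    j = max(range(n), key=lambda k: score[k])
    chain = []
    while j != -1:
        chain.append(hsps[j])
        j = prev[j]
    chain.reverse()
    return chain


def select_best_hits(
    hsps: Sequence[Hsp],
    max_intron_span: int = 10_000,
    entry_order: Sequence[ReferenceGeneEntry] | None = None,
    identity_floor_frac: float = 0.6,
    cluster_score_frac: float = 0.5,
) -> dict[str, list[list[Hsp]]]:
    """Per gene: keep the single best reference entry, cluster HSPs per copy.

    The reference entry whose best HSP has the highest percent identity wins
    (ties: longer aligned length, then first entry in input order). The
    surviving HSPs are then clustered by (strand, subject proximity up to
    ``max_intron_span``) into per-gene-copy clusters ordered by query
    coordinate, so an intron gene's cluster reads HSP1, HSP2, ... in gene
    orientation and an IR-duplicated gene yields two clusters.

    Low-signal noise is pruned relative to the gene's best hit: HSPs below
    ``identity_floor_frac`` of the best percent identity are dropped before
    clustering, and clusters scoring (sum of aligned length x identity)
    below ``cluster_score_frac`` of the gene's best cluster are discarded —
    equal-quality IR copies always survive.
    """
    order: dict[int, int] = {}
    if entry_order is not None:
        order = {id(e): i for i, e in enumerate(entry_order)}
    by_gene: dict[str, list[Hsp]] = {}
    for h in hsps:
        by_gene.setdefault(h.gene_name, []).append(h)

    result: dict[str, list[list[Hsp]]] = {}
    for gene in sorted(by_gene):
        gene_hsps = by_gene[gene]
        by_entry: dict[int, list[Hsp]] = {}
        for h in gene_hsps:
            by_entry.setdefault(id(h.entry), []).append(h)

        def rank(entry_id: int) -> tuple[float, int, int]:
            hs = by_entry[entry_id]
            best = max(hs, key=lambda h: (h.percent_identity, h.aligned_length))
            return (
                -best.percent_identity,
                -best.aligned_length,
                order.get(entry_id, 0),
            )

        best_entry = min(by_entry, key=rank)
        chosen = by_entry[best_entry]
        best_identity = max(h.percent_identity for h in chosen)
        chosen = [
            h
            for h in chosen
            if h.percent_identity >= identity_floor_frac * best_identity
        ]
        entry = chosen[0].entry
        gap_cap = max_intron_span
        if entry is not None and not entry.has_intron:
            # HSPs of one copy of an intron-free gene cannot be farther
            # apart than the gene itself (with slack for alignment fraying)
            gap_cap = min(max_intron_span, max(2 * entry.length, 300))
        clusters: list[list[Hsp]] = []
        for strand in (FORWARD, REVERSE):
            strand_hsps = sorted(
                (h for h in chosen if h.strand == strand), key=lambda h: h.s_start
            )
            current: list[Hsp] = []
            for h in strand_hsps:
                if current and h.s_start - max(x.s_end for x in current) > gap_cap:
                    clusters.append(current)
                    current = []
                current.append(h)
            if current:
                clusters.append(current)
        clusters = [_chain(c) for c in clusters]

        def score(cluster: list[Hsp]) -> float:
            return sum(h.aligned_length * h.percent_identity for h in cluster)

        if clusters:
            best_score = max(score(c) for c in clusters)
            clusters = [
                c for c in clusters if score(c) >= cluster_score_frac * best_score
            ]
        for c in clusters:
            c.sort(key=lambda h: h.q_start)
        clusters.sort(key=lambda c: min(h.s_start for h in c))
        result[gene] = clusters
    return result
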