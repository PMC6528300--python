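"""Inverted-repeat boundary detection and query-coverage pseudogene QC.

The IR pair is found by a self-search of the target against its own reverse
complement (the in-process equivalent of a self-BLASTN): exact k-mer seeds
between the sequence and its reverse complement, ungapped X-drop extension,
and the longest non-overlapping reverse-strand pair of length at least
``min_ir_length`` (default 1000, the single adjustable parameter) becomes
(IRa, IRb). The two inter-IR regions are the large and small single-copy
regions.

Query coverage — annotated gene length divided by reference gene length —
flags putative pseudogenes outside the (0.5, 2) default band; the
comparisons are strict, so a coverage exactly at a bound passes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from ._seq import revcomp
from .genbank_io import PlastomeRecord
from .search import _extend_ungapped, _kmer_index

_K_IR = 17
_XDROP_IR = 20


@dataclasses.dataclass
class IrAnnotation:
    found: bool
    ira: tuple[int, int] = (0, 0)
    irb: tuple[int, int] = (0, 0)
    lsc: tuple[int, int] = (0, 0)  # end < start means the region wraps
    ssc: tuple[int, int] = (0, 0)
    identity: float = 0.0

    @property
    def length(self) -> int:
        return self.ira[1] - self.ira[0]


@dataclasses.dataclass
class CoverageFlag:
    gene_name: str
    copy_index: int
    coverage: float
    bound_violated: str  # "low" | "high"


def _inverted_repeat_pairs(
    seq: str, min_len: int
) -> list[tuple[int, int, int, float]]:
    """(start1, start2, span, identity%) for reverse-complement repeat pairs,
    canonicalized so the first copy precedes and does not overlap the second."""
    L = len(seq)
    rc = revcomp(seq)
    index = _kmer_index(rc, _K_IR)
    by_diag: dict[int, list[int]] = {}
    for i in range(0, L - _K_IR + 1):
        for j in index.get(seq[i : i + _K_IR], ()):
            by_diag.setdefault(j - i, []).append(i)
    pairs: dict[tuple[int, int, int], float] = {}
    for diag, positions in by_diag.items():
        positions.sort()
        runs: list[list[int]] = [[]]
        for i in positions:
            if runs[-1] and i - runs[-1][-1] > 3 * _K_IR:
                runs.append([])
            runs[-1].append(i)
        for run in runs:
            if not run:
                continue
            qs, qe = run[0], run[-1] + _K_IR
            qs, qe = _extend_ungapped(seq, rc, qs, qe, diag, (1, -2, _XDROP_IR))
            span = qe - qs
            if span < min_len:
                continue
            j = diag + qs
            a, b = qs, L - (j + span)  # forward-axis starts of the two copies
            first, second = min(a, b), max(a, b)
            if first + span > second:  # self-overlapping palindrome
                continue
            matches = sum(seq[i] == rc[i + diag] for i in range(qs, qe))
            key = (first, second, span)
            pairs[key] = max(pairs.get(key, 0.0), 100.0 * matches / span)
    return [(f, s, sp, ident) for (f, s, sp), ident in sorted(pairs.items())]


def detect_ir(
    target: PlastomeRecord,
    min_ir_length: int = 1000,
    circular: bool = False,
) -> IrAnnotation:
    """Locate the inverted-repeat pair and derive the quadripartite layout.

    With ``circular`` the search runs on the doubled sequence so a repeat
    copy spanning the origin is still found; reported intervals are
    normalized to start in [0, L) and an interval with end > L wraps.
    Returns ``found=False`` for IR-lacking plastomes.
    """
    seq = target.sequence
    L = len(seq)
    if circular:
        doubled = seq + seq
        raw = _inverted_repeat_pairs(doubled, min_ir_length)
        seen: dict[tuple[int, int, int], float] = {}
        for f, s, span, ident in raw:
            if span > L:
                continue
            fn, sn = f % L, s % L
            first, second = min(fn, sn), max(fn, sn)
            # drop duplicates produced by the doubling
            key = (first, second, span)
            seen[key] = max(seen.get(key, 0.0), ident)
        candidates = [(f, s, sp, i) for (f, s, sp), i in seen.items()]
        # discard pairs overlapping on the circle
        candidates = [
            c
            for c in candidates
            if not _circ_overlap(c[0], c[2], c[1], c[2], L)
        ]
    else:
        candidates = _inverted_repeat_pairs(seq, min_ir_length)
    if not candidates:
        return IrAnnotation(found=False)
    best = max(candidates, key=lambda c: (c[2], c[3], -c[0]))
    f, s, span, ident = best
    ira, irb = (f, f + span), (s, s + span)
    inter1 = (ira[1] % L, irb[0])
    inter2 = (irb[1] % L, ira[0])
    len1 = (inter1[1] - inter1[0]) % L
    len2 = (inter2[1] - inter2[0]) % L
    lsc, ssc = (inter1, inter2) if len1 >= len2 else (inter2, inter1)
    return IrAnnotation(
        found=True, ira=ira, irb=irb, lsc=lsc, ssc=ssc, identity=ident
    )


def _circ_overlap(a: int, la: int, b: int, lb: int, L: int) -> bool:
    pts_a = {(a + i) % L for i in range(la)}
    for i in range(lb):
        if (b + i) % L in pts_a:
            return True
    return False


def query_coverage(annotated_len: int, reference_len: int) -> float:
    """Annotated gene length divided by reference gene length (exon sums)."""
    if reference_len <= 0:
        raise ValueError("reference length must be positive")
    return annotated_len / reference_len


def flag_pseudogenes(
    annotations: Sequence,
    db,
    qmin: float = 0.5,
    qmax: float = 2.0,
) -> list[CoverageFlag]:
    """One flag per annotation whose coverage falls strictly outside
    [qmin, qmax]; thresholds are user-adjustable."""
    if qmin >= qmax:
        raise ValueError("qmin must be smaller than qmax")
    flags = []
    for ann in annotations:
        ref_len = getattr(ann, "reference_length", 0)
        if not ref_len:
            entries = db.entries_for(ann.gene_name)
            if not entries:
                continue
            ref_len = max(e.length for e in entries)
        cov = query_coverage(len(ann.location), ref_len)
        if cov < qmin:
            flags.append(CoverageFlag(ann.gene_name, ann.copy_index, cov, "low"))
        elif cov > qmax:
            flags.append(CoverageFlag(ann.gene_name, ann.copy_index, cov, "high"))
    return flags
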