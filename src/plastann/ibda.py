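"""Intron Boundary Detection Algorithm (IBDA).

Classifies the region between two consecutive HSPs of one gene copy as an
intact intron or an intron loss, then places the exon/intron boundaries.

For protein-coding genes the exon-2 start is found with the same sliding
4-residue probe machinery as the start-codon search, then moved left by the
number of split-codon nucleotides, ``len(reference exon2) mod 3`` — the
leading nucleotides of exon 2 that complete the codon begun in exon 1. The
exon-1/intron boundary is placed by the mirrored procedure (probe from the
reference exon-1 C-terminus, scanned left-to-right, moved right by
``len(reference exon1) mod 3``).

Intron-containing tRNAs use 9-nt probes from the terminal 30 nt of each
reference exon instead, searched in the 30 nt of each HSP end plus a 30 nt
flank.
"""

from __future__ import annotations

import dataclasses

from ._seq import is_stop, translate
from .gbda import GbdaParams, probe_search, refine_terminus, upstream_stop_bound

INTRON_PRESENT = "intron_present"
INTRON_LOST = "intron_lost"
SINGLE_HSP = "single_hsp"


@dataclasses.dataclass
class IntronCall:
    status: str
    exon_locations: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    boundary_strategy: str = "probe"  # "probe" | "fallback_b"
    split_codon_nt: int = 0
    probe_shift: int | None = None
    warnings: list[str] = dataclasses.field(default_factory=list)
    exon1_end: int | None = None  # cs coordinate, exclusive
    exon2_start: int | None = None  # cs coordinate


def split_codon_nt(ref_exon2_len_nt: int) -> int:
    """Number of leading exon-2 nucleotides completing the split codon."""
    return ref_exon2_len_nt % 3


def classify_interhsp(target_cs: str, hsp1_3p: int, hsp2_5p: int) -> str:
    """Intron present or lost, from the region strictly between two HSPs.

    The intron is present iff the region contains an in-frame stop codon
    (frame continued from HSP1) or its length is not a multiple of three;
    it is lost iff the region is empty or stop-free with length 0 mod 3.
    ``hsp1_3p`` must lie on a codon boundary of HSP1's frame; overlapping
    HSPs must be trimmed by the caller first.
    """
    if hsp2_5p < hsp1_3p:
        raise ValueError("HSP1 must end at or before HSP2 starts (trim overlaps)")
    gap = hsp2_5p - hsp1_3p
    if gap == 0:
        return INTRON_LOST
    if gap % 3 != 0:
        return INTRON_PRESENT
    for p in range(hsp1_3p, hsp2_5p - 2, 3):
        if is_stop(target_cs[p : p + 3]):
            return INTRON_PRESENT
    return INTRON_LOST


def _probe_search_mirror(
    target_cs: str,
    region_start: int,
    region_end: int,
    ref_aa: str,
    params: GbdaParams,
) -> tuple[int, int] | None:
    """Mirror of :func:`plastann.gbda.probe_search` for the exon-1 3' end.

    Probes are cut from the C-terminus of ``ref_aa`` and slide upstream; the
    region is scanned left-to-right and the candidate closest to the
    downstream stop (the region end) wins. Returns (nt position just past
    the matched last codon, shift) or None.
    """
    plen = params.probe_len_aa
    n_codons = max(0, (region_end - region_start) // 3)
    region_aa = translate(target_cs[region_start : region_start + 3 * n_codons])
    for k in range(0, params.search_depth_aa - plen + 1):
        hi = len(ref_aa) - k
        if hi - plen < 0:
            break
        probe = ref_aa[hi - plen : hi]
        candidates = []
        m = region_aa.find(probe)
        while m != -1:
            end_codon = m + plen + k
            if end_codon <= n_codons:
                candidates.append(end_codon)
            m = region_aa.find(probe, m + 1)
        if candidates:
            return region_start + 3 * max(candidates), k
    return None


def locate_pcg_intron_boundaries(
    target_cs: str,
    hsp1_3p: int,
    hsp2_5p: int,
    ref_exon1_aa: str,
    ref_exon2_aa: str,
    ref_exon1_len_nt: int,
    ref_exon2_len_nt: int,
    params: GbdaParams | None = None,
) -> IntronCall:
    """Place both exon/intron boundaries of an intron-containing PCG.

    Call only after :func:`classify_interhsp` returned ``intron_present``.
    ``hsp1_3p``/``hsp2_5p`` are coding-strand codon boundaries of the two
    HSPs.
    """
    params = params or GbdaParams()
    split = split_codon_nt(ref_exon2_len_nt)
    r1 = ref_exon1_len_nt % 3
    warnings: list[str] = []
    if (r1 + split) % 3 != 0:
        warnings.append(
            "reference exon lengths are not frame-consistent "
            f"(exon1 mod 3 = {r1}, exon2 mod 3 = {split})"
        )
    strategy = "probe"
    shift = None

    # exon2 5' boundary
    region_start, truncated = upstream_stop_bound(target_cs, hsp2_5p)
    if truncated:
        warnings.append("no in-frame stop upstream of HSP2; region truncated")
    region_end = min(len(target_cs), hsp2_5p + 3 * params.search_depth_aa)
    found = probe_search(target_cs, region_start, region_end, ref_exon2_aa, params)
    if found is not None:
        first_codon, shift = found
    else:
        first_codon = hsp2_5p
        strategy = "fallback_b"
        warnings.append(
            "exon2 probe not found; HSP2 5' end tentatively used; verify manually"
        )
    exon2_start = first_codon - split

    # exon1 3' boundary (mirrored procedure)
    stop_after, stop_warn = _first_stop_at_or_after(target_cs, hsp1_3p)
    warnings.extend(stop_warn)
    region_start1 = max(hsp1_3p % 3, hsp1_3p - 3 * params.search_depth_aa)
    found1 = _probe_search_mirror(
        target_cs, region_start1, stop_after, ref_exon1_aa, params
    )
    if found1 is not None:
        last_codon_end, _shift1 = found1
    else:
        last_codon_end = hsp1_3p
        strategy = "fallback_b"
        warnings.append(
            "exon1 probe not found; HSP1 3' end tentatively used; verify manually"
        )
    exon1_end = last_codon_end + r1

    if not exon1_end < exon2_start:
        warnings.append("degenerate intron boundaries; HSP ends kept")
        exon1_end, exon2_start = hsp1_3p + r1, hsp2_5p - split
    return IntronCall(
        status=INTRON_PRESENT,
        boundary_strategy=strategy,
        split_codon_nt=split,
        probe_shift=shift,
        warnings=warnings,
        exon1_end=exon1_end,
        exon2_start=exon2_start,
    )


def _first_stop_at_or_after(target_cs: str, pos: int) -> tuple[int, list[str]]:
    """Start position of the first in-frame stop at/after ``pos`` (frame of
    ``pos``); region bound for the mirrored exon-1 probe search."""
    for p in range(pos, len(target_cs) - 2, 3):
        if is_stop(target_cs[p : p + 3]):
            return p, []
    last = pos + 3 * ((len(target_cs) - pos) // 3)
    return last, ["no in-frame stop downstream of HSP1; region truncated"]


def trna_intron_lost(
    gap_nt: int, q_gap: int, max_gap_nt: int = 10, max_q_gap: int = 3
) -> bool:
    """Zero/short-gap intron-loss rule for tRNAs (no reading-frame concept):
    subject gap below ``max_gap_nt`` with abutting query coordinates."""
    return gap_nt < max_gap_nt and abs(q_gap) <= max_q_gap


def locate_trna_intron_boundaries(
    target_cs: str,
    hsp1_cs: tuple[int, int],
    hsp2_cs: tuple[int, int],
    ref_exon1_nt: str,
    ref_exon2_nt: str,
    params: GbdaParams | None = None,
) -> IntronCall:
    """Refine all four exon ends of an intron-containing tRNA independently
    with the 9-nt probe scheme; outer ends behave like RNA-gene termini."""
    params = params or GbdaParams()
    w = params.rna_window_nt
    warnings: list[str] = []
    ends = []
    spec = [
        (hsp1_cs[0], ref_exon1_nt[:w], True, "exon1 5'"),
        (hsp1_cs[1], ref_exon1_nt[-w:], False, "exon1 3'"),
        (hsp2_cs[0], ref_exon2_nt[:w], True, "exon2 5'"),
        (hsp2_cs[1], ref_exon2_nt[-w:], False, "exon2 3'"),
    ]
    for anchor, term, five_prime, label in spec:
        b, _ = refine_terminus(target_cs, anchor, term, five_prime, params)
        if b is None:
            b = anchor
            warnings.append(f"{label} probe not found; HSP end kept")
        ends.append(b)
    e1 = (ends[0], ends[1])
    e2 = (ends[2], ends[3])
    if not (e1[0] < e1[1] <= e2[0] < e2[1]):
        warnings.append("degenerate tRNA exon boundaries; HSP ends kept")
        e1, e2 = hsp1_cs, hsp2_cs
    return IntronCall(
        status=INTRON_PRESENT,
        exon_locations=[e1, e2],
        warnings=warnings,
    )
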