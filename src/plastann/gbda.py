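"""Gene Boundary Detection Algorithm (GBDA).

Resolves start and stop codons of protein-coding genes from a preliminary
HSP, and refines the termini of rRNAs and intron-free tRNAs with short
nucleotide probes. All operations act on the coding-strand-oriented target
sequence (``target_cs``); the caller maps coordinates back to the forward
axis.

The start-codon cascade, in order:

a. the HSP's first residue is methionine -> its ATG is the start;
b. otherwise, among in-frame ATGs between the first in-frame stop upstream
   of the HSP and the HSP's 20th residue, the one closest to that stop;
c. otherwise a 4-residue probe cut from the reference N-terminus slides
   one residue at a time (up to the 20th), the translated region is scanned
   for it, and the matched position is shifted back by the slide count —
   this recovers non-ATG starts and is flagged for manual checking;
d. otherwise the HSP 5' end itself, flagged.
"""

from __future__ import annotations

import dataclasses

from ._seq import is_stop, translate

STRATEGY_MANUAL_CHECK = ("c", "d")


@dataclasses.dataclass
class GbdaParams:
    search_depth_aa: int = 20  # start search reaches the 20th HSP residue
    probe_len_aa: int = 4
    rna_probe_nt: int = 9
    rna_window_nt: int = 30  # terminal window of the HSP searched
    rna_flank_nt: int = 30  # flank added outside the HSP end

    def __post_init__(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class GbdaResult:
    start: int  # nt coordinate of the start codon (gene orientation)
    strategy: str  # "a" | "b" | "c" | "d"
    start_codon: str
    stop_end: int | None = None  # just past the stop codon
    probe_shift: int | None = None  # slide count used by strategy (c)
    warnings: list[str] = dataclasses.field(default_factory=list)


def find_stop(target_cs: str, scan_from: int) -> tuple[int, list[str]]:
    """First in-frame stop codon at/after ``scan_from``; returns its 3' end.

    With no stop before the sequence end the ORF runs away: the last full
    codon boundary is returned together with a warning.
    """
    for p in range(scan_from, len(target_cs) - 2, 3):
        if is_stop(target_cs[p : p + 3]):
            return p + 3, []
    last = scan_from + 3 * ((len(target_cs) - scan_from) // 3)
    return last, ["runaway ORF: no in-frame stop codon before sequence end"]


def upstream_stop_bound(target_cs: str, pos: int) -> tuple[int, bool]:
    """Start of the region delimited by the first in-frame stop upstream of
    ``pos`` (exclusive of the stop). Returns (region_start, truncated)."""
    p = pos - 3
    while p >= 0:
        if is_stop(target_cs[p : p + 3]):
            return p + 3, False
        p -= 3
    return pos % 3, True


def probe_search(
    target_cs: str,
    region_start: int,
    region_end: int,
    ref_aa: str,
    params: GbdaParams | None = None,
) -> tuple[int, int] | None:
    """GBDA strategy-(c) sliding-probe search; shared with the intron module.

    ``region_start`` must be in frame. Probes are ``ref_aa[k:k+4]`` for
    k = 0, 1, ... within the first ``search_depth_aa`` residues. For the
    first probe with a match in the translated region, the matched position
    shifted left by k codons (and still inside the region) becomes the
    candidate; with several candidates the one closest to ``region_start``
    (the upstream stop) wins. Returns (nt position of the start codon,
    shift k) or None.
    """
    params = params or GbdaParams()
    plen = params.probe_len_aa
    n_codons = max(0, (region_end - region_start) // 3)
    region_aa = translate(target_cs[region_start : region_start + 3 * n_codons])
    for k in range(0, params.search_depth_aa - plen + 1):
        probe = ref_aa[k : k + plen]
        if len(probe) < plen:
            break
        candidates = []
        m = region_aa.rfind(probe)
        while m != -1:
            if m - k >= 0:
                candidates.append(m - k)
            m = region_aa.rfind(probe, 0, m)
        if candidates:
            return region_start + 3 * min(candidates), k
    return None


def find_start(
    target_cs: str,
    hsp_5p: int,
    ref_aa: str,
    params: GbdaParams | None = None,
) -> GbdaResult:
    """Resolve the start codon for a PCG HSP via the a/b/c/d cascade."""
    params = params or GbdaParams()
    warnings: list[str] = []

    codon0 = target_cs[hsp_5p : hsp_5p + 3]
    if translate(codon0) == "M":
        return GbdaResult(start=hsp_5p, strategy="a", start_codon=codon0)

    region_start, truncated = upstream_stop_bound(target_cs, hsp_5p)
    if truncated:
        warnings.append("no in-frame stop upstream; region truncated at sequence start")
    region_end = min(len(target_cs), hsp_5p + 3 * params.search_depth_aa)

    atgs = [
        p
        for p in range(region_start, region_end - 2, 3)
        if target_cs[p : p + 3] == "ATG"
    ]
    if atgs:
        start = min(atgs)  # closest to the upstream stop
        return GbdaResult(
            start=start, strategy="b", start_codon="ATG", warnings=warnings
        )

    found = probe_search(target_cs, region_start, region_end, ref_aa, params)
    if found is not None:
        start, shift = found
        codon = target_cs[start : start + 3]
        warnings.append(
            f"start found by reference probe (shift {shift}); "
            f"codon {codon}; verify manually"
        )
        if codon != "ATG":
            warnings.append(f"non-ATG start codon {codon}")
        return GbdaResult(
            start=start,
            strategy="c",
            start_codon=codon,
            probe_shift=shift,
            warnings=warnings,
        )

    codon = target_cs[hsp_5p : hsp_5p + 3]
    warnings.append("putative start at HSP 5' end; verify manually")
    if codon != "ATG":
        warnings.append(f"non-ATG start codon {codon}")
    return GbdaResult(start=hsp_5p, strategy="d", start_codon=codon, warnings=warnings)


def _occurrences(haystack: str, needle: str) -> list[int]:
    out = []
    m = haystack.find(needle)
    while m != -1:
        out.append(m)
        m = haystack.find(needle, m + 1)
    return out


def refine_terminus(
    target_cs: str,
    anchor: int,
    ref_terminus: str,
    five_prime: bool,
    params: GbdaParams | None = None,
) -> tuple[int | None, int | None]:
    """Probe-anchor one RNA-gene terminus near the HSP end ``anchor``.

    ``ref_terminus`` is the terminal ``rna_window_nt`` of the reference gene
    (5' slice for ``five_prime``, 3' slice otherwise). 9-nt probes slide
    inward from the terminus; the first probe with a match anchors the
    boundary, shifted outward by the probe's offset. The match whose implied
    boundary lies closest to the HSP end wins. Returns (boundary, offset) or
    (None, None); the 3' boundary is exclusive.
    """
    params = params or GbdaParams()
    k = params.rna_probe_nt
    if five_prime:
        origin = max(0, anchor - params.rna_flank_nt)
        region = target_cs[origin : min(len(target_cs), anchor + params.rna_window_nt)]
    else:
        origin = max(0, anchor - params.rna_window_nt)
        region = target_cs[origin : min(len(target_cs), anchor + params.rna_flank_nt)]
    for off in range(0, len(ref_terminus) - k + 1):
        if five_prime:
            probe = ref_terminus[off : off + k]
        else:
            end = len(ref_terminus) - off
            probe = ref_terminus[end - k : end]
        candidates = []
        for m in _occurrences(region, probe):
            if five_prime:
                b = origin + m - off
                if b >= 0:
                    candidates.append(b)
            else:
                b = origin + m + k + off
                if b <= len(target_cs):
                    candidates.append(b)
        if candidates:
            return min(candidates, key=lambda b: (abs(b - anchor), b)), off
    return None, None


def refine_rna_boundaries(
    target_cs: str,
    hsp_5p: int,
    hsp_3p: int,
    ref_rna_nt: str,
    params: GbdaParams | None = None,
) -> tuple[int, int, list[str]]:
    """Refine both ends of an rRNA / intron-free tRNA around its HSP."""
    params = params or GbdaParams()
    w = params.rna_window_nt
    warnings: list[str] = []
    b5, _ = refine_terminus(target_cs, hsp_5p, ref_rna_nt[:w], True, params)
    if b5 is None:
        b5 = hsp_5p
        warnings.append("5' terminus probe not found; HSP end kept")
    b3, _ = refine_terminus(target_cs, hsp_3p, ref_rna_nt[-w:], False, params)
    if b3 is None:
        b3 = hsp_3p
        warnings.append("3' terminus probe not found; HSP end kept")
    if b5 >= b3:  # degenerate anchoring; fall back to the HSP
        warnings.append("probe anchoring degenerate; HSP boundaries kept")
        b5, b3 = hsp_5p, hsp_3p
    return b5, b3, warnings
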