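"""Synthetic plastome fixtures with known-truth annotations.

Generates matched (reference GenBank, target FASTA) pairs that emulate the
conserved quadripartite plastome architecture — a large and a small
single-copy region separated by two identical inverted repeats — populated
with protein-coding genes (with and without introns), tRNAs (with and
without introns) and rRNAs (inside the IR). Base composition is ~36% GC, as
in real plastomes. The target is the reference mutated at a per-site
substitution rate plus optional structured perturbations, and every gene
copy carries a truth record of its expected annotation outcome, so the whole
pipeline can be scored without downloading anything.

Perturbations (applied one gene each, on forward-strand single-copy genes):

``intron_loss``              drop the intron of an intron PCG
``start_non_atg``            ATG -> ACG initiator, upstream scrubbed
``start_shift_to_upstream_atg``  start knocked out; in-frame ATG planted 18 nt upstream
``truncate_gene``            3' 70% replaced by random sequence (coverage < 0.5)
``delete_gene``              whole locus replaced by random sequence
``mutate_below_threshold``   codons scrambled to ~30% amino-acid identity
``short_exon1_gene``         adds an rpl16-like gene (9 nt first exon)

Introns are stop-rich in the exon frame by default so the stop-codon intron
test is exercised; ``intron_style="frame_shift"`` generates stop-free
introns whose length is not a multiple of three, exercising the mod-3 test
alone.
"""

from __future__ import annotations

import dataclasses
import random
from pathlib import Path
from typing import Sequence

from ._seq import CODON_TO_AA, STOP_CODONS, revcomp, translate
from .genbank_io import (
    FORWARD,
    REVERSE,
    FeatureLocation,
    GeneFeature,
    PlastomeRecord,
    write_fasta,
    write_genbank,
)
from .pipeline import (
    GeneAnnotation,
    TargetLog,
    W_COVERAGE,
    W_INTRON_LOSS,
    W_LOW_IDENTITY,
    W_NON_ATG,
)

PERTURBATIONS = (
    "intron_loss",
    "start_non_atg",
    "start_shift_to_upstream_atg",
    "truncate_gene",
    "delete_gene",
    "mutate_below_threshold",
    "short_exon1_gene",
)

_SENSE_CODONS = sorted(CODON_TO_AA)
_SENSE_NO_ATG = [c for c in _SENSE_CODONS if c != "ATG"]
_BASES = "ACGT"
_ALT = {b: [x for x in _BASES if x != b] for b in _BASES}

_PCG_PLAIN_NAMES = ["rbcL", "psbA", "matK", "ndhF", "rpoB", "atpB", "psaA", "petA",
                    "ccsA", "rps4", "rpl20", "cemA"]
_PCG_INTRON_NAMES = ["atpF", "ndhA", "rpoC1", "ycf3", "clpP", "ndhB", "rpl2"]
_TRNA_PLAIN_NAMES = ["trnH-GUG", "trnD-GUC", "trnS-GCU", "trnW-CCA", "trnP-UGG",
                     "trnM-CAU", "trnF-GAA", "trnQ-UUG"]
_TRNA_INTRON_NAMES = ["trnK-UUU", "trnL-UAA", "trnG-UCC", "trnA-UGC"]
_RRNA_NAMES = ["rrn16", "rrn23", "rrn4.5", "rrn5"]

_SHORT_EXON1_SEQ = "ATGCTTAGC"  # rpl16-like 9 nt first exon (starts with ATG)


@dataclasses.dataclass
class FixtureSpec:
    seed: int = 0
    n_pcg_plain: int = 6
    n_pcg_intron: int = 3
    n_trna_plain: int = 5
    n_trna_intron: int = 2
    n_rrna: int = 2
    ir_length: int = 3000
    divergence: float = 0.0
    perturbations: tuple[str, ...] = ()
    intron_style: str = "stop_rich"  # or "frame_shift"

    def __post_init__(self) -> None:
        for field in ("n_pcg_plain", "n_pcg_intron", "n_trna_plain",
                      "n_trna_intron", "n_rrna", "ir_length"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")
        if not 0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")
        unknown = set(self.perturbations) - set(PERTURBATIONS)
        if unknown:
            raise ValueError(f"unknown perturbations: {sorted(unknown)}")
        if self.intron_style not in ("stop_rich", "frame_shift"):
            raise ValueError("intron_style must be stop_rich or frame_shift")


@dataclasses.dataclass
class TruthEntry:
    gene_name: str
    category: str
    copy_index: int
    strand: int
    segments: tuple[tuple[int, int], ...]  # target coords, reading order
    intron_status: str  # "none" | "present" | "lost"
    start_codon: str | None
    expected: str  # "annotated" | "missing" | "skipped"
    expected_warning: str | None
    perturbation: str | None


@dataclasses.dataclass
class Fixture:
    spec: FixtureSpec
    reference: PlastomeRecord
    target: PlastomeRecord
    truth: list[TruthEntry]
    reference_truth: list[TruthEntry]
    ir: tuple[tuple[int, int], tuple[int, int]] | None


# ---------------------------------------------------------------------------
# random sequence building blocks
# ---------------------------------------------------------------------------


def _rand_dna(rng: random.Random, n: int) -> str:
    # ~36% GC, plastome-like
    return "".join(rng.choices("ACGT", weights=[32, 18, 18, 32], k=n))


def _rand_codons(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_SENSE_NO_ATG) for _ in range(n))


def _rand_stop(rng: random.Random) -> str:
    return rng.choice(sorted(STOP_CODONS))


def _scrub_frame_stops(seq: str, frame_offset: int, rng: random.Random) -> str:
    s = list(seq)
    for p in range(frame_offset, len(s) - 2, 3):
        while "".join(s[p : p + 3]) in STOP_CODONS:
            s[p + 1] = rng.choice(_ALT[s[p + 1]])
    return "".join(s)


def _mutate(seq: str, rng: random.Random, rate: float,
            protected: Sequence[tuple[int, int]] = ()) -> str:
    if rate <= 0:
        return seq
    s = list(seq)
    for i in range(len(s)):
        if any(a <= i < b for a, b in protected):
            continue
        if s[i] in _ALT and rng.random() < rate:
            s[i] = rng.choice(_ALT[s[i]])
    return "".join(s)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class _Gene:
    name: str
    category: str  # "PCG" | "tRNA" | "rRNA"
    exons: list[str]  # reference, coding strand
    introns: list[str]
    strand: int = FORWARD
    region: str = "lsc"  # "lsc" | "ir" | "ssc"
    perturbation: str | None = None
    # target-side realization, filled by _prepare_target
    t_seq: str = ""
    t_feature_exons: list[tuple[int, int]] | None = None  # (offset, len) in element
    t_start_ext: int = 0  # truth start extends this far into the upstream spacer
    t_intron_status: str = "none"
    expected: str = "annotated"
    expected_warning: str | None = None

    def cs_seq(self, exons: Sequence[str], introns: Sequence[str]) -> str:
        parts = [exons[0]]
        for intron, exon in zip(introns, exons[1:]):
            parts += [intron, exon]
        return "".join(parts)

    @property
    def ref_seq(self) -> str:
        return self.cs_seq(self.exons, self.introns)

    def ref_exon_offsets(self) -> list[tuple[int, int]]:
        out, pos = [], 0
        for i, exon in enumerate(self.exons):
            out.append((pos, len(exon)))
            pos += len(exon)
            if i < len(self.introns):
                pos += len(self.introns[i])
        return out


def _make_pcg(rng: random.Random, name: str, n_aa: int) -> _Gene:
    # no ATG codon among the first 20 internal codons: keeps the start-codon
    # cascade unambiguous under every perturbation
    head = _rand_codons(rng, min(19, n_aa - 1))
    tail = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_aa - 1 - len(head) // 3))
    cds = "ATG" + head + tail[: 3 * (n_aa - 1) - len(head)] + _rand_stop(rng)
    return _Gene(name=name, category="PCG", exons=[cds], introns=[])


def _make_intron(rng: random.Random, length: int, exon1_len: int,
                 exon2_len: int, style: str) -> str:
    """Intron sequence with controlled stop-codon content.

    ``stop_rich``: a stop is planted at the first in-frame codon (frame
    continued from exon 1) and near the intron end in exon 2's frame, so the
    stop-codon criterion fires regardless of the intron length.
    ``frame_shift``: the exon-1 frame is scrubbed stop-free and the length is
    forced off 3, so only the mod-3 criterion fires.
    """
    r1 = exon1_len % 3
    if style == "frame_shift" and length % 3 == 0:
        length += 1
    intron = _rand_dna(rng, length)
    f1 = (3 - r1) % 3  # first in-frame codon (exon-1 continuation)
    if style == "stop_rich":
        intron = intron[:f1] + "TAA" + intron[f1 + 3 :]
        split = exon2_len % 3
        # last codon in exon 2's frame fully inside the intron
        p = length + split - 3
        while p + 3 > length:
            p -= 3
        if p >= f1 + 3:
            intron = intron[:p] + "TAA" + intron[p + 3 :]
    else:
        intron = _scrub_frame_stops(intron, f1, rng)
    return intron


def _make_intron_pcg(rng: random.Random, name: str, n_aa: int, style: str,
                     short_exon1: bool = False) -> _Gene:
    if short_exon1:
        body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_aa - 3))
        cds = _SHORT_EXON1_SEQ + body + _rand_stop(rng)
        exon1_len = 9
        intron_len = rng.randrange(400, 900)
    else:
        g = _make_pcg(rng, name, n_aa)
        cds = g.exons[0]
        exon1_len = rng.randrange(90, len(cds) - 120)
        intron_len = rng.randrange(80, 300)
    exon1, exon2 = cds[:exon1_len], cds[exon1_len:]
    intron = _make_intron(rng, intron_len, len(exon1), len(exon2), style)
    if short_exon1:
        while _SHORT_EXON1_SEQ in intron:  # keep the exon-1 probe unique
            intron = intron.replace(_SHORT_EXON1_SEQ, _rand_dna(rng, 9), 1)
    return _Gene(name=name, category="PCG", exons=[exon1, exon2], introns=[intron])


def _make_rna(rng: random.Random, name: str, category: str, length: int) -> _Gene:
    return _Gene(name=name, category=category, exons=[_rand_dna(rng, length)],
                 introns=[])


def _make_intron_trna(rng: random.Random, name: str) -> _Gene:
    e1 = _rand_dna(rng, rng.randrange(40, 60))
    e2 = _rand_dna(rng, rng.randrange(40, 60))
    intron = _rand_dna(rng, rng.randrange(70, 120))
    return _Gene(name=name, category="tRNA", exons=[e1, e2], introns=[intron])


# ---------------------------------------------------------------------------
# perturbation application (target side)
# ---------------------------------------------------------------------------


def _apply_perturbation(gene: _Gene, rng: random.Random,
                        t_exons: list[str], t_introns: list[str]) -> None:
    """Fill the gene's target-side realization from its (already diverged)
    exon/intron sequences plus the structured edit."""
    p = gene.perturbation
    if p == "intron_loss":
        joined = "".join(t_exons)
        gene.t_seq = joined
        gene.t_feature_exons = [(0, len(joined))]
        gene.t_intron_status = "lost"
        gene.expected_warning = W_INTRON_LOSS
        return
    if p == "delete_gene":
        full = gene.cs_seq(t_exons, t_introns)
        gene.t_seq = _rand_dna(rng, len(full))
        gene.t_feature_exons = None
        gene.expected = "missing"
        return
    if p == "mutate_below_threshold":
        cds = t_exons[0]
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for i in range(1, len(codons) - 1):
            if i % 15 >= 4:  # keep 4 of 15 -> ~27% amino-acid identity
                old_aa = CODON_TO_AA.get(codons[i])
                new = rng.choice(_SENSE_NO_ATG)
                while CODON_TO_AA[new] == old_aa:
                    new = rng.choice(_SENSE_NO_ATG)
                codons[i] = new
        gene.t_seq = "".join(codons)
        gene.t_feature_exons = None
        gene.expected = "skipped"
        gene.expected_warning = W_LOW_IDENTITY
        return
    if p == "truncate_gene":
        cds = t_exons[0]
        cut = 3 * (int(len(cds) * 0.30) // 3)
        scrubbed = _scrub_frame_stops(_rand_dna(rng, 45), 0, rng)
        tail_len = len(cds) - cut - 48
        gene.t_seq = cds[:cut] + scrubbed + "TAA" + _rand_dna(rng, tail_len)
        gene.t_feature_exons = [(0, cut + 48)]
        gene.expected_warning = W_COVERAGE
        return
    if p == "start_non_atg":
        cds = t_exons[0]
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        codons[0] = "ACG"
        for i in range(1, 20):  # no competing in-frame ATG for strategy (b)
            if i < len(codons) and codons[i] == "ATG":
                codons[i] = "ATC"
        t_exons = ["".join(codons)] + t_exons[1:]
        gene.t_seq = gene.cs_seq(t_exons, t_introns)
        gene.t_feature_exons = gene.ref_exon_offsets()
        gene.t_intron_status = "present" if t_introns else "none"
        gene.expected_warning = W_NON_ATG
        return
    if p == "start_shift_to_upstream_atg":
        cds = t_exons[0]
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        codons[0] = "GCC"
        for i in range(1, 20):
            if i < len(codons) and codons[i] == "ATG":
                codons[i] = "ATC"
        t_exons = ["".join(codons)] + t_exons[1:]
        gene.t_seq = gene.cs_seq(t_exons, t_introns)
        gene.t_feature_exons = gene.ref_exon_offsets()
        gene.t_start_ext = 18  # planted ATG + 5 codons upstream (spacer tail)
        gene.t_intron_status = "present" if t_introns else "none"
        return
    # no structured edit (includes short_exon1_gene: structural only)
    gene.t_seq = gene.cs_seq(t_exons, t_introns)
    gene.t_feature_exons = gene.ref_exon_offsets()
    gene.t_intron_status = "present" if t_introns else "none"
    if p == "short_exon1_gene":
        gene.expected_warning = None


#: spacer tail planted upstream of a start-shift gene: in-frame stop, the new
#: start, five non-stop codons
_START_SHIFT_TAIL = "TAA" + "ATG" + "GCTGAAGCTGAAGCT"


# ---------------------------------------------------------------------------
# fixture assembly
# ---------------------------------------------------------------------------


def _element_features(gene: _Gene, base: int, elem_len: int, side: str,
                      copy_index: int = 0, mirror: bool = False):
    """Truth segments of one gene element placed at ``base``.

    ``mirror`` places the reverse-complemented IR copy. Returns
    (segments in reading order, effective strand) or None when the target
    copy has no expected annotation.
    """
    if side == "ref":
        exon_offsets = gene.ref_exon_offsets()
        start_ext = 0
    else:
        if gene.t_feature_exons is None:
            return None
        exon_offsets = gene.t_feature_exons
        start_ext = gene.t_start_ext
    strand = -gene.strand if mirror else gene.strand
    # the element is placed reverse-complemented iff the effective strand
    # is reverse (gene strand XOR mirror)
    segs = []
    for i, (off, ln) in enumerate(exon_offsets):
        a, b = off, off + ln
        if i == 0:
            a -= start_ext
        if strand == FORWARD:
            segs.append((base + a, base + b))
        else:
            segs.append((base + elem_len - b, base + elem_len - a))
    return tuple(segs), strand


def _assemble(elements, side: str) -> tuple[str, list]:
    """Concatenate (kind, payload) elements; returns sequence and per-gene
    placement records (gene, base, elem_len, mirror)."""
    seq_parts: list[str] = []
    placements = []
    pos = 0
    for kind, payload in elements:
        if kind == "spacer":
            s = payload
        elif kind == "gene":
            gene, mirror = payload
            s = gene.ref_seq if side == "ref" else gene.t_seq
            if gene.strand == REVERSE:
                s = revcomp(s)
            if mirror:
                s = revcomp(s)
            placements.append((gene, pos, len(s), mirror))
        else:  # pragma: no cover
            raise ValueError(kind)
        seq_parts.append(s)
        pos += len(s)
    return "".join(seq_parts), placements


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build reference + target records and the truth table for ``spec``."""
    rng = random.Random(spec.seed)

    genes: list[_Gene] = []
    plain_pcgs = []
    for i in range(spec.n_pcg_plain):
        name = _PCG_PLAIN_NAMES[i % len(_PCG_PLAIN_NAMES)] + (
            "" if i < len(_PCG_PLAIN_NAMES) else f"_{i}"
        )
        n_aa = rng.randrange(170, 220) if i == 0 else rng.randrange(100, 220)
        g = _make_pcg(rng, name, n_aa)
        plain_pcgs.append(g)
        genes.append(g)
    intron_pcgs = []
    for i in range(spec.n_pcg_intron):
        name = _PCG_INTRON_NAMES[i % len(_PCG_INTRON_NAMES)] + (
            "" if i < len(_PCG_INTRON_NAMES) else f"_{i}"
        )
        g = _make_intron_pcg(rng, name, rng.randrange(150, 260), spec.intron_style)
        intron_pcgs.append(g)
        genes.append(g)
    for i in range(spec.n_trna_plain):
        name = _TRNA_PLAIN_NAMES[i % len(_TRNA_PLAIN_NAMES)] + (
            "" if i < len(_TRNA_PLAIN_NAMES) else f"_{i}"
        )
        genes.append(_make_rna(rng, name, "tRNA", rng.randrange(70, 90)))
    for i in range(spec.n_trna_intron):
        name = _TRNA_INTRON_NAMES[i % len(_TRNA_INTRON_NAMES)] + (
            "" if i < len(_TRNA_INTRON_NAMES) else f"_{i}"
        )
        genes.append(_make_intron_trna(rng, name))
    rrnas = []
    for i in range(spec.n_rrna):
        name = _RRNA_NAMES[i % len(_RRNA_NAMES)] + (
            "" if i < len(_RRNA_NAMES) else f"_{i}"
        )
        g = _make_rna(rng, name, "rRNA", rng.randrange(400, 700))
        rrnas.append(g)
        genes.append(g)
    if "short_exon1_gene" in spec.perturbations:
        g = _make_intron_pcg(rng, "rpl16", rng.randrange(120, 180),
                             spec.intron_style, short_exon1=True)
        g.perturbation = "short_exon1_gene"
        genes.append(g)

    # assign the remaining perturbations to distinct suitable genes
    plain_iter = iter(plain_pcgs)
    for p in spec.perturbations:
        if p == "short_exon1_gene":
            continue
        if p == "intron_loss":
            if not intron_pcgs:
                raise ValueError("intron_loss perturbation needs an intron PCG")
            target_gene = intron_pcgs[0]
        elif p == "truncate_gene":
            target_gene = plain_pcgs[0]
        else:
            target_gene = next(
                (g for g in plain_iter if g.perturbation is None and
                 g is not plain_pcgs[0]),
                None,
            )
            if target_gene is None:
                raise ValueError(f"not enough plain PCGs for perturbation {p}")
        if target_gene.perturbation is not None:
            raise ValueError(f"gene {target_gene.name} already perturbed")
        target_gene.perturbation = p

    # strands: random, except perturbed genes stay forward (their upstream
    # edits live in the preceding spacer) and rRNAs vary inside the IR
    for g in genes:
        if g.perturbation is None:
            g.strand = rng.choice((FORWARD, REVERSE))
        else:
            g.strand = FORWARD

    # region assignment: rRNAs (and one plain tRNA if spare) go into the IR,
    # last non-perturbed gene into the SSC, the rest into the LSC
    ir_genes: list[_Gene] = list(rrnas)
    spare_trnas = [g for g in genes if g.category == "tRNA"
                   and not g.introns and g.perturbation is None]
    if spec.ir_length and spare_trnas:
        ir_genes.append(spare_trnas[-1])
    if not spec.ir_length:
        ir_genes = []
    for g in ir_genes:
        g.region = "ir"
    ssc_pool = [g for g in genes if g.region == "lsc" and g.perturbation is None]
    ssc_genes = ssc_pool[-1:] if ssc_pool else []
    for g in ssc_genes:
        g.region = "ssc"
    lsc_genes = [g for g in genes if g.region == "lsc"]

    def block(block_genes: list[_Gene], mirror_all: bool = False):
        elems: list = []
        for g in block_genes:
            elems.append(("spacer", _rand_dna(rng, rng.randrange(150, 350))))
            elems.append(("gene", (g, mirror_all)))
        elems.append(("spacer", _rand_dna(rng, rng.randrange(150, 350))))
        return elems

    lsc_elems = block(lsc_genes)
    ira_elems = block(ir_genes) if ir_genes else []
    ssc_elems = block(ssc_genes)

    # pad the IR block to exactly ir_length
    if ira_elems:
        content = sum(
            len(p) if k == "spacer" else len(p[0].ref_seq)
            for k, p in ira_elems
        )
        if content > spec.ir_length:
            raise ValueError(
                f"ir_length {spec.ir_length} too small for the IR gene block "
                f"({content} nt)"
            )
        ira_elems.append(("spacer", _rand_dna(rng, spec.ir_length - content)))

    # --- target-side realization -------------------------------------------
    t_rng = random.Random(spec.seed + 0x5F5E1)
    for g in genes:
        protected: list[tuple[int, int]] = []
        if g.perturbation == "short_exon1_gene":
            protected = [(0, 9)]  # the invariant first exon
        mutated = _mutate(g.ref_seq, t_rng, spec.divergence, protected)
        # re-split into exons/introns at the reference offsets
        t_exons, t_introns, pos = [], [], 0
        for i, exon in enumerate(g.exons):
            t_exons.append(mutated[pos : pos + len(exon)])
            pos += len(exon)
            if i < len(g.introns):
                t_introns.append(mutated[pos : pos + len(g.introns[i])])
                pos += len(g.introns[i])
        if g.perturbation == "short_exon1_gene" and t_introns:
            while _SHORT_EXON1_SEQ in t_introns[0]:
                t_introns[0] = t_introns[0].replace(
                    _SHORT_EXON1_SEQ, _rand_dna(t_rng, 9), 1
                )
        _apply_perturbation(g, t_rng, t_exons, t_introns)

    def target_elements(elems):
        out = []
        for idx, (kind, payload) in enumerate(elems):
            if kind == "spacer":
                out.append(["spacer", _mutate(payload, t_rng, spec.divergence)])
            else:
                out.append([kind, payload])
        # upstream spacer edits for start perturbations (forward genes only)
        for idx, (kind, payload) in enumerate(out):
            if kind != "gene":
                continue
            g, _mir = payload
            if g.perturbation == "start_non_atg":
                sp = out[idx - 1][1]
                out[idx - 1][1] = sp[:-3] + "TAA"
            elif g.perturbation == "start_shift_to_upstream_atg":
                sp = out[idx - 1][1]
                out[idx - 1][1] = sp[: -len(_START_SHIFT_TAIL)] + _START_SHIFT_TAIL
        return [tuple(e) for e in out]

    t_lsc, t_ira, t_ssc = (
        target_elements(lsc_elems),
        target_elements(ira_elems),
        target_elements(ssc_elems),
    )

    def build(side: str, lsc, ira, ssc):
        seq_lsc, pl_lsc = _assemble(lsc, side)
        seq_ira, pl_ira = _assemble(ira, side)
        seq_ssc, pl_ssc = _assemble(ssc, side)
        seq_irb = revcomp(seq_ira)
        offsets = {
            "lsc": 0,
            "ira": len(seq_lsc),
            "ssc": len(seq_lsc) + len(seq_ira),
            "irb": len(seq_lsc) + len(seq_ira) + len(seq_ssc),
        }
        genome = seq_lsc + seq_ira + seq_ssc + seq_irb
        truth: list[TruthEntry] = []

        def emit(gene, base, elem_len, mirror, copy_index):
            res = _element_features(gene, base, elem_len, side, copy_index, mirror)
            if res is None:
                segs = None
                strand = gene.strand
            else:
                segs, strand = res
            intron_status = (
                ("present" if gene.introns else "none")
                if side == "ref"
                else gene.t_intron_status
            )
            expected = "annotated" if side == "ref" else gene.expected
            warning = None if side == "ref" else gene.expected_warning
            if segs is None:
                a, b = base, base + elem_len
                segs = ((a, b),)
            truth.append(
                TruthEntry(
                    gene_name=gene.name,
                    category=gene.category,
                    copy_index=copy_index,
                    strand=strand,
                    segments=segs,
                    intron_status=intron_status,
                    start_codon=(gene.exons[0][:3] if gene.category == "PCG"
                                 else None),
                    expected=expected,
                    expected_warning=warning,
                    perturbation=gene.perturbation if side != "ref" else None,
                )
            )

        for gene, base, elem_len, mirror in pl_lsc:
            emit(gene, base, elem_len, mirror, 0)
        for gene, base, elem_len, mirror in pl_ira:
            emit(gene, offsets["ira"] + base, elem_len, mirror, 0)
        for gene, base, elem_len, mirror in pl_ssc:
            emit(gene, offsets["ssc"] + base, elem_len, mirror, 0)
        # IRb: mirrored copies of the IRa genes
        for gene, base, elem_len, mirror in pl_ira:
            mirrored_base = offsets["irb"] + (len(seq_ira) - base - elem_len)
            emit(gene, mirrored_base, elem_len, not mirror, 1)
        ir = None
        if seq_ira:
            ir = (
                (offsets["ira"], offsets["ira"] + len(seq_ira)),
                (offsets["irb"], offsets["irb"] + len(seq_irb)),
            )
        return genome, truth, ir

    ref_seq, ref_truth, ref_ir = build("ref", lsc_elems, ira_elems, ssc_elems)
    tgt_seq, tgt_truth, tgt_ir = build("target", t_lsc, t_ira, t_ssc)

    reference = PlastomeRecord(
        record_id=f"ref_fixture_{spec.seed}", sequence=ref_seq
    )
    kind_by_category = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    for e in ref_truth:
        loc = FeatureLocation(e.segments, e.strand)
        reference.features.append(
            GeneFeature(e.gene_name, "gene",
                        FeatureLocation((loc.span,), e.strand),
                        {"gene": e.gene_name})
        )
        reference.features.append(
            GeneFeature(e.gene_name, kind_by_category[e.category], loc,
                        {"gene": e.gene_name})
        )
    target = PlastomeRecord(
        record_id=f"target_fixture_{spec.seed}", sequence=tgt_seq
    )
    return Fixture(
        spec=spec,
        reference=reference,
        target=target,
        truth=tgt_truth,
        reference_truth=ref_truth,
        ir=tgt_ir,
    )


def write_fixture(spec: FixtureSpec, directory: str | Path):
    """Materialize a fixture on disk: reference GenBank, target FASTA and a
    tab-separated truth table. Returns the three paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fx = generate_fixture(spec)
    anns = []
    for e in fx.reference_truth:
        anns.append(
            GeneAnnotation(
                gene_name=e.gene_name,
                category=e.category,
                copy_index=e.copy_index,
                location=FeatureLocation(e.segments, e.strand),
                source_reference=fx.reference.record_id,
                reference_length=sum(b - a for a, b in e.segments),
            )
        )
    ref_path = directory / "reference.gb"
    target_path = directory / "target.fasta"
    truth_path = directory / "truth.tsv"
    write_genbank(fx.reference, anns, ref_path)
    write_fasta(fx.target, target_path)
    with open(truth_path, "w") as fh:
        fh.write("gene\tcategory\tcopy\tstrand\tsegments\tintron_status\t"
                 "expected\texpected_warning\tperturbation\n")
        for e in fx.truth:
            segs = ",".join(f"{a}-{b}" for a, b in e.segments)
            fh.write(
                f"{e.gene_name}\t{e.category}\t{e.copy_index}\t{e.strand}\t"
                f"{segs}\t{e.intron_status}\t{e.expected}\t"
                f"{e.expected_warning or '.'}\t{e.perturbation or '.'}\n"
            )
    return ref_path, target_path, truth_path


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_against_truth(annotations: Sequence[GeneAnnotation],
                        truth: Sequence[TruthEntry]) -> dict[str, int]:
    """Count missing / wrong / wrong-boundary / correct annotations.

    Gene-level counts (MG/WG/WGB/CG) apply to single-exon truth entries,
    exon-level counts (ME/WE/WEB/CE) to intron-containing ones. An
    annotation overlapping no truth locus is wrong (WG or WE); one
    overlapping a locus with exact segment agreement is correct; an overlap
    with any boundary mismatch counts as a wrong boundary.
    """
    counts = dict.fromkeys(("MG", "WG", "WGB", "CG", "ME", "WE", "WEB", "CE"), 0)
    used: set[int] = set()

    def overlaps(seg1, seg2) -> bool:
        return seg1[0] < seg2[1] and seg2[0] < seg1[1]

    for entry in truth:
        exon_level = len(entry.segments) > 1 or entry.intron_status == "present"
        candidates = [
            (i, ann)
            for i, ann in enumerate(annotations)
            if i not in used
            and ann.gene_name == entry.gene_name
            and ann.location.strand == entry.strand
            and overlaps(ann.location.span,
                         (min(a for a, _ in entry.segments),
                          max(b for _, b in entry.segments)))
        ]
        if entry.expected != "annotated":
            for i, _ in candidates:
                used.add(i)
                counts["WG"] += 1  # spurious annotation at a dead locus
            continue
        if not candidates:
            counts["ME" if exon_level else "MG"] += len(entry.segments) if exon_level else 1
            continue
        i, ann = max(
            candidates,
            key=lambda ia: sum(
                min(b, tb) - max(a, ta)
                for a, b in ia[1].location.segments
                for ta, tb in entry.segments
                if overlaps((a, b), (ta, tb))
            ),
        )
        used.add(i)
        if exon_level:
            ann_segs = list(ann.location.segments)
            for tseg in entry.segments:
                match = [s for s in ann_segs if overlaps(s, tseg)]
                if not match:
                    counts["ME"] += 1
                elif any(s == tseg for s in match):
                    counts["CE"] += 1
                else:
                    counts["WEB"] += 1
            for s in ann_segs:
                if not any(overlaps(s, tseg) for tseg in entry.segments):
                    counts["WE"] += 1
        else:
            if tuple(ann.location.segments) == tuple(entry.segments):
                counts["CG"] += 1
            else:
                counts["WGB"] += 1
    for i, ann in enumerate(annotations):
        if i not in used:
            if len(ann.location.segments) > 1:
                counts["WE"] += len(ann.location.segments)
            else:
                counts["WG"] += 1
    return counts


def perturbation_recovered(entry: TruthEntry,
                           annotations: Sequence[GeneAnnotation],
                           log: TargetLog) -> bool:
    """Did the pipeline classify this perturbed gene copy as intended?"""
    p = entry.perturbation
    anns = [a for a in annotations if a.gene_name == entry.gene_name]
    logged = {t for t, msg in log.warnings if entry.gene_name in msg}
    if p == "intron_loss":
        return (
            W_INTRON_LOSS in logged
            and any(len(a.location.segments) == 1 for a in anns)
        )
    if p == "start_non_atg":
        return any(
            a.start_strategy in ("c", "d") and a.start_codon != "ATG"
            for a in anns
        ) and W_NON_ATG in logged
    if p == "start_shift_to_upstream_atg":
        return any(
            a.location.segments[0][0] == entry.segments[0][0]
            and a.start_strategy == "b"
            for a in anns
        )
    if p == "truncate_gene":
        return W_COVERAGE in logged and any(
            "low" in msg for t, msg in log.warnings
            if t == W_COVERAGE and entry.gene_name in msg
        )
    if p == "delete_gene":
        return entry.gene_name in log.missing_gene_names and not anns
    if p == "mutate_below_threshold":
        return entry.gene_name in {s.gene_name for s in log.skipped}
    if p == "short_exon1_gene":
        exon1_truth = entry.segments[0]
        return any(
            len(a.location.segments) == 2 and a.location.segments[0] == exon1_truth
            for a in anns
        )
    raise ValueError(f"unknown perturbation {p!r}")
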