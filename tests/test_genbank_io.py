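"""GenBank parsing, feature extraction, validation and round-trip writing."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from plastann._seq import revcomp
from plastann.genbank_io import (
    FORWARD,
    REVERSE,
    FeatureLocation,
    GenBankParseError,
    PlastomeRecord,
    extract_feature_sequence,
    parse_genbank,
    read_fasta_target,
    validate_reference,
    write_genbank,
)
from plastann.pipeline import GeneAnnotation


def _feat(record, name, kind):
    return next(
        f for f in record.features if f.gene_name == name and f.kind == kind
    )


class TestParse:
    def test_join_location_converts_to_zero_based(self, toy_genbank):
        rec = parse_genbank(toy_genbank)
        cds = _feat(rec, "psbX", "CDS")
        assert cds.location.segments == ((9, 18), (100, 190))
        assert cds.location.strand == FORWARD

    def test_complement_location(self, toy_genbank):
        rec = parse_genbank(toy_genbank)
        trna = _feat(rec, "trnX-AAA", "tRNA")
        assert trna.location.segments == ((49, 130),)
        assert trna.location.strand == REVERSE

    def test_complement_join_extraction_matches_manual_slicing(
        self, toy_genbank, toy_seq
    ):
        rec = parse_genbank(toy_genbank)
        cds = _feat(rec, "ycfX", "CDS")
        expected = revcomp(toy_seq[199:300] + toy_seq[399:406])
        assert extract_feature_sequence(rec, cds.location) == expected

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "bad.gb"
        bad.write_text("this is not a genbank file\n")
        with pytest.raises(GenBankParseError):
            parse_genbank(bad)

    def test_fuzzy_location_recorded_not_crashed(self, tmp_path, toy_seq):
        from conftest import _fline, _genbank_text, _qline

        features = [
            _fline("CDS", "<10..190"),
            _qline('/gene="psbF"'),
        ]
        path = tmp_path / "fuzzy.gb"
        path.write_text(_genbank_text(toy_seq, features))
        rec = parse_genbank(path)
        assert not rec.features
        assert any("fuzzy" in i for i in rec.issues)


class TestExtract:
    def test_forward_and_reverse_single_segment(self):
        rec = PlastomeRecord("r", "ATGCAAAA")
        fwd = FeatureLocation(((0, 3),), FORWARD)
        rev = FeatureLocation(((0, 3),), REVERSE)
        assert extract_feature_sequence(rec, fwd) == "ATG"
        assert extract_feature_sequence(rec, rev) == "CAT"

    def test_out_of_bounds_raises(self):
        rec = PlastomeRecord("r", "ATGC")
        with pytest.raises(IndexError):
            extract_feature_sequence(rec, FeatureLocation(((2, 9),), FORWARD))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_strand_symmetry(self, seed):
        """Extracting on the reverse strand equals the reverse complement of
        the forward extraction read exon-last."""
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        rec = PlastomeRecord("r", seq)
        a = rng.randrange(0, 100)
        b = a + rng.randrange(5, 50)
        c = b + rng.randrange(1, 50)
        d = c + rng.randrange(5, 50)
        fwd = FeatureLocation(((a, b), (c, d)), FORWARD)
        rev = FeatureLocation(((c, d), (a, b)), REVERSE)
        assert extract_feature_sequence(rec, rev) == revcomp(
            extract_feature_sequence(rec, fwd)
        )


class TestValidate:
    def test_clean_reference_has_no_issues(self, gold_fixture):
        assert validate_reference(gold_fixture.reference) == []

    def test_missing_gene_qualifier_reported(self, toy_genbank):
        rec = parse_genbank(toy_genbank)
        trna = _feat(rec, "trnX-AAA", "tRNA")
        trna.gene_name = ""
        issues = validate_reference(rec)
        missing = [i for i in issues if "missing /gene" in i]
        assert len(missing) == 1 and "tRNA" in missing[0]

    def test_cds_frame_issue(self, toy_seq):
        rec = PlastomeRecord("r", toy_seq)
        from plastann.genbank_io import GeneFeature

        rec.features.append(
            GeneFeature("badC", "CDS", FeatureLocation(((0, 100),), FORWARD))
        )
        assert any("not a multiple of 3" in i for i in validate_reference(rec))


class TestRoundTrip:
    def test_write_then_parse_is_identity_on_features(self, tmp_path, gold_fixture):
        rec = gold_fixture.reference
        anns = [
            GeneAnnotation(
                gene_name=e.gene_name,
                category=e.category,
                copy_index=e.copy_index,
                location=FeatureLocation(e.segments, e.strand),
                source_reference="ref",
                reference_length=1,
            )
            for e in gold_fixture.reference_truth
        ]
        out = tmp_path / "out.gb"
        write_genbank(rec, anns, out)
        back = parse_genbank(out)
        want = sorted(
            (a.gene_name, a.location.segments, a.location.strand) for a in anns
        )
        got = sorted(
            (f.gene_name, f.location.segments, f.location.strand)
            for f in back.features
            if f.kind in ("CDS", "tRNA", "rRNA")
        )
        assert got == want

    def test_multi_exon_written_as_join(self, tmp_path):
        seq = "A" * 250
        rec = PlastomeRecord("r", seq)
        ann = GeneAnnotation(
            gene_name="g1",
            category="PCG",
            copy_index=0,
            location=FeatureLocation(((9, 18), (100, 190)), FORWARD),
            source_reference="ref",
            reference_length=99,
        )
        out = tmp_path / "j.gb"
        write_genbank(rec, [ann], out)
        text = out.read_text()
        assert "join(10..18,101..190)" in text

    def test_single_segment_written_without_join(self, tmp_path):
        rec = PlastomeRecord("r", "A" * 100)
        ann = GeneAnnotation(
            gene_name="g1",
            category="PCG",
            copy_index=0,
            location=FeatureLocation(((9, 90),), FORWARD),
            source_reference="ref",
            reference_length=81,
        )
        out = tmp_path / "s.gb"
        write_genbank(rec, [ann], out)
        assert "join" not in out.read_text()


class TestFasta:
    def test_single_sequence_required(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(GenBankParseError):
            read_fasta_target(p)

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">a\nacgtACGT\n")
        assert read_fasta_target(p).sequence == "ACGTACGT"
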