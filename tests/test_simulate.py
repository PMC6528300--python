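"""The fixture generator itself: validity, determinism, truth bookkeeping."""

import pytest

from plastann._seq import STOP_CODONS, revcomp, translate
from plastann.genbank_io import extract_feature_sequence, validate_reference
from plastann.pipeline import GeneAnnotation
from plastann.genbank_io import FeatureLocation
from plastann.simulate import (
    FixtureSpec,
    generate_fixture,
    score_against_truth,
    write_fixture,
)


class TestGeneratedReferences:
    def test_references_pass_validation(self):
        for seed in (0, 1, 2):
            fx = generate_fixture(FixtureSpec(seed=seed))
            assert validate_reference(fx.reference) == []

    def test_divergence_zero_means_identical_sequences(self):
        fx = generate_fixture(FixtureSpec(seed=4))
        assert fx.target.sequence == fx.reference.sequence
        assert [e.segments for e in fx.truth] == [
            e.segments for e in fx.reference_truth
        ]

    def test_cds_features_are_clean_orfs(self):
        fx = generate_fixture(FixtureSpec(seed=5))
        for feat in fx.reference.features:
            if feat.kind != "CDS":
                continue
            nt = extract_feature_sequence(fx.reference, feat.location)
            assert nt[:3] == "ATG"
            assert nt[-3:] in STOP_CODONS
            aa = translate(nt)
            assert "*" not in aa[:-1]

    def test_ir_copies_are_reverse_complements(self):
        fx = generate_fixture(FixtureSpec(seed=6))
        (a1, b1), (a2, b2) = fx.ir
        seq = fx.target.sequence
        assert b1 - a1 == b2 - a2 == fx.spec.ir_length
        assert seq[a1:b1] == revcomp(seq[a2:b2])

    def test_fixed_seed_reproduces_byte_identical_files(self, tmp_path):
        p1 = write_fixture(FixtureSpec(seed=9), tmp_path / "a")
        p2 = write_fixture(FixtureSpec(seed=9), tmp_path / "b")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FixtureSpec(divergence=0.9)
        with pytest.raises(ValueError):
            FixtureSpec(perturbations=("no_such_thing",))
        with pytest.raises(ValueError):
            generate_fixture(FixtureSpec(ir_length=100))  # too small for genes


class TestPerturbationConstruction:
    def test_intron_loss_removes_intron_from_target(self):
        fx = generate_fixture(FixtureSpec(seed=10, perturbations=("intron_loss",)))
        e = next(t for t in fx.truth if t.perturbation == "intron_loss")
        assert e.intron_status == "lost"
        assert len(e.segments) == 1
        ref_e = next(
            t for t in fx.reference_truth if t.gene_name == e.gene_name
        )
        assert len(ref_e.segments) == 2
        # the joined exons read as one clean ORF in the target
        a, b = e.segments[0]
        nt = fx.target.sequence[a:b] if e.strand == 1 else revcomp(
            fx.target.sequence[a:b]
        )
        assert "*" not in translate(nt)[:-1]

    def test_start_non_atg_plants_acg(self):
        fx = generate_fixture(FixtureSpec(seed=11, perturbations=("start_non_atg",)))
        e = next(t for t in fx.truth if t.perturbation == "start_non_atg")
        a, _ = e.segments[0]
        assert fx.target.sequence[a : a + 3] == "ACG"
        assert fx.target.sequence[a - 3 : a] == "TAA"  # adjacent in-frame stop

    def test_truth_start_shift_extends_upstream(self):
        fx = generate_fixture(
            FixtureSpec(seed=12, perturbations=("start_shift_to_upstream_atg",))
        )
        e = next(
            t for t in fx.truth if t.perturbation == "start_shift_to_upstream_atg"
        )
        ref_e = next(t for t in fx.reference_truth if t.gene_name == e.gene_name)
        assert e.segments[0][0] == ref_e.segments[0][0] - 18
        assert fx.target.sequence[e.segments[0][0] :][:3] == "ATG"

    def test_short_exon1_structure(self):
        fx = generate_fixture(
            FixtureSpec(seed=13, perturbations=("short_exon1_gene",))
        )
        e = next(t for t in fx.truth if t.perturbation == "short_exon1_gene")
        assert len(e.segments) == 2
        a, b = e.segments[0]
        assert b - a == 9
        assert fx.target.sequence[a:b] == "ATGCTTAGC"


class TestScoring:
    def _ann(self, entry):
        return GeneAnnotation(
            gene_name=entry.gene_name,
            category=entry.category,
            copy_index=entry.copy_index,
            location=FeatureLocation(entry.segments, entry.strand),
            source_reference="r",
            reference_length=sum(b - a for a, b in entry.segments),
        )

    def test_perfect_annotation_scores_all_correct(self):
        fx = generate_fixture(FixtureSpec(seed=14))
        anns = [self._ann(e) for e in fx.truth]
        c = score_against_truth(anns, fx.truth)
        assert c["MG"] == c["WG"] == c["WGB"] == 0
        assert c["ME"] == c["WE"] == c["WEB"] == 0
        n_single = sum(1 for e in fx.truth if len(e.segments) == 1)
        n_exons = sum(len(e.segments) for e in fx.truth if len(e.segments) > 1)
        assert c["CG"] == n_single and c["CE"] == n_exons

    def test_boundary_off_by_three_counts_wrong_boundary(self):
        fx = generate_fixture(FixtureSpec(seed=14))
        anns = [self._ann(e) for e in fx.truth]
        single = next(
            i for i, a in enumerate(anns) if len(a.location.segments) == 1
        )
        (a, b), s = anns[single].location.segments[0], anns[single].location.strand
        anns[single].location = FeatureLocation(((a + 3, b),), s)
        c = score_against_truth(anns, fx.truth)
        assert c["WGB"] == 1

    def test_spurious_annotation_counts_wrong_gene(self):
        fx = generate_fixture(FixtureSpec(seed=15, perturbations=("delete_gene",)))
        dead = next(e for e in fx.truth if e.expected == "missing")
        anns = [self._ann(e) for e in fx.truth if e.expected == "annotated"]
        anns.append(self._ann(dead))  # annotate the deleted locus anyway
        c = score_against_truth(anns, fx.truth)
        assert c["WG"] == 1

    def test_missing_gene_counted(self):
        fx = generate_fixture(FixtureSpec(seed=14))
        anns = [
            self._ann(e) for e in fx.truth if len(e.segments) == 1
        ][:-1]  # drop one single-exon gene
        c = score_against_truth(anns, fx.truth)
        assert c["MG"] == 1
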