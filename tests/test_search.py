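"""Homology-search backends and best-hit selection."""

import random

import pytest

from plastann._seq import revcomp, translate
from plastann.genbank_io import FORWARD, REVERSE, PlastomeRecord
from plastann.reference_db import ReferenceGeneEntry, build_reference_db
from plastann.search import (
    BlastBackend,
    BuiltinBackend,
    Hsp,
    SearchConfig,
    select_best_hits,
)
from plastann.simulate import FixtureSpec, generate_fixture


def _entry(name, nt, ref="refA", exons=None):
    return ReferenceGeneEntry(
        gene_name=name,
        category="tRNA",
        nt_sequence=nt,
        exon_lengths=tuple(exons or (len(nt),)),
        source_record=ref,
    )


def _rand(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def cfg():
    return SearchConfig()


class TestBuiltinNucleotide:
    def test_exact_substring_hit(self, cfg):
        rng = random.Random(0)
        query = _rand(rng, 120)
        subject = _rand(rng, 1000) + query + _rand(rng, 1000)
        target = PlastomeRecord("t", subject)
        hits = BuiltinBackend().search_nucleotide([_entry("g", query)], target, cfg)
        exact = [h for h in hits if h.percent_identity == 100.0]
        assert len(exact) == 1
        h = exact[0]
        assert (h.s_start, h.s_end, h.strand) == (1000, 1120, FORWARD)
        assert (h.q_start, h.q_end) == (0, 120)

    def test_reverse_complement_hit(self, cfg):
        rng = random.Random(1)
        query = _rand(rng, 120)
        subject = _rand(rng, 500) + revcomp(query) + _rand(rng, 500)
        target = PlastomeRecord("t", subject)
        hits = BuiltinBackend().search_nucleotide([_entry("g", query)], target, cfg)
        exact = [h for h in hits if h.percent_identity == 100.0]
        assert len(exact) == 1
        h = exact[0]
        assert (h.s_start, h.s_end, h.strand) == (500, 620, REVERSE)

    def test_substitution_identity_matches_direct_count(self, cfg):
        rng = random.Random(2)
        query = _rand(rng, 100)
        mutated = list(query)
        for pos in rng.sample(range(10, 90), 5):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        subject = _rand(rng, 400) + "".join(mutated) + _rand(rng, 400)
        target = PlastomeRecord("t", subject)
        hits = BuiltinBackend().search_nucleotide([_entry("g", query)], target, cfg)
        best = max(hits, key=lambda h: h.aligned_length)
        # ungapped aligner: identity over the full span is exactly 95%
        assert best.percent_identity == pytest.approx(95.0, abs=1.0)


class TestBuiltinProtein:
    def test_forward_frame_and_coordinates(self, cfg):
        rng = random.Random(3)
        cds = "ATG" + "".join(
            rng.choice(["GCT", "GAA", "CTT", "AAA", "TTT"]) for _ in range(60)
        )
        peptide = translate(cds)
        for offset in (0, 1, 2):
            subject = _rand(rng, 300 + offset) + cds + _rand(rng, 300)
            target = PlastomeRecord("t", subject)
            entry = ReferenceGeneEntry(
                gene_name="g", category="PCG", nt_sequence=cds,
                exon_lengths=(len(cds),), source_record="r",
                aa_sequence=peptide,
            )
            hits = BuiltinBackend().search_protein([entry], target, cfg)
            best = max(hits, key=lambda h: h.aligned_length)
            assert best.percent_identity == 100.0
            assert best.s_start == 300 + offset
            assert best.frame == best.s_start % 3

    def test_reverse_strand_maps_to_forward_axis(self, cfg):
        rng = random.Random(4)
        cds = "ATG" + "".join(
            rng.choice(["GCT", "GAA", "CTT", "AAA", "TTT"]) for _ in range(60)
        )
        subject = _rand(rng, 300) + revcomp(cds) + _rand(rng, 300)
        target = PlastomeRecord("t", subject)
        entry = ReferenceGeneEntry(
            gene_name="g", category="PCG", nt_sequence=cds,
            exon_lengths=(len(cds),), source_record="r",
            aa_sequence=translate(cds),
        )
        hits = BuiltinBackend().search_protein([entry], target, cfg)
        best = max(hits, key=lambda h: h.aligned_length)
        assert best.strand == REVERSE
        assert (best.s_start, best.s_end) == (300, 300 + len(cds))

    def test_coordinate_sanity_extraction_realigns(self, cfg, gold_fixture, gold_db):
        """Extracting any reported subject interval and translating it in the
        reported frame recovers at least the reported identity (minus slack)."""
        target = gold_fixture.target
        hits = BuiltinBackend().search_protein(
            gold_db.cds_aa_intronless, target, cfg
        )
        for h in hits:
            if h.percent_identity < 60:
                continue
            cs = (
                target.sequence
                if h.strand == FORWARD
                else revcomp(target.sequence)
            )
            a, b = h.cs_interval(target.length)
            got = translate(cs[a:b])
            want = h.entry.aa_sequence[h.q_start : h.q_end]
            matches = sum(x == y for x, y in zip(got, want))
            assert 100.0 * matches / len(want) >= h.percent_identity - 5


class TestSelection:
    def _hsp(self, gene, ref, ident, length, s=0, strand=FORWARD, entry=None):
        return Hsp(
            gene_name=gene, reference_id=ref, mode="nucleotide",
            q_start=0, q_end=length, s_start=s, s_end=s + length,
            strand=strand, frame=0, percent_identity=ident,
            aligned_length=length, entry=entry,
        )

    def test_best_reference_wins(self):
        e1 = _entry("X", "A" * 100, ref="ref1")
        e2 = _entry("X", "C" * 100, ref="ref2")
        hsps = [
            self._hsp("X", "ref1", 98.0, 100, s=0, entry=e1),
            self._hsp("X", "ref2", 91.0, 100, s=0, entry=e2),
        ]
        sel = select_best_hits(hsps, entry_order=[e1, e2])
        kept = [h for c in sel["X"] for h in c]
        assert all(h.reference_id == "ref1" for h in kept)

    def test_single_hsp_single_cluster(self):
        e = _entry("Y", "A" * 50)
        sel = select_best_hits([self._hsp("Y", "refA", 99.0, 50, entry=e)])
        assert len(sel["Y"]) == 1 and len(sel["Y"][0]) == 1

    def test_ir_duplicated_gene_yields_two_clusters(self, gold_fixture, gold_db):
        rrna = [e for e in gold_db.rna_nt if e.category == "rRNA"][0]
        hits = BuiltinBackend().search_nucleotide(
            [rrna], gold_fixture.target, SearchConfig()
        )
        sel = select_best_hits(hits, entry_order=[rrna])
        clusters = sel[rrna.gene_name]
        assert len(clusters) == 2
        strands = {c[0].strand for c in clusters}
        assert strands == {FORWARD, REVERSE}  # mirrored IR copies
        truth = sorted(
            e.segments[0]
            for e in gold_fixture.truth
            if e.gene_name == rrna.gene_name
        )
        got = sorted(
            (min(h.s_start for h in c), max(h.s_end for h in c)) for c in clusters
        )
        assert got == truth


class TestBackendEquivalence:
    def test_blast_and_builtin_agree_on_cluster_intervals(self):
        """On a diverged fixture both backends pick the same loci
        (per-cluster subject intervals overlap with Jaccard >= 0.9)."""
        fx = generate_fixture(FixtureSpec(seed=2, divergence=0.03))
        db = build_reference_db([fx.reference])
        cfg = SearchConfig()
        blast, builtin = BlastBackend(), BuiltinBackend()
        b_hits = blast.search_nucleotide(db.rna_nt, fx.target, cfg)
        b_hits += blast.search_protein(db.pcg_aa, fx.target, cfg)
        i_hits = builtin.search_nucleotide(db.rna_nt, fx.target, cfg)
        i_hits += builtin.search_protein(db.pcg_aa, fx.target, cfg)

        def spans(hits):
            sel = select_best_hits(hits)
            return {
                g: sorted(
                    (min(h.s_start for h in c), max(h.s_end for h in c))
                    for c in cl
                )
                for g, cl in sel.items()
            }

        bs, is_ = spans(b_hits), spans(i_hits)
        assert set(bs) == set(is_)
        for gene in is_:
            for (a0, a1), (b0, b1) in zip(is_[gene], bs[gene]):
                inter = max(0, min(a1, b1) - max(a0, b0))
                union = max(a1, b1) - min(a0, b0)
                assert inter / union >= 0.9, gene
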