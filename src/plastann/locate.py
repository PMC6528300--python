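"""Turn per-gene HSP clusters into preliminary gene loci.

Includes the dedicated upstream probe search for genes whose first exon is
too short for the similarity search to see (rpl16 / petB / petD, first exons
of 6-9 nt): the reference exon-1 sequence is matched exactly on the coding
strand within a window upstream of the located exon 2, and the match closest
to exon 2 wins. These first exons are essentially invariant across
angiosperms, which is what justifies mismatch-free matching (one mismatch
can be allowed explicitly).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .genbank_io import PlastomeRecord
from .reference_db import ReferenceDatabase, ReferenceGeneEntry
from .search import (
    Hsp,
    SearchConfig,
    get_backend,
    select_best_hits,
)

#: a reference first exon at or below this length cannot be found by the
#: similarity search and triggers the upstream exact-probe rescue
SHORT_EXON1_MAX_NT = 12

DEFAULT_EXON1_WINDOW_NT = 2000


@dataclasses.dataclass
class PreliminaryLocus:
    gene_name: str
    category: str
    strand: int
    hsp_cluster: list[Hsp]  # ordered HSP1, HSP2, ... by query position
    copy_index: int
    reference_entry: ReferenceGeneEntry

    def __post_init__(self) -> None:
        if not self.hsp_cluster:
            raise ValueError("locus needs at least one HSP")
        if any(h.strand != self.strand for h in self.hsp_cluster):
            raise ValueError("all HSPs of a locus must share a strand")


@dataclasses.dataclass
class SkippedGene:
    gene_name: str
    best_identity: float


def locate_genes(
    db: ReferenceDatabase,
    target: PlastomeRecord,
    cfg: SearchConfig | None = None,
) -> tuple[list[PreliminaryLocus], list[SkippedGene], list[str]]:
    """Search, select best reference hits, and build per-copy loci.

    Protein-coding genes whose best percent identity falls below the
    configured threshold (default 40%) are put on the skipped list with
    their identity for the log; genes with no hit at all are reported
    missing.
    """
    cfg = cfg or SearchConfig()
    backend = get_backend(cfg)
    nt_hits = backend.search_nucleotide(db.rna_nt, target, cfg) if db.rna_nt else []
    aa_hits = backend.search_protein(db.pcg_aa, target, cfg) if db.pcg_aa else []

    loci: list[PreliminaryLocus] = []
    skipped: list[SkippedGene] = []
    located: set[str] = set()

    def significant(cluster: list[Hsp]) -> bool:
        # a stray short hit is not a gene: require either a quarter of the
        # query covered or a substantial absolute aligned length
        entry = cluster[0].entry
        qlen = (
            len(entry.aa_sequence) if cluster[0].mode == "protein"
            else len(entry.nt_sequence)
        )
        aligned = sum(h.aligned_length for h in cluster)
        return aligned >= 0.25 * qlen or aligned >= 30

    rna_clusters = select_best_hits(nt_hits, cfg.max_intron_span, db.rna_nt)
    rna_clusters = {
        g: [c for c in cl if significant(c)] for g, cl in rna_clusters.items()
    }
    for gene, clusters in rna_clusters.items():
        for ci, cluster in enumerate(clusters):
            entry = cluster[0].entry
            loci.append(
                PreliminaryLocus(
                    gene_name=gene,
                    category=entry.category,
                    strand=cluster[0].strand,
                    hsp_cluster=cluster,
                    copy_index=ci,
                    reference_entry=entry,
                )
            )
        if clusters:
            located.add(gene)

    pcg_clusters = select_best_hits(aa_hits, cfg.max_intron_span, db.pcg_aa)
    pcg_clusters = {
        g: [c for c in cl if significant(c)] for g, cl in pcg_clusters.items()
    }
    def cluster_identity(cluster: list[Hsp]) -> float:
        # aligned-length-weighted identity: a short frayed fragment must not
        # outvote the body of the alignment in the threshold decision
        total = sum(h.aligned_length for h in cluster)
        return sum(h.aligned_length * h.percent_identity for h in cluster) / total

    for gene, clusters in pcg_clusters.items():
        if not clusters:
            continue
        best_identity = max(cluster_identity(c) for c in clusters)
        if best_identity < cfg.identity_threshold_pcg:
            skipped.append(SkippedGene(gene, best_identity))
            continue
        for ci, cluster in enumerate(clusters):
            entry = cluster[0].entry
            loci.append(
                PreliminaryLocus(
                    gene_name=gene,
                    category="PCG",
                    strand=cluster[0].strand,
                    hsp_cluster=cluster,
                    copy_index=ci,
                    reference_entry=entry,
                )
            )
        located.add(gene)

    skipped_names = {s.gene_name for s in skipped}
    missing = sorted(db.gene_names - located - skipped_names)
    return loci, skipped, missing


def needs_exon1_rescue(entry: ReferenceGeneEntry) -> bool:
    """True for intron PCGs whose first exon is too short to be hit."""
    return (
        entry.category == "PCG"
        and entry.has_intron
        and entry.exon_lengths[0] <= SHORT_EXON1_MAX_NT
    )


def locate_short_exon1(
    target_cs: str,
    exon2_5p: int,
    ref_exon1_nt: str,
    window: int = DEFAULT_EXON1_WINDOW_NT,
    max_mismatches: int = 0,
) -> tuple[int, int] | None:
    """Find the short first exon upstream of a located exon 2.

    Exact (or ``max_mismatches``-tolerant) search for the reference exon-1
    sequence on the coding strand within ``window`` nt upstream of
    ``exon2_5p``; the match closest to exon 2 wins. Returns the exon-1
    interval in coding-strand coordinates, or None.
    """
    n = len(ref_exon1_nt)
    lo = max(0, exon2_5p - window)
    best: int | None = None
    for p in range(lo, exon2_5p - n + 1):
        window_seq = target_cs[p : p + n]
        mismatches = sum(a != b for a, b in zip(window_seq, ref_exon1_nt))
        if mismatches <= max_mismatches:
            best = p  # keep scanning; the largest p is nearest to exon 2
    if best is None:
        return None
    return best, best + n


def order_loci(loci: Sequence[PreliminaryLocus]) -> list[PreliminaryLocus]:
    """Deterministic processing order: by first subject coordinate."""
    return sorted(
        loci, key=lambda l: (min(h.s_start for h in l.hsp_cluster), l.gene_name)
    )
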