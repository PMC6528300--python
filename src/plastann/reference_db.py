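"""The four-component reference gene database.

From one or more annotated reference plastomes this module extracts every
rRNA, tRNA and CDS feature and organizes them into the four collections the
search layer indexes:

* RNA nucleotides (rRNA + tRNA, spliced),
* PCG nucleotides (spliced CDS),
* CDS amino acids without introns,
* CDS amino acids with introns (full protein plus per-exon peptides).

CDS are translated under the plastid/bacterial code (table 11) verbatim —
non-ATG initiator codons are *not* forced to methionine, because the start
search downstream matches literal N-terminal residues of the reference.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from ._seq import translate
from .genbank_io import PlastomeRecord, extract_feature_sequence


class FrameError(ValueError):
    pass


def translate_cds(nt: str) -> tuple[str, list[str]]:
    """Translate a spliced CDS; returns (aa_without_terminal_stop, warnings).

    The terminal stop is dropped; an internal stop is kept (as ``*``) and
    produces a warning, since it usually marks a pseudogene in the reference.
    """
    if len(nt) % 3 != 0:
        raise FrameError(f"CDS length {len(nt)} is not a multiple of 3")
    aa = translate(nt)
    warnings = []
    if aa.endswith("*"):
        aa = aa[:-1]
    else:
        warnings.append("CDS does not end with a stop codon")
    if "*" in aa:
        warnings.append("internal stop codon (possible pseudogene in reference)")
    return aa, warnings


def exon_peptides(exon_nts: Sequence[str]) -> list[str]:
    """Per-exon amino-acid sequences of an intron-containing CDS.

    Split codons are assigned to neither flanking exon: each exon's peptide
    covers only the codons that lie entirely inside it. The leading
    nucleotides of exon *i* that complete a codon begun in exon *i-1* are
    skipped; the carry propagates across exons.
    """
    peptides = []
    carry = 0
    for nt in exon_nts:
        lead = (3 - carry) % 3
        usable = nt[lead : lead + 3 * ((len(nt) - lead) // 3)]
        peptides.append(translate(usable))
        carry = (carry + len(nt)) % 3
    return peptides


@dataclasses.dataclass
class ReferenceGeneEntry:
    gene_name: str
    category: str  # "rRNA" | "tRNA" | "PCG"
    nt_sequence: str  # coding strand, exons concatenated
    exon_lengths: tuple[int, ...]
    source_record: str
    aa_sequence: str = ""  # PCG only, terminal stop dropped
    exon_aa: tuple[str, ...] = ()  # PCG with introns: per-exon peptides
    warnings: tuple[str, ...] = ()

    @property
    def has_intron(self) -> bool:
        return len(self.exon_lengths) > 1

    @property
    def length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_name, self.nt_sequence)


@dataclasses.dataclass
class ReferenceDatabase:
    rna_nt: list[ReferenceGeneEntry]
    pcg_nt: list[ReferenceGeneEntry]
    cds_aa_intronless: list[ReferenceGeneEntry]
    cds_aa_intron: list[ReferenceGeneEntry]

    @property
    def gene_names(self) -> set[str]:
        return {e.gene_name for e in self.rna_nt} | {
            e.gene_name for e in self.pcg_nt
        }

    @property
    def pcg_aa(self) -> list[ReferenceGeneEntry]:
        return self.cds_aa_intronless + self.cds_aa_intron

    def entries_for(self, gene_name: str) -> list[ReferenceGeneEntry]:
        return [
            e for e in self.rna_nt + self.pcg_nt if e.gene_name == gene_name
        ]

    def components(self) -> dict[str, list[ReferenceGeneEntry]]:
        return {
            "rna_nt": self.rna_nt,
            "pcg_nt": self.pcg_nt,
            "cds_aa_intronless": self.cds_aa_intronless,
            "cds_aa_intron": self.cds_aa_intron,
        }


def build_reference_db(
    records: Sequence[PlastomeRecord],
    aliases: Mapping[str, str] | None = None,
) -> ReferenceDatabase:
    """Build the reference database from parsed reference plastomes.

    Entries with identical (gene name, nucleotide sequence) are deduplicated,
    so the two inverted-repeat copies of a gene collapse to one entry, while
    distinct references contribute parallel entries per gene name. ``aliases``
    optionally normalizes gene-name spelling variants before grouping.
    """
    aliases = dict(aliases or {})
    rna: list[ReferenceGeneEntry] = []
    pcg: list[ReferenceGeneEntry] = []
    seen: set[tuple[str, str]] = set()
    for record in records:
        for feat in record.features:
            if feat.kind not in ("CDS", "tRNA", "rRNA") or not feat.gene_name:
                continue
            name = aliases.get(feat.gene_name, feat.gene_name)
            nt = extract_feature_sequence(record, feat.location)
            if (name, nt) in seen:
                continue
            seen.add((name, nt))
            exon_lengths = tuple(b - a for a, b in feat.location.segments)
            if feat.kind == "CDS":
                aa, warns = translate_cds(nt)
                exon_nts = []
                pos = 0
                for ln in exon_lengths:
                    exon_nts.append(nt[pos : pos + ln])
                    pos += ln
                pcg.append(
                    ReferenceGeneEntry(
                        gene_name=name,
                        category="PCG",
                        nt_sequence=nt,
                        exon_lengths=exon_lengths,
                        source_record=record.record_id,
                        aa_sequence=aa,
                        exon_aa=tuple(exon_peptides(exon_nts))
                        if len(exon_lengths) > 1
                        else (),
                        warnings=tuple(warns),
                    )
                )
            else:
                rna.append(
                    ReferenceGeneEntry(
                        gene_name=name,
                        category=feat.kind,
                        nt_sequence=nt,
                        exon_lengths=exon_lengths,
                        source_record=record.record_id,
                    )
                )
    if not rna and not pcg:
        raise ValueError("no annotatable features in the reference set")
    return ReferenceDatabase(
        rna_nt=rna,
        pcg_nt=pcg,
        cds_aa_intronless=[e for e in pcg if not e.has_intron],
        cds_aa_intron=[e for e in pcg if e.has_intron],
    )


def write_component_fastas(db: ReferenceDatabase, directory) -> dict[str, str]:
    """Serialize the four components as FASTA (for external search tools)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for comp_name, entries in db.components().items():
        path = directory / f"{comp_name}.fasta"
        with open(path, "w") as handle:
            for i, e in enumerate(entries):
                seq = e.aa_sequence if comp_name.startswith("cds_aa") else e.nt_sequence
                handle.write(f">{comp_name}|{i}|{e.gene_name}|{e.source_record}\n")
                handle.write(seq + "\n")
        paths[comp_name] = str(path)
    return paths
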