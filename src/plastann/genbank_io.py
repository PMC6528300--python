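"""GenBank / FASTA input-output and the coordinate model.

Reads annotated reference plastomes from GenBank flat files, extracts
feature sequences, validates references, and writes annotated target
plastomes back to GenBank format.

Internal coordinates are 0-based half-open on the forward strand; the
conversion to GenBank's 1-based inclusive convention happens only inside
:func:`parse_genbank` and :func:`write_genbank`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    ExactPosition,
    SeqFeature,
)
from Bio.SeqFeature import SimpleLocation as BioSimpleLocation
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

#: feature kinds transferred from references; everything else is ignored
ANNOTATABLE_KINDS = ("gene", "CDS", "tRNA", "rRNA")

FORWARD = 1
REVERSE = -1


@dataclasses.dataclass(frozen=True)
class FeatureLocation:
    """Ordered exon segments of one feature.

    ``segments`` are (start, end) 0-based half-open intervals on the forward
    axis, ordered 5'->3' in the gene's reading direction (ascending for the
    forward strand, descending for the reverse strand).
    """

    segments: tuple[tuple[int, int], ...]
    strand: int  # FORWARD or REVERSE

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("FeatureLocation needs at least one segment")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"invalid strand {self.strand!r}")
        for a, b in self.segments:
            if not a < b:
                raise ValueError(f"empty or inverted segment ({a}, {b})")
        order = sorted(self.segments, reverse=self.strand == REVERSE)
        if list(self.segments) != order:
            raise ValueError("segments not ordered in reading direction")
        flat = sorted(self.segments)
        for (a1, b1), (a2, b2) in zip(flat, flat[1:]):
            if a2 < b1:
                raise ValueError("overlapping segments")

    @property
    def span(self) -> tuple[int, int]:
        """(min start, max end) on the forward axis."""
        return min(a for a, _ in self.segments), max(b for _, b in self.segments)

    def __len__(self) -> int:
        return sum(b - a for a, b in self.segments)

    def to_biopython(self):
        parts = [
            BioSimpleLocation(a, b, self.strand) for a, b in sorted(self.segments)
        ]
        if len(parts) == 1:
            return parts[0]
        if self.strand == REVERSE:
            # Biopython keeps compound parts in 5'->3' order of the feature
            parts = parts[::-1]
        return CompoundLocation(parts)

    @classmethod
    def from_biopython(cls, loc) -> "FeatureLocation":
        strand = FORWARD if (loc.strand or 1) >= 0 else REVERSE
        segs = sorted(
            ((int(p.start), int(p.end)) for p in loc.parts),
            reverse=strand == REVERSE,
        )
        return cls(tuple(segs), strand)


@dataclasses.dataclass
class GeneFeature:
    gene_name: str
    kind: str  # one of ANNOTATABLE_KINDS
    location: FeatureLocation
    qualifiers: dict[str, str] = dataclasses.field(default_factory=dict)

    def describe(self) -> str:
        a, b = self.location.span
        return f"{self.kind} {self.gene_name or '<unnamed>'} @ {a + 1}..{b}"


@dataclasses.dataclass
class PlastomeRecord:
    record_id: str
    sequence: str
    features: list[GeneFeature] = dataclasses.field(default_factory=list)
    topology: str = "linear"
    issues: list[str] = dataclasses.field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


class GenBankParseError(ValueError):
    pass


def _is_exact(pos) -> bool:
    return type(pos) is ExactPosition


def parse_genbank(path: str | Path) -> PlastomeRecord:
    """Parse a GenBank flat file into a :class:`PlastomeRecord`.

    Only gene/CDS/tRNA/rRNA features are kept. Fuzzy (``<``/``>``) and
    ``order(...)`` locations are not guessed at: the offending feature is
    dropped and recorded in ``record.issues`` for :func:`validate_reference`.
    """
    path = Path(path)
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise GenBankParseError(f"{path}: not parseable as GenBank: {exc}") from exc
    record = PlastomeRecord(
        record_id=seqrec.id or path.stem,
        sequence=str(seqrec.seq).upper(),
        topology=seqrec.annotations.get("topology", "linear"),
    )
    for feat in seqrec.features:
        if feat.type not in ANNOTATABLE_KINDS:
            continue
        gene_name = ""
        if "gene" in feat.qualifiers and feat.qualifiers["gene"]:
            gene_name = str(feat.qualifiers["gene"][0]).strip()
        loc = feat.location
        if loc is None:
            record.issues.append(f"{feat.type} {gene_name}: missing location")
            continue
        if getattr(loc, "operator", "join") == "order":
            record.issues.append(
                f"{feat.type} {gene_name}: order(...) location not supported"
            )
            continue
        if not all(_is_exact(p.start) and _is_exact(p.end) for p in loc.parts):
            record.issues.append(
                f"{feat.type} {gene_name}: fuzzy position rejected"
            )
            continue
        qualifiers = {
            k: str(v[0]) if isinstance(v, list) and v else str(v)
            for k, v in feat.qualifiers.items()
        }
        record.features.append(
            GeneFeature(
                gene_name=gene_name,
                kind=feat.type,
                location=FeatureLocation.from_biopython(loc),
                qualifiers=qualifiers,
            )
        )
    return record


def read_fasta_target(path: str | Path) -> PlastomeRecord:
    """Read an unannotated target plastome: FASTA, one sequence per file."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise GenBankParseError(
            f"{path}: expected exactly one sequence per target file, "
            f"found {len(records)}"
        )
    seq = str(records[0].seq).upper()
    if not seq:
        raise GenBankParseError(f"{path}: empty sequence")
    return PlastomeRecord(record_id=records[0].id or path.stem, sequence=seq)


def extract_feature_sequence(record: PlastomeRecord, loc: FeatureLocation) -> str:
    """Coding-strand sequence of a feature (exons concatenated 5'->3')."""
    out = []
    for a, b in loc.segments:
        if a < 0 or b > record.length:
            raise IndexError(
                f"segment ({a}, {b}) outside record of length {record.length}"
            )
        piece = record.sequence[a:b]
        out.append(revcomp(piece) if loc.strand == REVERSE else piece)
    return "".join(out)


def validate_reference(record: PlastomeRecord) -> list[str]:
    """Report problems that make a reference unusable or suspect.

    One issue per feature lacking the indispensable gene-name qualifier, per
    CDS whose spliced length is not a multiple of 3 or that contains
    ambiguity codes, and per feature with out-of-bounds coordinates.
    Parse-time issues (fuzzy/order locations) are included. An empty list
    means the record is usable as a reference.
    """
    issues = list(record.issues)
    for feat in record.features:
        if not feat.gene_name:
            issues.append(f"missing /gene qualifier: {feat.describe()}")
        a, b = feat.location.span
        if a < 0 or b > record.length:
            issues.append(f"out of bounds: {feat.describe()}")
            continue
        if feat.kind == "CDS":
            nt = extract_feature_sequence(record, feat.location)
            if len(nt) % 3 != 0:
                issues.append(
                    f"CDS length {len(nt)} not a multiple of 3: {feat.describe()}"
                )
            if "N" in nt:
                issues.append(f"ambiguity codes inside CDS: {feat.describe()}")
    return issues


def _annotation_features(annotations, ir=None) -> list[SeqFeature]:
    from .pipeline import GeneAnnotation  # noqa: F401  (typing only)

    feats: list[SeqFeature] = []
    kind_by_category = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    for ann in sorted(annotations, key=lambda a: a.location.span):
        bioloc = ann.location.to_biopython()
        gene_span = BioSimpleLocation(*ann.location.span, ann.location.strand)
        feats.append(
            SeqFeature(gene_span, type="gene", qualifiers={"gene": [ann.gene_name]})
        )
        kind = kind_by_category[ann.category]
        quals: dict[str, list[str]] = {"gene": [ann.gene_name]}
        if kind == "CDS":
            quals["codon_start"] = ["1"]
        if ann.warnings:
            quals["note"] = ["; ".join(ann.warnings)]
        feats.append(SeqFeature(bioloc, type=kind, qualifiers=quals))
    if ir is not None and ir.found:
        for name, (a, b) in (("IRa", ir.ira), ("IRb", ir.irb)):
            feats.append(
                SeqFeature(
                    BioSimpleLocation(a, b, FORWARD),
                    type="repeat_region",
                    qualifiers={"rpt_type": ["inverted"], "note": [name]},
                )
            )
    return feats


def write_genbank(
    record: PlastomeRecord,
    annotations: Sequence,
    path: str | Path,
    ir=None,
) -> None:
    """Write an annotated target plastome as a GenBank flat file.

    Each :class:`~plastann.pipeline.GeneAnnotation` produces a ``gene``
    feature spanning the locus plus a CDS/tRNA/rRNA feature with the exon
    structure (``join(...)`` for multi-exon, ``complement(...)`` for the
    reverse strand). The file re-parses to identical coordinates.
    """
    path = Path(path)
    name = record.record_id.replace(" ", "_")[:16] or "target"
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.record_id,
        name=name,
        description="annotated by plastann",
        annotations={
            "molecule_type": "DNA",
            "topology": record.topology,
            "data_file_division": "PLN",
        },
    )
    source = SeqFeature(
        BioSimpleLocation(0, record.length, FORWARD),
        type="source",
        qualifiers={"organism": [record.record_id]},
    )
    seqrec.features = [source] + _annotation_features(annotations, ir)
    with open(path, "w") as handle:
        SeqIO.write([seqrec], handle, "genbank")


def write_fasta(record: PlastomeRecord, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f">{record.record_id}\n")
        seq = record.sequence
        for i in range(0, len(seq), 70):
            handle.write(seq[i : i + 70] + "\n")


def records_from_dir(
    directory: str | Path, suffixes: Iterable[str] = (".gb", ".gbk", ".genbank")
) -> list[PlastomeRecord]:
    """Parse every GenBank file in ``directory`` (sorted for determinism)."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in set(suffixes)
    )
    return [parse_genbank(p) for p in paths]
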