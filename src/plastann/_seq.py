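"""Low-level nucleotide/codon helpers shared across modules.

All sequences are plain upper-case ``str`` over {A,C,G,T,N}; coordinates are
0-based half-open throughout the package. Translation uses the plastid /
bacterial genetic code (NCBI translation table 11) taken from Biopython's
codon-table data.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: codon -> single-letter amino acid, table 11 (stops absent; see STOP_CODONS)
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str, *, to_stop: bool = False) -> str:
    """Translate ``nt`` (frame 0) under table 11.

    Stop codons render as ``*``; codons containing ambiguity codes render as
    ``X``. Trailing nucleotides that do not fill a codon are ignored.
    ``to_stop`` truncates at the first stop (the stop itself excluded).
    """
    aa = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            if to_stop:
                break
            aa.append("*")
        else:
            aa.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aa)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
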