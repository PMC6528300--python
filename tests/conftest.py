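import random

import pytest

from plastann.reference_db import build_reference_db
from plastann.simulate import FixtureSpec, generate_fixture


def _fixed_seq(n: int, seed: int = 42) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


TOY_SEQ = _fixed_seq(500)


def _fline(key: str, location: str) -> str:
    return " " * 5 + key.ljust(16) + location


def _qline(text: str) -> str:
    return " " * 21 + text


def _genbank_text(seq: str, feature_lines: list[str], name: str = "TOY1") -> str:
    lines = [
        f"LOCUS       {name:<16}{len(seq):>12} bp    DNA     linear   "
        "PLN 01-JAN-2019",
        "DEFINITION  toy plastome fragment.",
        f"ACCESSION   {name}",
        f"VERSION     {name}.1",
        "FEATURES             Location/Qualifiers",
        _fline("source", f"1..{len(seq)}"),
        *feature_lines,
        "ORIGIN",
    ]
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_genbank(tmp_path):
    """Hand-written GenBank flat file with join/complement locations."""
    features = [
        _fline("gene", "10..190"),
        _qline('/gene="psbX"'),
        _fline("CDS", "join(10..18,101..190)"),
        _qline('/gene="psbX"'),
        _fline("tRNA", "complement(50..130)"),
        _qline('/gene="trnX-AAA"'),
        _fline("CDS", "complement(join(200..300,400..406))"),
        _qline('/gene="ycfX"'),
    ]
    path = tmp_path / "toy.gb"
    path.write_text(_genbank_text(TOY_SEQ, features))
    return path


@pytest.fixture
def toy_seq():
    return TOY_SEQ


@pytest.fixture(scope="session")
def gold_fixture():
    """One divergence-free fixture (target == reference sequence)."""
    return generate_fixture(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def gold_db(gold_fixture):
    return build_reference_db([gold_fixture.reference])
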