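import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

import degenphylo as dp

SENSE_CODONS = sorted(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if str(Seq(c).translate()) != "*"
)
STOP_CODONS = ["TAA", "TAG", "TGA"]


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def closure_oracle_table() -> dict[str, str]:
    """Independent degen1 construction: transitive closure of
    single-nucleotide synonymous steps (Biopython translation), then
    per-position IUPAC unions."""
    code_to_set = dp.codon_recoding.IUPAC_CODES
    set_to_code = {v: k for k, v in code_to_set.items()}
    table = {}
    for codon in SENSE_CODONS:
        fam, frontier = {codon}, [codon]
        while frontier:
            c = frontier.pop()
            for pos in range(3):
                for b in "ACGT":
                    d = c[:pos] + b + c[pos + 1:]
                    if d not in fam and translate(d) == translate(c):
                        fam.add(d)
                        frontier.append(d)
        table[codon] = "".join(
            set_to_code[frozenset(c[pos] for c in fam)] for pos in range(3))
    return table


@pytest.fixture(scope="session")
def oracle_table():
    return closure_oracle_table()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_codon_alignment(rng, n_taxa=6, n_codons=30, p_gap=0.05,
                           p_ambig=0.05) -> dp.CodonAlignment:
    """Random in-frame alignment over sense codons with occasional gap or
    ambiguity codons."""
    ambig = ["CAY", "YTG", "MGA", "TCN", "RAA", "GGN"]
    seqs = []
    for i in range(n_taxa):
        chunks = []
        for _ in range(n_codons):
            u = rng.random()
            if u < p_gap:
                chunks.append("---" if rng.random() < 0.5 else "???")
            elif u < p_gap + p_ambig:
                chunks.append(ambig[rng.integers(len(ambig))])
            else:
                chunks.append(SENSE_CODONS[rng.integers(len(SENSE_CODONS))])
        seqs.append("".join(chunks))
    return dp.CodonAlignment([f"tx{i + 1}" for i in range(n_taxa)], seqs, "g1")
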