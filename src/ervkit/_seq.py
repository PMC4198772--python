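"""Small shared sequence helpers (nucleotide alphabets, translation)."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

NUCS = "ACGT"
PURINES = frozenset("AG")
STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide string; trailing partial codon dropped."""
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(NUCS))[rng.choice(4, size=length, p=p)])


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AA20))[rng.integers(0, 20, size=length)])


def mutate_protein(rng: np.random.Generator, protein: str, divergence: float) -> str:
    """Substitute a `divergence` fraction of residues with random other residues."""
    chars = list(protein)
    hit = rng.random(len(chars)) < divergence
    for i in np.flatnonzero(hit):
        choices = AA20.replace(chars[i], "")
        chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)
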