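"""Sense-codon state space for the standard (universal) genetic code.

The 61 sense codons are ordered lexicographically over T, C, A, G (the
conventional ordering in codon-model software), and the module precomputes
the single-nucleotide-difference structure that codon rate matrices need:
which codon pairs are one substitution apart, whether that substitution is
a transition, and whether it is synonymous.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"

_table = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_table.stop_codons)

#: 61 sense codons in TCAG lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)

N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid (one-letter) encoded by each sense codon.
CODON_AA: tuple[str, ...] = tuple(_table.forward_table[c] for c in SENSE_CODONS)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)


def _pair_structure():
    rows, cols, transition, synonymous = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            rows.append(i)
            cols.append(j)
            transition.append(_is_transition(ci[k], cj[k]))
            synonymous.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.asarray(rows, dtype=np.intp),
        np.asarray(cols, dtype=np.intp),
        np.asarray(transition, dtype=bool),
        np.asarray(synonymous, dtype=bool),
    )


#: indices (i, j) of ordered codon pairs one nucleotide apart, with flags.
PAIR_I, PAIR_J, PAIR_IS_TRANSITION, PAIR_IS_SYNONYMOUS = _pair_structure()


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop codon.

    Raises KeyError for codons containing non-ACGT characters.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    if codon not in CODON_INDEX:
        raise KeyError(f"not an unambiguous DNA codon: {codon!r}")
    return CODON_AA[CODON_INDEX[codon]]


def encode_codon_sequence(seq: str) -> np.ndarray:
    """Encode an aligned codon row as indices into SENSE_CODONS.

    Triplets that are all-gap (``---``) or contain any non-ACGT character
    are encoded as -1 (missing data for likelihood purposes).
    """
    if len(seq) % 3:
        raise ValueError("codon sequence length must be a multiple of 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for s in range(len(out)):
        codon = seq[3 * s : 3 * s + 3].upper()
        out[s] = CODON_INDEX.get(codon, -1)
    return out
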