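"""Genetic-code bookkeeping for the 61 sense codons of the standard code.

Everything downstream (rate matrices, simulation, counting estimators) works on
integer codon indices into :data:`SENSE_CODONS`; the gap codon ``---`` is
represented by the index ``GAP``.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
GAP = -1
GAP_CODON = "---"

_table = CodonTable.unambiguous_dna_by_id[1]

#: the 61 sense codons of the standard code, in lexicographic (ACGT) order
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product(NUCS, repeat=3)
    if "".join(c) not in _table.stop_codons
)
N_CODONS = len(SENSE_CODONS)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
STOP_CODONS = frozenset(_table.stop_codons)
AMINO_ACID: tuple[str, ...] = tuple(_table.forward_table[c] for c in SENSE_CODONS)

#: codon index array of shape (61, 3): nucleotide index at each codon position
CODON_NUCS = np.array(
    [[NUCS.index(n) for n in codon] for codon in SENSE_CODONS], dtype=np.int8
)


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def _one_step_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    one = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    ts = np.zeros_like(one)
    nonsyn = np.zeros_like(one)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            one[i, j] = True
            ts[i, j] = _is_transition(ci[p], cj[p])
            nonsyn[i, j] = AMINO_ACID[i] != AMINO_ACID[j]
    return one, ts, nonsyn


#: boolean 61x61 masks over ordered codon pairs reachable by one nucleotide change
ONE_STEP, TRANSITION, NONSYNONYMOUS = _one_step_masks()


def codon_to_index(codon: str) -> int:
    """Map a codon string to its sense-codon index; ``---`` maps to GAP.

    Raises ``ValueError`` on stop codons or malformed codons.
    """
    codon = codon.upper()
    if codon == GAP_CODON:
        return GAP
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} not allowed in a codon alignment")
    try:
        return CODON_INDEX[codon]
    except KeyError:
        raise ValueError(f"invalid codon {codon!r}") from None


def index_to_codon(idx: int) -> str:
    return GAP_CODON if idx == GAP else SENSE_CODONS[idx]


def translate_codon(codon: str) -> str:
    return AMINO_ACID[CODON_INDEX[codon]]


def f3x4_frequencies(codon_indices: np.ndarray) -> np.ndarray:
    """F3x4 stationary codon frequencies from observed codons.

    Position-specific nucleotide frequencies are estimated over all non-gap
    codons in ``codon_indices`` (any shape); the codon frequency is the product
    over the three positions, restricted to sense codons and renormalized.
    A position with an unobserved nucleotide gets a 0.5 pseudocount on every
    nucleotide at that position so the stationary distribution stays strictly
    positive.
    """
    idx = np.asarray(codon_indices).ravel()
    idx = idx[idx != GAP]
    if idx.size == 0:
        raise ValueError("cannot estimate codon frequencies from an all-gap input")
    pos_freq = np.empty((3, 4))
    for p in range(3):
        counts = np.bincount(CODON_NUCS[idx, p], minlength=4).astype(float)
        if np.any(counts == 0):
            counts += 0.5
        pos_freq[p] = counts / counts.sum()
    freqs = pos_freq[0, CODON_NUCS[:, 0]] * pos_freq[1, CODON_NUCS[:, 1]] * pos_freq[2, CODON_NUCS[:, 2]]
    return freqs / freqs.sum()


def uniform_frequencies() -> np.ndarray:
    """Uniform distribution over the 61 sense codons (test convenience)."""
    return np.full(N_CODONS, 1.0 / N_CODONS)
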