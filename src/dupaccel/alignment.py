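"""In-frame codon alignments keyed by taxon-role labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import codons


@dataclass
class CodonAlignment:
    """A gapped, in-frame alignment over the 61 sense codons.

    ``codon_indices`` has shape (n_taxa, n_columns) with entries in [0, 61)
    or :data:`dupaccel.codons.GAP` for the gap codon ``---``.
    """

    labels: tuple[str, ...]
    codon_indices: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.codon_indices = np.asarray(self.codon_indices, dtype=np.int16)
        if self.codon_indices.ndim != 2 or self.codon_indices.shape[0] != len(self.labels):
            raise ValueError("codon_indices must be (n_taxa, n_columns)")
        if self.codon_indices.shape[1] < 1:
            raise ValueError("alignment must have at least one codon column")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        bad = (self.codon_indices < codons.GAP) | (self.codon_indices >= codons.N_CODONS)
        if bad.any():
            raise ValueError("codon indices out of range")

    @property
    def length(self) -> int:
        """Number of codon columns."""
        return self.codon_indices.shape[1]

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "CodonAlignment":
        """Build from label -> nucleotide string (length divisible by 3).

        Stop codons and partially gapped codons are rejected.
        """
        labels = tuple(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        (nt_len,) = lengths
        if nt_len % 3 != 0:
            raise ValueError(f"sequence length {nt_len} is not a multiple of 3")
        rows = []
        for label, seq in sequences.items():
            seq = seq.upper()
            row = []
            for i in range(0, nt_len, 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != codons.GAP_CODON:
                    raise ValueError(
                        f"{label}: partially gapped codon {codon!r} at codon column {i // 3}"
                    )
                try:
                    row.append(codons.codon_to_index(codon))
                except ValueError as e:
                    raise ValueError(f"{label}, codon column {i // 3}: {e}") from None
            rows.append(row)
        return cls(labels=labels, codon_indices=np.array(rows, dtype=np.int16))

    def sequence(self, label: str) -> str:
        row = self.codon_indices[self.labels.index(label)]
        return "".join(codons.index_to_codon(int(i)) for i in row)

    def to_sequences(self) -> dict[str, str]:
        return {label: self.sequence(label) for label in self.labels}

    def row(self, label: str) -> np.ndarray:
        return self.codon_indices[self.labels.index(label)]

    def subset(self, labels: list[str] | tuple[str, ...]) -> "CodonAlignment":
        rows = np.stack([self.row(l) for l in labels])
        return CodonAlignment(labels=tuple(labels), codon_indices=rows)

    def drop_gapped_columns(self) -> "CodonAlignment":
        """Keep only columns where no sequence has a gap."""
        keep = (self.codon_indices != codons.GAP).all(axis=0)
        if not keep.any():
            raise ValueError("no gap-free codon columns")
        return CodonAlignment(labels=self.labels, codon_indices=self.codon_indices[:, keep])
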