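"""The fixed six-taxon duplication topology and its branch classes.

One gene duplication is represented by six sequences: two paralogs in each of
two sister species that split after the duplication (mouse/rat, or
human/orangutan in the primate sets) plus single-copy outgroup orthologs (cow
and dog) that diverged before it.  The unrooted topology is fixed by study
design:

    (((M1, R1), (M2, R2)), C, D)

with internal nodes n1 = (M1,R1) ancestor, n2 = (M2,R2) ancestor, n3 = the
duplication node and n4 = the junction toward C and D.  Rooting at n4 gives
nine branches, each named after its child node; every branch carries one of
five ω classes:

    preD      C–n4, D–n4, n3–n4   (preduplication)
    ipostD1   n1–n3               (initial postduplication, copy 1)
    ipostD2   n2–n3
    rpostD1   M1–n1, R1–n1        (recent postduplication, copy 1)
    rpostD2   M2–n2, R2–n2
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import OMEGA_CLASSES

TIP_ROLES = ("C", "D", "M1", "M2", "R1", "R2")

#: branch names = child node when rooted at n4
BRANCHES = ("C", "D", "n3", "n1", "n2", "M1", "R1", "M2", "R2")

CLASS_OF_BRANCH: dict[str, str] = {
    "C": "preD",
    "D": "preD",
    "n3": "preD",
    "n1": "ipostD1",
    "n2": "ipostD2",
    "M1": "rpostD1",
    "R1": "rpostD1",
    "M2": "rpostD2",
    "R2": "rpostD2",
}

#: parent of each branch's child node, rooted at n4
PARENT = {
    "C": "n4",
    "D": "n4",
    "n3": "n4",
    "n1": "n3",
    "n2": "n3",
    "M1": "n1",
    "R1": "n1",
    "M2": "n2",
    "R2": "n2",
}

#: children of each internal node when rooted at n4
CHILDREN_N4 = {
    "n4": ("C", "D", "n3"),
    "n3": ("n1", "n2"),
    "n1": ("M1", "R1"),
    "n2": ("M2", "R2"),
}

#: same topology re-rooted at the duplication node n3 (branch n3 hangs n4)
CHILDREN_N3 = {
    "n3": ("n1", "n2", "n4"),
    "n4": ("C", "D"),
    "n1": ("M1", "R1"),
    "n2": ("M2", "R2"),
}

#: codeml-dialect branch-label index per ω class (#0..#4)
CLASS_LABEL_INDEX = {cls: k for k, cls in enumerate(OMEGA_CLASSES)}


@dataclass
class SextupletTree:
    """Branch lengths (substitutions per codon) on the fixed topology."""

    branch_lengths: dict[str, float]
    class_of_branch: dict[str, str] = field(default_factory=lambda: dict(CLASS_OF_BRANCH))

    def __post_init__(self) -> None:
        if set(self.branch_lengths) != set(BRANCHES):
            missing = set(BRANCHES) - set(self.branch_lengths)
            extra = set(self.branch_lengths) - set(BRANCHES)
            raise ValueError(f"branch set mismatch: missing {missing}, extra {extra}")
        for b, t in self.branch_lengths.items():
            if not np.isfinite(t) or t < 0:
                raise ValueError(f"branch {b}: length must be finite and >= 0, got {t}")
        if self.class_of_branch != CLASS_OF_BRANCH:
            raise ValueError("branch-class assignment is fixed by study design")

    @classmethod
    def from_lengths(cls, **lengths: float) -> "SextupletTree":
        return cls(branch_lengths=dict(lengths))

    def length_vector(self) -> np.ndarray:
        return np.array([self.branch_lengths[b] for b in BRANCHES])

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two nodes."""

        def to_root(node: str) -> list[str]:
            path = []
            while node != "n4":
                path.append(node)
                node = PARENT[node]
            return path

        pa, pb = to_root(a), to_root(b)
        shared = set(pa) & set(pb)
        return sum(self.branch_lengths[x] for x in pa + pb if x not in shared)

    def newick(self, include_classes: bool = True) -> str:
        """Newick string, classes encoded as ``#k`` branch labels (k = 0..4)."""

        def lab(branch: str) -> str:
            if not include_classes:
                return ""
            return f" #{CLASS_LABEL_INDEX[self.class_of_branch[branch]]}"

        def edge(branch: str, name: str | None = None) -> str:
            return f"{name or branch}{lab(branch)}:{self.branch_lengths[branch]:.6f}"

        n1 = f"({edge('M1')},{edge('R1')}){lab('n1')}:{self.branch_lengths['n1']:.6f}"
        n2 = f"({edge('M2')},{edge('R2')}){lab('n2')}:{self.branch_lengths['n2']:.6f}"
        n3 = f"({n1},{n2}){lab('n3')}:{self.branch_lengths['n3']:.6f}"
        return f"({n3},{edge('C')},{edge('D')});"
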