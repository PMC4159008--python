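"""Construction of analysis-ready sextuplet sets from homology relations.

A usable duplication is a dog gene with a one-to-one cow ortholog and
one-to-many orthology to mouse (or human) paralogs, each of which has a
one-to-one rat (orangutan) ortholog.  Families with more than two paralogs are
decomposed recursively into single-duplication sets by repeatedly taking the
paralog pair with the smallest synonymous divergence as the most recent
duplication and removing one member at random.  A synonymous-divergence filter
then removes sets whose pairwise distances are too large to postdate the
dog–cow / rodent split (defaults to ds > 1), which also purges gene losses in
the outgroup lineage and gross misassignments.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("C", "D", "M1", "M2", "R1", "R2")
FILTER_COMPARISONS = ("C-D", "M1-R1", "M2-R2", "M1-M2", "R1-R2")

_VALID_RELATIONS = {"one-to-one", "one-to-many", "many-to-many"}
_GENOME_SETS = ({"cow", "dog", "mouse", "rat"}, {"cow", "dog", "human", "orangutan"})


@dataclass
class SextupletSet:
    """One duplication: role -> gene id, plus family provenance."""

    genes: dict[str, str]
    source_cluster: str
    duplication_rank: int = 1

    def __post_init__(self) -> None:
        if set(self.genes) != set(ROLES):
            raise ValueError(f"need exactly the roles {ROLES}, got {sorted(self.genes)}")
        if len(set(self.genes.values())) != len(ROLES):
            raise ValueError("all six gene ids must be distinct")

    @property
    def set_id(self) -> str:
        return f"{self.source_cluster}.{self.duplication_rank}"


@dataclass
class FamilyCluster:
    """A dog/cow anchor with >2 mouse paralogs awaiting decomposition."""

    dog: str
    cow: str
    pairs: list[tuple[str, str]]  # (mouse paralog, its rat one-to-one ortholog)
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if not self.cluster_id:
            self.cluster_id = self.dog


def validate_homology_table(table: pd.DataFrame) -> None:
    required = {"gene_id_a", "genome_a", "gene_id_b", "genome_b", "relation"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"homology table lacks columns {sorted(missing)}")
    bad = ~table["relation"].isin(_VALID_RELATIONS)
    if bad.any():
        row = table.index[bad][0]
        raise ValueError(f"row {row}: unknown relation {table.loc[row, 'relation']!r}")
    genomes = set(table["genome_a"]) | set(table["genome_b"])
    if not any(genomes <= g for g in _GENOME_SETS):
        raise ValueError(f"unexpected genome labels: {sorted(genomes)}")


def _relations(table: pd.DataFrame, genome_a: str, genome_b: str) -> pd.DataFrame:
    fwd = table[(table["genome_a"] == genome_a) & (table["genome_b"] == genome_b)]
    rev = table[(table["genome_a"] == genome_b) & (table["genome_b"] == genome_a)].rename(
        columns={
            "gene_id_a": "gene_id_b",
            "gene_id_b": "gene_id_a",
            "genome_a": "genome_b",
            "genome_b": "genome_a",
        }
    )
    return pd.concat([fwd, rev], ignore_index=True)


def find_sextuplets(
    table: pd.DataFrame,
    ingroup: tuple[str, str] = ("mouse", "rat"),
) -> tuple[list[SextupletSet], list[FamilyCluster]]:
    """Candidate sets (2-paralog clusters) and multi-paralog family clusters.

    Emits one candidate per dog gene with a one-to-one cow ortholog and
    exactly two mouse paralogs (one-to-many from dog), each with a one-to-one
    rat ortholog; clusters with more such paralogs are returned as
    :class:`FamilyCluster` for :func:`decompose_family`.
    """
    validate_homology_table(table)
    sp1, sp2 = ingroup
    dog_cow = _relations(table, "dog", "cow")
    dog_mouse = _relations(table, "dog", sp1)
    mouse_rat = _relations(table, sp1, sp2)

    one2one_cow = dog_cow[dog_cow["relation"] == "one-to-one"]
    cow_counts = one2one_cow.groupby("gene_id_a")["gene_id_b"].nunique()
    rat_of = {
        r.gene_id_a: r.gene_id_b
        for r in mouse_rat[mouse_rat["relation"] == "one-to-one"].itertuples()
    }

    sets: list[SextupletSet] = []
    clusters: list[FamilyCluster] = []
    for dog, grp in dog_mouse[dog_mouse["relation"] == "one-to-many"].groupby("gene_id_a"):
        if cow_counts.get(dog, 0) != 1:
            continue
        cow = one2one_cow.loc[one2one_cow["gene_id_a"] == dog, "gene_id_b"].iloc[0]
        pairs = sorted(
            (m, rat_of[m]) for m in grp["gene_id_b"].unique() if m in rat_of
        )
        if len(pairs) < 2:
            continue
        if len(pairs) == 2:
            (m1, r1), (m2, r2) = pairs
            sets.append(
                SextupletSet(
                    genes={"C": cow, "D": dog, "M1": m1, "M2": m2, "R1": r1, "R2": r2},
                    source_cluster=dog,
                )
            )
        else:
            clusters.append(FamilyCluster(dog=dog, cow=cow, pairs=pairs))
    return sets, clusters


def decompose_family(
    cluster: FamilyCluster,
    ds_matrix: dict[frozenset, float],
    seed: int = 0,
) -> list[SextupletSet]:
    """Recursively split a multi-paralog family into single-duplication sets.

    At each step the paralog pair with the smallest synonymous divergence is
    taken as the most recent duplication and emitted as a set; one member of
    the pair (chosen by a set-scoped seeded RNG, so families are independent)
    is then removed together with its sister-species ortholog, and the
    procedure recurses until one paralog remains.  A family of k paralogs
    yields k − 1 sets, ranked 1 (most recent) to k − 1.  Ties in ds are broken
    lexicographically by gene-id pair and logged.
    """
    pairs = dict(cluster.pairs)
    if len(pairs) < 2:
        raise ValueError("family must contain at least 2 paralogs")
    for a in pairs:
        for b in pairs:
            if a < b:
                key = frozenset((a, b))
                if key not in ds_matrix:
                    raise ValueError(f"ds_matrix lacks pair ({a}, {b})")
                if ds_matrix[key] < 0:
                    raise ValueError(f"negative ds for pair ({a}, {b})")
    rng = np.random.default_rng([seed, zlib.crc32(cluster.cluster_id.encode())])
    remaining = sorted(pairs)
    out: list[SextupletSet] = []
    rank = 1
    while len(remaining) > 1:
        candidates = sorted(
            ((a, b) for i, a in enumerate(remaining) for b in remaining[i + 1 :]),
            key=lambda ab: (ds_matrix[frozenset(ab)], ab),
        )
        best = candidates[0]
        if len(candidates) > 1 and ds_matrix[frozenset(candidates[1])] == ds_matrix[frozenset(best)]:
            logger.info(
                "family %s: ds tie at %.6g broken lexicographically (%s)",
                cluster.cluster_id,
                ds_matrix[frozenset(best)],
                best,
            )
        m1, m2 = best
        out.append(
            SextupletSet(
                genes={
                    "C": cluster.cow,
                    "D": cluster.dog,
                    "M1": m1,
                    "M2": m2,
                    "R1": pairs[m1],
                    "R2": pairs[m2],
                },
                source_cluster=cluster.cluster_id,
                duplication_rank=rank,
            )
        )
        removed = best[int(rng.integers(2))]
        remaining.remove(removed)
        rank += 1
    return out


def filter_ds(
    sets: list[SextupletSet],
    ds_table: dict[str, dict[str, float]],
    threshold: float = 1.0,
) -> tuple[list[SextupletSet], pd.DataFrame]:
    """Drop sets with excessive synonymous divergence.

    ``ds_table`` maps set_id to the five comparison ds values
    (C-D, M1-R1, M2-R2, M1-M2, R1-R2).  A set is removed iff any of them is
    strictly greater than ``threshold`` (a ds exactly at the threshold is
    retained); a missing or non-finite value rejects the set as "incomplete".
    Returns retained sets and a rejection log.
    """
    retained = []
    rejections = []
    for s in sets:
        ds = ds_table.get(s.set_id, {})
        missing = [c for c in FILTER_COMPARISONS if c not in ds or not np.isfinite(ds[c])]
        if missing:
            rejections.append((s.set_id, "incomplete", ";".join(missing), np.nan))
            continue
        over = [c for c in FILTER_COMPARISONS if ds[c] > threshold]
        if over:
            rejections.append((s.set_id, "ds_above_threshold", over[0], ds[over[0]]))
            continue
        retained.append(s)
    log = pd.DataFrame(rejections, columns=["set_id", "reason", "comparison", "ds"])
    return retained, log


def sets_to_frame(sets: list[SextupletSet]) -> pd.DataFrame:
    rows = [
        {"set_id": s.set_id, "source_cluster": s.source_cluster, "rank": s.duplication_rank, **s.genes}
        for s in sets
    ]
    return pd.DataFrame(rows, columns=["set_id", "source_cluster", "rank", *ROLES])
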