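"""Synthetic codon data with the statistical structure the analysis assumes.

Generates sextuplet codon alignments evolved along the fixed duplication
topology with five branch-class ω values, multi-duplication gene families,
gene-conversion tracts, and homology/synteny table fixtures — so the whole
pipeline is testable without any genome download.  Every generator is
deterministic in its seed and returns machine-readable truth alongside the
data.

The default scenario mirrors the headline pattern the pipeline is built to
detect: preduplication ω = 0.10, an initial burst at ω = 0.40 in both copies,
and recent rates of 0.25 (fast copy) versus 0.10 (slow copy, back at the
preduplication level), with a paralog synonymous depth near 0.3.  The true
rate differences are therefore δ_f = 0.15 and δ_s = 0.00.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import codons, trees
from .alignment import CodonAlignment
from .model import ClassMatrixCache, CodonModelParams

#: mildly non-uniform position-specific nucleotide frequencies (A, C, G, T)
_POS_NUC_FREQS = np.array(
    [
        [0.28, 0.21, 0.30, 0.21],
        [0.30, 0.22, 0.19, 0.29],
        [0.22, 0.27, 0.27, 0.24],
    ]
)

DEFAULT_OMEGAS = {
    "preD": 0.10,
    "ipostD1": 0.40,
    "ipostD2": 0.40,
    "rpostD1": 0.25,
    "rpostD2": 0.10,
}

#: branch lengths (substitutions/codon): paralog synonymous depth (path ds
#: between M1–M2 / R1–R2 under the class ω values) = 0.30, C–D path = 0.4
DEFAULT_BRANCH_LENGTHS = {
    "C": 0.20,
    "D": 0.20,
    "n3": 0.10,
    "n1": 0.096,
    "n2": 0.096,
    "M1": 0.11,
    "R1": 0.11,
    "M2": 0.11,
    "R2": 0.11,
}


def default_codon_freqs() -> np.ndarray:
    """F3x4-style stationary codon frequencies used by the default scenarios."""
    f = (
        _POS_NUC_FREQS[0, codons.CODON_NUCS[:, 0]]
        * _POS_NUC_FREQS[1, codons.CODON_NUCS[:, 1]]
        * _POS_NUC_FREQS[2, codons.CODON_NUCS[:, 2]]
    )
    return f / f.sum()


def default_params(kappa: float = 2.5) -> CodonModelParams:
    return CodonModelParams(
        kappa=kappa, omega_by_class=dict(DEFAULT_OMEGAS), codon_freqs=default_codon_freqs()
    )


@dataclass
class SimulationScenario:
    """Everything needed to simulate one sextuplet alignment reproducibly."""

    tree: trees.SextupletTree
    params: CodonModelParams
    n_codons: int
    seed: int
    lineage_tag: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.lineage_tag not in ("rodent", "primate", "synthetic"):
            raise ValueError(f"unknown lineage_tag {self.lineage_tag!r}")


def default_scenario(
    seed: int,
    n_codons: int = 500,
    age_scale: float = 1.0,
    lineage_tag: str = "synthetic",
) -> SimulationScenario:
    """The study's default scenario; ``age_scale`` multiplies the
    post-duplication branch lengths to move the duplication age while keeping
    the ω regimes fixed."""
    lengths = dict(DEFAULT_BRANCH_LENGTHS)
    for b in ("n1", "n2", "M1", "R1", "M2", "R2"):
        lengths[b] *= age_scale
    return SimulationScenario(
        tree=trees.SextupletTree(branch_lengths=lengths),
        params=default_params(),
        n_codons=n_codons,
        seed=seed,
        lineage_tag=lineage_tag,
    )


def _sample_children(p: np.ndarray, parent_states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.size)
    return np.argmax(cum[parent_states] > u[:, None], axis=1).astype(np.int16)


def simulate_sextuplet(scenario: SimulationScenario) -> tuple[CodonAlignment, dict]:
    """Evolve codons along the duplication topology rooted at n4.

    The root state is drawn from the stationary distribution; each branch
    applies its class's transition matrix.  Returns the six tip sequences and
    a truth record (scenario parameters) for recovery tests.
    """
    rng = np.random.default_rng(scenario.seed)
    pi = scenario.params.codon_freqs
    cache = ClassMatrixCache(pi=pi)
    p_of_branch = {
        b: cache.get(
            scenario.params.kappa,
            scenario.params.omega_by_class[trees.CLASS_OF_BRANCH[b]],
        ).transition_matrix(scenario.tree.branch_lengths[b])
        for b in trees.BRANCHES
    }
    states = {"n4": rng.choice(codons.N_CODONS, size=scenario.n_codons, p=pi).astype(np.int16)}
    # walk the rooted topology parent -> child in a fixed order
    for b in trees.BRANCHES:
        states[b] = _sample_children(p_of_branch[b], states[trees.PARENT[b]], rng)
    aln = CodonAlignment(
        labels=trees.TIP_ROLES,
        codon_indices=np.stack([states[r] for r in trees.TIP_ROLES]),
    )
    truth = {
        "omega_by_class": dict(scenario.params.omega_by_class),
        "kappa": scenario.params.kappa,
        "branch_lengths": dict(scenario.tree.branch_lengths),
        "n_codons": scenario.n_codons,
        "seed": scenario.seed,
        "lineage_tag": scenario.lineage_tag,
        "delta_f_true": max(
            scenario.params.omega_by_class["rpostD1"], scenario.params.omega_by_class["rpostD2"]
        )
        - scenario.params.omega_by_class["preD"],
        "delta_s_true": min(
            scenario.params.omega_by_class["rpostD1"], scenario.params.omega_by_class["rpostD2"]
        )
        - scenario.params.omega_by_class["preD"],
    }
    return aln, truth


def simulate_cohort(
    n_sets: int,
    seed: int,
    n_codons: int = 500,
    age_scales: np.ndarray | None = None,
    lineage_tag: str = "synthetic",
) -> list[tuple[str, CodonAlignment, dict]]:
    """A cohort of independent sextuplet sets, one sub-seed per set.

    ``age_scales`` (length n_sets) varies the duplication age across sets;
    default is all 1.0.
    """
    if age_scales is None:
        age_scales = np.ones(n_sets)
    if len(age_scales) != n_sets:
        raise ValueError("age_scales must have length n_sets")
    out = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_sets) % (2**31)
    for i in range(n_sets):
        scen = default_scenario(
            seed=int(child_seeds[i]),
            n_codons=n_codons,
            age_scale=float(age_scales[i]),
            lineage_tag=lineage_tag,
        )
        aln, truth = simulate_sextuplet(scen)
        out.append((f"set{i:03d}", aln, truth))
    return out


# ---------------------------------------------------------------------------
# multi-duplication families
# ---------------------------------------------------------------------------


def simulate_family(
    n_paralogs: int,
    depths: list[float],
    seed: int,
    n_codons: int = 300,
    params: CodonModelParams | None = None,
    omega: float = 0.2,
) -> tuple[dict[str, np.ndarray], dict]:
    """Nested duplications in a caterpillar topology at given synonymous depths.

    ``depths`` are the paralog–paralog path depths of successive duplications,
    strictly increasing: paralogs p0 and p1 split at depths[0], their ancestor
    and p2 at depths[1], and so on.  Returns codon-index sequences per paralog
    and the true duplication order (most recent first) for decomposition tests.
    """
    if n_paralogs < 2:
        raise ValueError("need at least 2 paralogs")
    if len(depths) != n_paralogs - 1:
        raise ValueError("need n_paralogs - 1 depths")
    d = list(depths)
    if any(b <= a for a, b in zip(d, d[1:])):
        raise ValueError("depths must be strictly increasing and distinct")
    if params is None:
        params = default_params()
    rng = np.random.default_rng(seed)
    pi = params.codon_freqs
    cache = ClassMatrixCache(pi=pi)
    heights = [x / 2.0 for x in d]  # ultrametric node heights

    root_height = heights[-1]
    root = rng.choice(codons.N_CODONS, size=n_codons, p=pi).astype(np.int16)

    def evolve(state: np.ndarray, t: float) -> np.ndarray:
        if t <= 0:
            return state.copy()
        p = cache.get(params.kappa, omega).transition_matrix(t)
        return _sample_children(p, state, rng)

    names = [f"p{i}" for i in range(n_paralogs)]
    # walk from the deepest split down the caterpillar spine
    seqs: dict[str, np.ndarray] = {}
    spine = root
    spine_height = root_height
    for k in range(n_paralogs - 1, 0, -1):
        # at height heights[k-1] the spine splits off paralog p_k
        branch = spine_height - heights[k - 1]
        node = evolve(spine, branch)
        seqs[names[k]] = evolve(node, heights[k - 1])
        spine = node
        spine_height = heights[k - 1]
    seqs[names[0]] = evolve(spine, spine_height)
    truth = {
        "order": [(names[0], names[1])]
        + [(f"anc{k}", names[k + 1]) for k in range(1, n_paralogs - 1)],
        "depths": d,
        "most_recent_pair": (names[0], names[1]),
    }
    return seqs, truth


# ---------------------------------------------------------------------------
# gene conversion
# ---------------------------------------------------------------------------

_WITHIN_SPECIES_PARALOGS = ({"M1", "M2"}, {"R1", "R2"})


@dataclass
class ConversionEvent:
    """A gene-conversion tract: acceptor codons replaced by the donor's."""

    donor: str
    acceptor: str
    tract: tuple[int, int]  # half-open codon-column interval [start, end)

    def __post_init__(self) -> None:
        if {self.donor, self.acceptor} not in _WITHIN_SPECIES_PARALOGS:
            raise ValueError(
                f"{self.donor}->{self.acceptor}: donor and acceptor must be "
                "within-species paralogs (M1/M2 or R1/R2)"
            )
        start, end = self.tract
        if not (0 <= start <= end):
            raise ValueError(f"invalid tract {self.tract}")


def apply_gene_conversion(aln: CodonAlignment, event: ConversionEvent) -> CodonAlignment:
    """Replace the acceptor's codons by the donor's over the tract."""
    start, end = event.tract
    if end > aln.length:
        raise ValueError(f"tract end {end} exceeds alignment length {aln.length}")
    idx = aln.codon_indices.copy()
    di = aln.labels.index(event.donor)
    ai = aln.labels.index(event.acceptor)
    idx[ai, start:end] = idx[di, start:end]
    return CodonAlignment(labels=aln.labels, codon_indices=idx)


# ---------------------------------------------------------------------------
# homology and synteny fixtures
# ---------------------------------------------------------------------------


def make_homology_fixture(
    n_valid: int,
    n_dogcow_many: int = 0,
    n_missing_rat: int = 0,
    n_multi: int = 0,
    paralogs_per_multi: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Homology-table fixture with planted valid and invalid orthology patterns.

    Valid pattern: dog gene with a one-to-one cow ortholog, one-to-many
    orthology to two mouse paralogs, each with a one-to-one rat ortholog.
    ``n_dogcow_many`` plants dog–cow many-to-many cases and ``n_missing_rat``
    plants a mouse paralog without a rat one-to-one ortholog (neither yields a
    set).  ``n_multi`` plants families with >2 paralogs that must go through
    family decomposition.  Returns the table and a truth dict.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = {"valid_dog_genes": [], "invalid_dog_genes": [], "multi_dog_genes": []}
    counter = 0

    def add(a, ga, b, gb, rel):
        rows.append((a, ga, b, gb, rel))

    kinds = (
        ["valid"] * n_valid + ["dogcow_many"] * n_dogcow_many + ["missing_rat"] * n_missing_rat + ["multi"] * n_multi
    )
    rng.shuffle(kinds)
    for kind in kinds:
        i = counter
        counter += 1
        dog, cow = f"dog{i:04d}", f"cow{i:04d}"
        if kind == "dogcow_many":
            add(dog, "dog", cow, "cow", "many-to-many")
            truth["invalid_dog_genes"].append(dog)
            k = 2
        elif kind == "multi":
            add(dog, "dog", cow, "cow", "one-to-one")
            truth["multi_dog_genes"].append(dog)
            k = paralogs_per_multi
        else:
            add(dog, "dog", cow, "cow", "one-to-one")
            (truth["valid_dog_genes"] if kind == "valid" else truth["invalid_dog_genes"]).append(dog)
            k = 2
        drop_rat = rng.integers(k) if kind == "missing_rat" else -1
        for j in range(k):
            mouse, rat = f"mouse{i:04d}_{j}", f"rat{i:04d}_{j}"
            add(dog, "dog", mouse, "mouse", "one-to-many")
            if j == drop_rat:
                add(mouse, "mouse", rat, "rat", "one-to-many")
            else:
                add(mouse, "mouse", rat, "rat", "one-to-one")
    table = pd.DataFrame(rows, columns=["gene_id_a", "genome_a", "gene_id_b", "genome_b", "relation"])
    return table, truth


def make_synteny_fixture(
    n_sets: int,
    window: int = 3,
    frac_original_first: float = 0.5,
    seed: int = 0,
    n_unresolved: int = 0,
    n_tandem: int = 0,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Synteny-table fixture: neighbor lists plus planted originality truth.

    For each resolvable set, one mouse paralog's flanking neighbors match the
    dog gene's neighborhood (the original copy) and the other's do not;
    exactly round(frac_original_first * n_resolved) sets have copy 1 as the
    original, in a seeded random order.
    ``n_unresolved`` sets get shuffled neighborhoods on both copies;
    ``n_tandem`` sets place the two paralogs adjacent to each other (tandem
    duplicates, to be excluded).  Returns (neighbors-by-gene, truth table with
    columns set_id, copy1, copy2, dog, original).
    """
    rng = np.random.default_rng(seed)
    neighbors: dict[str, list[str]] = {}
    truth_rows = []
    n_resolved = n_sets - n_unresolved - n_tandem
    kinds = ["resolved"] * n_resolved + ["unresolved"] * n_unresolved + ["tandem"] * n_tandem
    # plant an exact count of copy1-original sets, in a seeded random order
    n_first = int(round(frac_original_first * n_resolved))
    first_flags = np.zeros(n_resolved, dtype=bool)
    first_flags[:n_first] = True
    rng.shuffle(first_flags)
    resolved_idx = 0
    for i, kind in enumerate(kinds):
        set_id = f"set{i:03d}"
        dog, m1, m2 = f"dog{i:04d}", f"mouse{i:04d}_0", f"mouse{i:04d}_1"
        dog_nbrs = [f"nbr{i:04d}_{k}" for k in range(2 * window)]
        neighbors[dog] = list(dog_nbrs)
        decoy = [f"decoy{i:04d}_{k}" for k in range(2 * window)]
        if kind == "resolved":
            original = m1 if first_flags[resolved_idx] else m2
            resolved_idx += 1
            novel = m2 if original == m1 else m1
            neighbors[original] = list(dog_nbrs)
            neighbors[novel] = list(decoy)
        elif kind == "unresolved":
            original = "unresolved"
            neighbors[m1] = list(decoy[:window]) + [f"x{i}_{k}" for k in range(window)]
            neighbors[m2] = list(decoy[window:]) + [f"y{i}_{k}" for k in range(window)]
        else:  # tandem: paralogs adjacent, both sharing the dog neighborhood
            original = "tandem"
            neighbors[m1] = dog_nbrs[: 2 * window - 1] + [m2]
            neighbors[m2] = dog_nbrs[1:] + [m1]
        truth_rows.append((set_id, m1, m2, dog, original))
    truth = pd.DataFrame(truth_rows, columns=["set_id", "copy1", "copy2", "dog", "original"])
    return neighbors, truth
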