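"""Phylogenetic likelihood by Felsenstein pruning on codon alignments.

Columns are compressed to unique site patterns; gap codons contribute an
all-ones partial likelihood (missing data).  Because the substitution model is
time-reversible the likelihood does not depend on the rooting used for the
recursion, which the tests exploit (rooting at the duplication node versus the
outgroup junction).
"""

from __future__ import annotations

import numpy as np

from . import trees
from .alignment import CodonAlignment
from .codons import GAP, N_CODONS
from .model import ClassMatrixCache, CodonModelParams


def compress_columns(aln: CodonAlignment, labels: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (n_taxa, n_patterns) and their column counts."""
    rows = np.stack([aln.row(l) for l in labels])
    patterns, counts = np.unique(rows, axis=1, return_counts=True)
    return patterns, counts


def _tip_partial(p_matrix: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Partial likelihood at a parent for a tip child across patterns.

    Returns (n_patterns, 61): row P[:, state] for observed states, ones for gaps.
    """
    out = np.ones((states.shape[0], N_CODONS))
    obs = states != GAP
    out[obs] = p_matrix[:, states[obs]].T
    return out


def prune(
    node,
    tip_states: dict[str, np.ndarray],
    p_of_branch: dict[str, np.ndarray],
    children_of: dict[str, tuple[str, ...]],
) -> np.ndarray:
    """Partial likelihoods (n_patterns, 61) at ``node`` (recursive)."""
    parts = None
    for child in children_of[node]:
        p = p_of_branch[child]
        if child in children_of:
            part = prune(child, tip_states, p_of_branch, children_of) @ p.T
        else:
            part = _tip_partial(p, tip_states[child])
        parts = part if parts is None else parts * part
    return parts


def log_likelihood(
    aln: CodonAlignment,
    tree: trees.SextupletTree,
    params: CodonModelParams,
    root: str = "n4",
) -> float:
    """Log-likelihood of a sextuplet alignment under the branch-class model.

    ``root`` ∈ {"n4", "n3"} selects the node at which the pruning recursion is
    anchored; reversibility makes the result root-invariant.
    """
    missing = set(trees.TIP_ROLES) - set(aln.labels)
    if missing:
        raise ValueError(f"alignment lacks required taxon roles: {sorted(missing)}")
    if root not in ("n4", "n3"):
        raise ValueError(f"root must be 'n4' or 'n3', got {root!r}")
    patterns, counts = compress_columns(aln, trees.TIP_ROLES)
    if np.all(patterns == GAP):
        raise ValueError("alignment contains only gap columns")
    cache = ClassMatrixCache(pi=params.codon_freqs)
    p_of_branch = {
        b: cache.get(params.kappa, params.omega_by_class[trees.CLASS_OF_BRANCH[b]]).transition_matrix(
            tree.branch_lengths[b]
        )
        for b in trees.BRANCHES
    }
    children = trees.CHILDREN_N4 if root == "n4" else trees.CHILDREN_N3
    if root == "n3":
        # the stem branch hangs the n4 subtree below n3; same P by reversibility
        p_of_branch = dict(p_of_branch)
        p_of_branch["n4"] = p_of_branch.pop("n3")
    tip_states = {role: patterns[trees.TIP_ROLES.index(role)] for role in trees.TIP_ROLES}
    partials = prune(root, tip_states, p_of_branch, children)
    site_lik = partials @ params.codon_freqs
    if np.any(site_lik <= 0) or not np.isfinite(site_lik).all():
        raise FloatingPointError("non-finite site likelihood")
    total = float(counts @ np.log(site_lik))
    if not np.isfinite(total):
        raise FloatingPointError("non-finite log-likelihood")
    return total
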