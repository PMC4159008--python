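"""Maximum-likelihood fitting of the five-class branch model.

The free parameters are the nine branch lengths, a shared
transition/transversion ratio κ and one ω per branch class (preD, ipostD1,
ipostD2, rpostD1, rpostD2); stationary codon frequencies are fixed at the
alignment's empirical F3x4 estimate.  Optimization is bounded quasi-Newton
(L-BFGS-B) on log-transformed parameters with a small number of deterministic
restarts from jittered starting points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import trees
from .alignment import CodonAlignment
from .codons import GAP, f3x4_frequencies
from .likelihood import compress_columns, prune
from .model import (
    OMEGA_CLASSES,
    OMEGA_MAX,
    OMEGA_MIN,
    ClassMatrixCache,
    CodonModelParams,
    dn_ds_from_branch,
)

T_MIN, T_MAX = 1e-8, 20.0
KAPPA_MIN, KAPPA_MAX = 0.05, 100.0
_START = {"t": 0.1, "kappa": 2.0, "omega": 0.4}
_LBFGSB_OPTS = {"maxiter": 2000, "maxfun": 40000, "ftol": 1e-10}


@dataclass
class BranchFit:
    """Result of the branch-class ML fit."""

    params: CodonModelParams
    tree: trees.SextupletTree
    log_likelihood: float
    per_branch_dnds: dict[str, tuple[float, float]]
    converged: bool
    n_restarts_used: int
    at_bound: tuple[str, ...] = ()

    def omega(self, cls: str) -> float:
        return self.params.omega_by_class[cls]


def _neg_loglik_factory(aln: CodonAlignment, pi: np.ndarray, single_omega: bool):
    patterns, counts = compress_columns(aln, trees.TIP_ROLES)
    if np.all(patterns == GAP):
        raise ValueError("alignment contains only gap columns")
    tips = {role: patterns[i] for i, role in enumerate(trees.TIP_ROLES)}
    cache = ClassMatrixCache(pi=pi)
    n_cls = 1 if single_omega else len(OMEGA_CLASSES)

    def neg_loglik(x: np.ndarray) -> float:
        t = np.exp(x[:9])
        kappa = float(np.exp(x[9]))
        omegas = np.exp(x[10 : 10 + n_cls])
        omega_of = {
            cls: float(omegas[0] if single_omega else omegas[k])
            for k, cls in enumerate(OMEGA_CLASSES)
        }
        try:
            p_of_branch = {
                b: cache.get(kappa, omega_of[trees.CLASS_OF_BRANCH[b]]).transition_matrix(
                    float(t[i])
                )
                for i, b in enumerate(trees.BRANCHES)
            }
            partials = prune("n4", tips, p_of_branch, trees.CHILDREN_N4)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        site = partials @ pi
        if not np.isfinite(site).all() or np.any(site <= 0):
            return 1e12
        return -float(counts @ np.log(site))

    return neg_loglik


def _bounds(n_cls: int) -> list[tuple[float, float]]:
    return (
        [(np.log(T_MIN), np.log(T_MAX))] * 9
        + [(np.log(KAPPA_MIN), np.log(KAPPA_MAX))]
        + [(np.log(OMEGA_MIN), np.log(OMEGA_MAX))] * n_cls
    )


def fit_branch_model(
    aln: CodonAlignment,
    n_restarts: int = 3,
    seed: int = 0,
    freq_model: str = "F3x4",
    single_omega: bool = False,
) -> BranchFit:
    """Fit branch lengths, κ and the five class ω values by ML.

    ``single_omega=True`` ties all classes to one ω (the one-ratio null model
    nested inside the five-class model).  ``freq_model`` is "F3x4" (empirical,
    default) or "uniform" (test convenience).  Restart jitter is deterministic
    in ``seed``.
    """
    missing = set(trees.TIP_ROLES) - set(aln.labels)
    if missing:
        raise ValueError(f"alignment lacks required taxon roles: {sorted(missing)}")
    if freq_model == "F3x4":
        pi = f3x4_frequencies(aln.codon_indices)
    elif freq_model == "uniform":
        pi = np.full(61, 1.0 / 61)
    else:
        raise ValueError(f"unknown freq_model {freq_model!r}")
    neg_loglik = _neg_loglik_factory(aln, pi, single_omega)
    n_cls = 1 if single_omega else len(OMEGA_CLASSES)
    x0 = np.log(
        np.concatenate([np.full(9, _START["t"]), [_START["kappa"]], np.full(n_cls, _START["omega"])])
    )
    bounds = _bounds(n_cls)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            start = x0
        else:
            rng = np.random.default_rng([seed, r])
            start = np.clip(
                x0 + rng.normal(0.0, 0.5, size=x0.size),
                [b[0] for b in bounds],
                [b[1] for b in bounds],
            )
        res = minimize(neg_loglik, start, method="L-BFGS-B", bounds=bounds, options=_LBFGSB_OPTS)
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    t = np.exp(x[:9])
    kappa = float(np.exp(x[9]))
    omegas = np.exp(x[10:])
    omega_by_class = {
        cls: float(omegas[0] if single_omega else omegas[k]) for k, cls in enumerate(OMEGA_CLASSES)
    }
    params = CodonModelParams(kappa=kappa, omega_by_class=omega_by_class, codon_freqs=pi)
    tree = trees.SextupletTree(branch_lengths={b: float(t[i]) for i, b in enumerate(trees.BRANCHES)})
    per_branch = {
        b: dn_ds_from_branch(tree.branch_lengths[b], omega_by_class[trees.CLASS_OF_BRANCH[b]], params)
        for b in trees.BRANCHES
    }
    at_bound = tuple(
        cls
        for cls, w in omega_by_class.items()
        if w <= OMEGA_MIN * (1 + 1e-6) or w >= OMEGA_MAX * (1 - 1e-6)
    )
    converged = bool(best.success) and np.isfinite(best.fun)
    return BranchFit(
        params=params,
        tree=tree,
        log_likelihood=-float(best.fun),
        per_branch_dnds=per_branch,
        converged=converged,
        n_restarts_used=max(1, n_restarts),
        at_bound=at_bound,
    )
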