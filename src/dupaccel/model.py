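"""Goldman–Yang-style codon substitution model with branch-class ω.

The instantaneous rate of change between sense codons i and j is zero unless
they differ at exactly one nucleotide position, in which case

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

with the diagonal set so rows sum to zero.  Each ω class's generator is
rescaled to one expected substitution per codon per unit branch length at
stationarity, so branch lengths are in substitutions per codon.  The model is
time-reversible, which lets transition probabilities be computed through the
eigendecomposition of the symmetrized generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .codons import N_CODONS, NONSYNONYMOUS, ONE_STEP, TRANSITION

OMEGA_CLASSES = ("preD", "ipostD1", "ipostD2", "rpostD1", "rpostD2")

OMEGA_MIN = 1e-6
OMEGA_MAX = 50.0


@dataclass
class CodonModelParams:
    """Parameters of the branch-class codon model.

    kappa           transition/transversion rate ratio (> 0)
    omega_by_class  dn/ds rate ratio per branch class (each >= 0)
    codon_freqs     stationary frequencies of the 61 sense codons
    genetic_code    identifier of the codon->amino-acid table (only the
                    standard code, id 1, is supported)
    """

    kappa: float
    omega_by_class: dict[str, float]
    codon_freqs: np.ndarray
    genetic_code: int = 1

    def __post_init__(self) -> None:
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        validate_params(self.kappa, self.omega_by_class, self.codon_freqs)
        if self.genetic_code != 1:
            raise ValueError("only the standard genetic code (id 1) is supported")


def validate_params(kappa: float, omega_by_class: dict[str, float], pi: np.ndarray) -> None:
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError(f"kappa must be finite and > 0, got {kappa}")
    for cls, w in omega_by_class.items():
        if not np.isfinite(w) or w < 0:
            raise ValueError(f"omega for class {cls!r} must be finite and >= 0, got {w}")
    if pi.shape != (N_CODONS,):
        raise ValueError(f"codon_freqs must have length {N_CODONS}, got {pi.shape}")
    if np.any(pi < 0) or not np.isfinite(pi).all():
        raise ValueError("codon_freqs must be finite and non-negative")
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError(f"codon_freqs must sum to 1 (off by {pi.sum() - 1.0:.2e})")


def _unnormalized_rates(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    q = np.where(ONE_STEP, np.broadcast_to(pi, (N_CODONS, N_CODONS)), 0.0).copy()
    q[TRANSITION] *= kappa
    q[NONSYNONYMOUS] *= omega
    return q


def build_rate_matrix(params: CodonModelParams, omega: float) -> np.ndarray:
    """61x61 generator for one ω class, scaled to unit substitution rate.

    Rows sum to zero; the expected number of substitutions per codon per unit
    time at stationarity equals one.
    """
    if not np.isfinite(omega) or omega < 0:
        raise ValueError(f"omega must be finite and >= 0, got {omega}")
    pi = params.codon_freqs
    q = _unnormalized_rates(pi, params.kappa, omega)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -float(pi @ np.diag(q))
    if rate <= 0:
        raise ValueError("degenerate rate matrix: zero total substitution rate")
    return q / rate


@dataclass
class EigenQ:
    """Eigendecomposition of a reversible generator, for fast P(t)."""

    eigvals: np.ndarray
    right: np.ndarray  # D^{-1/2} V
    left: np.ndarray  # V^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        p = (self.right * np.exp(self.eigvals * t)) @ self.left
        np.maximum(p, 0.0, out=p)
        return p


def decompose_rate_matrix(q: np.ndarray, pi: np.ndarray) -> EigenQ:
    """Symmetrize the reversible generator and eigendecompose it.

    With D = diag(pi), S = D^{1/2} Q D^{-1/2} is symmetric; exp(Qt) =
    D^{-1/2} exp(St) D^{1/2} computed through the spectral decomposition of S.
    """
    sq = np.sqrt(pi)
    s = (q * sq[:, None]) / sq[None, :]
    s = 0.5 * (s + s.T)  # remove round-off asymmetry
    vals, vecs = eigh(s)
    return EigenQ(eigvals=vals, right=vecs / sq[:, None], left=vecs.T * sq[None, :])


def transition_probabilities(q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt) for the reversible generator ``q``.

    ``pi`` is the stationary distribution; if omitted it is recovered from the
    generator's left null vector.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if pi is None:
        pi = stationary_distribution(q)
    return decompose_rate_matrix(q, pi).transition_matrix(t)


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(q.T)
    k = int(np.argmin(np.abs(vals)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def substitution_fractions(params: CodonModelParams, omega: float) -> tuple[float, float]:
    """Stationary fractions of substitutions that are nonsynonymous/synonymous."""
    q = _unnormalized_rates(params.codon_freqs, params.kappa, omega)
    flux = params.codon_freqs[:, None] * q
    total = flux[ONE_STEP].sum()
    rho_n = flux[ONE_STEP & NONSYNONYMOUS].sum() / total
    return rho_n, 1.0 - rho_n


def dn_ds_from_branch(t: float, omega: float, params: CodonModelParams) -> tuple[float, float]:
    """Decompose a branch length into (dn, ds) under the class's ω.

    Let rho_N, rho_S be the stationary fractions of substitutions that are
    nonsynonymous/synonymous under ω, and rho*_N, rho*_S the same fractions at
    ω = 1 (the mutational opportunity).  Then

        dn = t * rho_N / (3 * rho*_N),    ds = t * rho_S / (3 * rho*_S)

    which makes dn/ds equal ω identically — the convention by which branch-model
    codon fits report per-branch rates.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    rho_n, rho_s = substitution_fractions(params, omega)
    rho_n1, rho_s1 = substitution_fractions(params, 1.0)
    return t * rho_n / (3.0 * rho_n1), t * rho_s / (3.0 * rho_s1)


@dataclass
class ClassMatrixCache:
    """Per-fit cache of eigendecomposed class generators.

    During optimization most evaluations change a single parameter, so the
    generators of the untouched ω classes (and of unchanged κ) are identical
    float-for-float; caching on the exact (kappa, omega) key removes the
    redundant eigendecompositions.
    """

    pi: np.ndarray
    _cache: dict[tuple[float, float], EigenQ] = field(default_factory=dict)

    def get(self, kappa: float, omega: float) -> EigenQ:
        key = (kappa, omega)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if len(self._cache) > 512:
            self._cache.clear()
        params = CodonModelParams(kappa=kappa, omega_by_class={}, codon_freqs=self.pi)
        eq = decompose_rate_matrix(build_rate_matrix(params, omega), self.pi)
        self._cache[key] = eq
        return eq
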