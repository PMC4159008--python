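"""Pairwise dn/ds estimation: ML on a two-taxon tree, and NG86 counting.

The ML route fits (t, κ, ω) by maximum likelihood under the same codon model
as the branch fit, with empirical F3x4 frequencies from the two sequences, and
decomposes t into (dn, ds) by the stationary-flux convention — so ω̂ = dn/ds
identically.  The NG86 route is Nei–Gojobori (1986) site counting with
pathway-averaged difference counting and a Jukes–Cantor correction; it serves
as a fast cross-check on the ML estimates.

Columns where either sequence has a gap are discarded before estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import minimize

from . import codons
from .alignment import CodonAlignment
from .codons import GAP, SENSE_CODONS, f3x4_frequencies
from .model import (
    OMEGA_MAX,
    OMEGA_MIN,
    ClassMatrixCache,
    CodonModelParams,
    dn_ds_from_branch,
)
from .fitting import KAPPA_MAX, KAPPA_MIN, T_MAX, T_MIN, _LBFGSB_OPTS, _START


@dataclass
class PairwiseDnDs:
    """dn/ds for one sequence pair; ``omega`` is None when ds = 0."""

    pair: tuple[str, str]
    dn: float
    ds: float
    omega: float | None
    method: str  # "ML" | "NG86"
    t: float | None = None
    kappa: float | None = None
    log_likelihood: float | None = None
    saturated: bool = False
    n_codons: int = 0

    def __post_init__(self) -> None:
        if not self.saturated and (self.dn < 0 or self.ds < 0):
            raise ValueError("dn and ds must be non-negative")


def _gapfree_rows(aln_or_pair, a: str | None = None, b: str | None = None):
    if isinstance(aln_or_pair, CodonAlignment):
        sub = aln_or_pair.subset([a, b])
        ra, rb = sub.codon_indices
        labels = (a, b)
    else:
        ra, rb = aln_or_pair
        labels = ("seq1", "seq2")
    keep = (ra != GAP) & (rb != GAP)
    if not keep.any():
        raise ValueError(f"no gap-free codon columns for pair {labels}")
    return ra[keep], rb[keep], labels


def pairwise_dnds_ml(
    a: np.ndarray | str,
    b: np.ndarray | str,
    pair: tuple[str, str] = ("seq1", "seq2"),
    n_restarts: int = 3,
    seed: int = 0,
) -> PairwiseDnDs:
    """ML (t, κ, ω) fit for two in-frame codon sequences.

    Accepts codon-index arrays or nucleotide strings.  Identical sequences
    short-circuit to dn = ds = 0 with ω undefined.
    """
    ra = _as_indices(a)
    rb = _as_indices(b)
    if ra.shape != rb.shape:
        raise ValueError("sequences must have equal codon length")
    keep = (ra != GAP) & (rb != GAP)
    if not keep.any():
        raise ValueError(f"no gap-free codon columns for pair {pair}")
    ra, rb = ra[keep], rb[keep]
    n = int(ra.size)
    pi = f3x4_frequencies(np.stack([ra, rb]))
    if np.array_equal(ra, rb):
        return PairwiseDnDs(pair=pair, dn=0.0, ds=0.0, omega=None, method="ML", t=0.0, n_codons=n)

    pairs = ra * 61 + rb
    uniq, counts = np.unique(pairs, return_counts=True)
    ia, ib = uniq // 61, uniq % 61
    cache = ClassMatrixCache(pi=pi)
    log_pi = np.log(pi)

    def neg_loglik(x: np.ndarray) -> float:
        t, kappa, omega = np.exp(x)
        try:
            p = cache.get(float(kappa), float(omega)).transition_matrix(float(t))
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        lik = p[ia, ib]
        if np.any(lik <= 0) or not np.isfinite(lik).all():
            return 1e12
        return -float(counts @ (log_pi[ia] + np.log(lik)))

    bounds = [
        (np.log(T_MIN), np.log(T_MAX)),
        (np.log(KAPPA_MIN), np.log(KAPPA_MAX)),
        (np.log(OMEGA_MIN), np.log(OMEGA_MAX)),
    ]
    x0 = np.log([_START["t"], _START["kappa"], _START["omega"]])
    best = None
    for r in range(max(1, n_restarts)):
        start = x0
        if r > 0:
            rng = np.random.default_rng([seed, r])
            start = np.clip(
                x0 + rng.normal(0.0, 0.5, size=3), [b[0] for b in bounds], [b[1] for b in bounds]
            )
        res = minimize(neg_loglik, start, method="L-BFGS-B", bounds=bounds, options=_LBFGSB_OPTS)
        if best is None or res.fun < best.fun:
            best = res
    t, kappa, omega = (float(v) for v in np.exp(best.x))
    params = CodonModelParams(kappa=kappa, omega_by_class={}, codon_freqs=pi)
    dn, ds = dn_ds_from_branch(t, omega, params)
    return PairwiseDnDs(
        pair=pair,
        dn=dn,
        ds=ds,
        omega=(None if ds == 0 else omega),
        method="ML",
        t=t,
        kappa=kappa,
        log_likelihood=-float(best.fun),
        n_codons=n,
    )


def _as_indices(seq) -> np.ndarray:
    if isinstance(seq, str):
        return CodonAlignment.from_sequences({"x": seq}).codon_indices[0]
    return np.asarray(seq)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

_PURINE = {"A", "G"}
_PYRIMIDINE = {"C", "T"}


def _aa(codon: str) -> str | None:
    """Amino acid of a codon, None for a stop (never synonymous)."""
    return None if codon in codons.STOP_CODONS else codons.translate_codon(codon)


def _site_counts() -> np.ndarray:
    """(61, 2) synonymous/nonsynonymous site counts per codon, normalized to 3."""
    out = np.zeros((len(SENSE_CODONS), 2))
    for i, codon in enumerate(SENSE_CODONS):
        s = n = 0.0
        for pos in range(3):
            for nuc in codons.NUCS:
                if nuc == codon[pos]:
                    continue
                mutant = codon[:pos] + nuc + codon[pos + 1 :]
                if mutant in codons.STOP_CODONS or _aa(mutant) != codons.AMINO_ACID[i]:
                    n += 1.0
                else:
                    s += 1.0
        out[i] = (3.0 * s / (s + n), 3.0 * n / (s + n))
    return out


_SITES = _site_counts()


def _diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0

    def step(x: str, y: str, w: float) -> tuple[float, float]:
        ax, ay = _aa(x), _aa(y)
        return (w, 0.0) if ax is not None and ax == ay else (0.0, w)

    sd = nd = 0.0
    if len(diff) == 1:
        sd, nd = step(c1, c2, 1.0)
    elif len(diff) == 2:
        for p in diff:
            mid = c1[:p] + c2[p] + c1[p + 1 :]
            for s, n in (step(c1, mid, 0.5), step(mid, c2, 0.5)):
                sd += s
                nd += n
    else:
        # 6 pathways x 3 steps, each step weighted 1/6 (total differences = 3)
        for path in permutations(diff):
            cur = c1
            for p in path:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                s, n = step(cur, nxt, 1.0 / 6.0)
                sd += s
                nd += n
                cur = nxt
    return sd, nd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0), False


def ng86_dnds(
    a: np.ndarray | str,
    b: np.ndarray | str,
    pair: tuple[str, str] = ("seq1", "seq2"),
) -> PairwiseDnDs:
    """Nei–Gojobori (1986) dn/ds with Jukes–Cantor correction.

    Site counts are averaged over the two sequences; mutations to stop codons
    count as nonsynonymous and pathways are averaged with equal weight.  A
    proportion of differences ≥ 3/4 cannot be corrected and is returned with
    ``saturated=True`` (dn/ds NaN as applicable) rather than raising.
    """
    ra = _as_indices(a)
    rb = _as_indices(b)
    if ra.shape != rb.shape:
        raise ValueError("sequences must have equal codon length")
    keep = (ra != GAP) & (rb != GAP)
    if not keep.any():
        raise ValueError(f"no gap-free codon columns for pair {pair}")
    ra, rb = ra[keep], rb[keep]
    s_sites = 0.5 * (_SITES[ra, 0].sum() + _SITES[rb, 0].sum())
    n_sites = 0.5 * (_SITES[ra, 1].sum() + _SITES[rb, 1].sum())
    sd = nd = 0.0
    for i, j in zip(ra, rb):
        if i != j:
            s, n = _diff_counts(SENSE_CODONS[i], SENSE_CODONS[j])
            sd += s
            nd += n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds, sat_s = _jukes_cantor(ps)
    dn, sat_n = _jukes_cantor(pn)
    saturated = sat_s or sat_n
    omega: float | None
    if saturated or ds == 0:
        omega = None
    else:
        omega = dn / ds
    return PairwiseDnDs(
        pair=pair,
        dn=dn,
        ds=ds,
        omega=omega,
        method="NG86",
        saturated=saturated,
        n_codons=int(ra.size),
    )
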