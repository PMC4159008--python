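"""Post-duplication rate statistics.

δ measures the difference between the recent postduplication and the
preduplication rate of protein evolution:

    δ_f = max(rpostD1, rpostD2) − preD       (fast copy)
    δ_s = min(rpostD1, rpostD2) − preD       (slow copy)

and, for the branch-model fit only, the analogous differences for the initial
internal branches (δ_if for the branch leading up to the fast recent branch,
δ_is for the slow one).  The pairwise variant replaces the class estimates by
O = dn/ds(C–D), P1 = dn/ds(M1–R1), P2 = dn/ds(M2–R2).  Duplication age is the
synonymous divergence between the paralogs, used as a proxy for time.

This module also provides the age binning, the paralog-ds gene-conversion
diagnostic, synteny-based original/novel classification, the exact test for
whether the fast copy tends to be the novel copy, and per-lineage summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import BranchFit
from .pairwise import PairwiseDnDs
from .set_builder import SextupletSet


@dataclass
class DuplicationRecord:
    """Per-set δ statistics; ``flagged`` records are excluded from summaries."""

    set_id: str
    delta_f: float
    delta_s: float
    age: float
    method: str  # "ML" | "pairwise"
    lineage: str = "synthetic"
    delta_if: float | None = None
    delta_is: float | None = None
    fast_copy: str | None = None  # "copy1" | "copy2"
    originality: dict[str, str] | None = None
    flagged: bool = False
    flag_reason: str = ""

    def __post_init__(self) -> None:
        if not self.flagged:
            if self.delta_f < self.delta_s - 1e-12:
                raise ValueError("delta_f must be >= delta_s")
            if self.age < 0:
                raise ValueError("age must be >= 0")


def duplication_age_ml(fit: BranchFit) -> float:
    """Mean over species of the per-branch ds summed along the paralog paths.

    The mouse path M1–n1–n3–n2–M2 and the rat path R1–n1–n3–n2–R2 each sum
    four branch ds values (the duplication node n3 joins n1 and n2 directly).
    """
    ds = {b: v[1] for b, v in fit.per_branch_dnds.items()}
    mouse = ds["M1"] + ds["n1"] + ds["n2"] + ds["M2"]
    rat = ds["R1"] + ds["n1"] + ds["n2"] + ds["R2"]
    for v in (mouse, rat):
        if v < 0:
            raise ValueError("negative path ds")
    return 0.5 * (mouse + rat)


def duplication_age_pairwise(ds_m1m2: float, ds_r1r2: float) -> float:
    """Mean of the two paralog synonymous divergences."""
    if ds_m1m2 < 0 or ds_r1r2 < 0:
        raise ValueError("negative ds")
    return 0.5 * (ds_m1m2 + ds_r1r2)


def compute_deltas_ml(fit: BranchFit, set_id: str = "", lineage: str = "synthetic") -> DuplicationRecord:
    """δ statistics from a branch-class ML fit.

    The fast copy is the one whose recent class ω is larger; δ_if uses the
    initial internal branch leading up to that copy's recent branches
    (ipostD1 for copy 1), δ_is the other.
    """
    if not fit.converged:
        return DuplicationRecord(
            set_id=set_id,
            delta_f=np.nan,
            delta_s=np.nan,
            age=np.nan,
            method="ML",
            lineage=lineage,
            flagged=True,
            flag_reason="unconverged fit",
        )
    w = fit.params.omega_by_class
    fast_is_1 = w["rpostD1"] >= w["rpostD2"]
    fast_copy = "copy1" if fast_is_1 else "copy2"
    delta_f = max(w["rpostD1"], w["rpostD2"]) - w["preD"]
    delta_s = min(w["rpostD1"], w["rpostD2"]) - w["preD"]
    ipost_f = w["ipostD1"] if fast_is_1 else w["ipostD2"]
    ipost_s = w["ipostD2"] if fast_is_1 else w["ipostD1"]
    return DuplicationRecord(
        set_id=set_id,
        delta_f=delta_f,
        delta_s=delta_s,
        delta_if=ipost_f - w["preD"],
        delta_is=ipost_s - w["preD"],
        age=duplication_age_ml(fit),
        method="ML",
        lineage=lineage,
        fast_copy=fast_copy,
    )


def compute_deltas_pairwise(
    comparisons: dict[str, PairwiseDnDs], set_id: str = "", lineage: str = "synthetic"
) -> DuplicationRecord:
    """δ statistics from the five-comparison design.

    ``comparisons`` maps "C-D", "M1-R1", "M2-R2", "M1-M2", "R1-R2" to
    pairwise estimates.  δ_if/δ_is are undefined for this method (internal
    branches are never estimated).  Any comparison with undefined ω (ds = 0)
    or saturation flags the record.
    """
    required = ("C-D", "M1-R1", "M2-R2", "M1-M2", "R1-R2")
    missing = [c for c in required if c not in comparisons]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    bad = [
        c
        for c in ("C-D", "M1-R1", "M2-R2")
        if comparisons[c].omega is None or comparisons[c].saturated
    ]
    bad += [c for c in ("M1-M2", "R1-R2") if comparisons[c].saturated]
    if bad:
        return DuplicationRecord(
            set_id=set_id,
            delta_f=np.nan,
            delta_s=np.nan,
            age=np.nan,
            method="pairwise",
            lineage=lineage,
            flagged=True,
            flag_reason=f"undefined omega or saturation in {';'.join(bad)}",
        )
    o = comparisons["C-D"].omega
    p1 = comparisons["M1-R1"].omega
    p2 = comparisons["M2-R2"].omega
    return DuplicationRecord(
        set_id=set_id,
        delta_f=max(p1, p2) - o,
        delta_s=min(p1, p2) - o,
        age=duplication_age_pairwise(comparisons["M1-M2"].ds, comparisons["R1-R2"].ds),
        method="pairwise",
        lineage=lineage,
        fast_copy="copy1" if p1 >= p2 else "copy2",
    )


_RECORD_COLUMNS = (
    "set_id", "method", "lineage", "age", "delta_f", "delta_s",
    "delta_if", "delta_is", "fast_copy", "flagged", "flag_reason",
)


def records_to_frame(records: list[DuplicationRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=list(_RECORD_COLUMNS))
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "method": r.method,
                "lineage": r.lineage,
                "age": r.age,
                "delta_f": r.delta_f,
                "delta_s": r.delta_s,
                "delta_if": r.delta_if,
                "delta_is": r.delta_is,
                "fast_copy": r.fast_copy,
                "flagged": r.flagged,
                "flag_reason": r.flag_reason,
            }
            for r in records
        ]
    )


@dataclass
class BinSummary:
    """Mean δ_f / δ_s over records whose age falls in one half-open bin."""

    lo: float
    hi: float
    n: int
    mean_delta_f: float
    mean_delta_s: float
    se_delta_f: float
    se_delta_s: float
    mean_age: float


def bin_deltas(
    records: list[DuplicationRecord], bin_edges: np.ndarray | list[float]
) -> tuple[list[BinSummary], int]:
    """Bin records by duplication age (half-open bins [lo, hi)).

    Flagged records are excluded; records outside all bins are dropped and
    counted.  SE is sample SD / sqrt(n), NaN for n < 2.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    usable = [r for r in records if not r.flagged]
    out = []
    n_outside = 0
    ages = np.array([r.age for r in usable])
    which = np.digitize(ages, edges) - 1  # bin index, -1/left or n-1/right = outside
    n_outside = int(np.sum((which < 0) | (which >= edges.size - 1) | (ages >= edges[-1])))
    for b in range(edges.size - 1):
        sel = [r for r, w in zip(usable, which) if w == b and r.age < edges[-1]]
        df = np.array([r.delta_f for r in sel])
        dsl = np.array([r.delta_s for r in sel])
        n = len(sel)
        out.append(
            BinSummary(
                lo=float(edges[b]),
                hi=float(edges[b + 1]),
                n=n,
                mean_delta_f=float(df.mean()) if n else np.nan,
                mean_delta_s=float(dsl.mean()) if n else np.nan,
                se_delta_f=float(df.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                se_delta_s=float(dsl.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                mean_age=float(ages[[w == b for w in which]].mean()) if n else np.nan,
            )
        )
    return out, n_outside


def bins_to_frame(bins: list[BinSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lo": b.lo,
                "hi": b.hi,
                "n": b.n,
                "mean_age": b.mean_age,
                "mean_delta_f": b.mean_delta_f,
                "se_delta_f": b.se_delta_f,
                "mean_delta_s": b.mean_delta_s,
                "se_delta_s": b.se_delta_s,
            }
            for b in bins
        ]
    )


@dataclass
class ConversionDiagnostic:
    """Correlation of paralog ds between sister species + per-set outliers."""

    r: float
    p: float
    n: int
    outlier: np.ndarray  # boolean per set
    slope: float
    intercept: float


def gene_conversion_check(
    ds_mouse_paralogs: np.ndarray | list[float],
    ds_rat_paralogs: np.ndarray | list[float],
    ratio_threshold: float = 0.5,
) -> ConversionDiagnostic:
    """Gene conversion deflates paralog ds in the converted species only.

    Computes the Pearson correlation of ds(M1–M2) versus ds(R1–R2) across
    sets; under duplication-wide divergence (no conversion) the two track each
    other closely.  A set is flagged as a conversion candidate when either
    species' paralog ds falls below ``ratio_threshold`` times the major-axis
    (standardized major axis) prediction from the other species.
    """
    x = np.asarray(ds_mouse_paralogs, dtype=float)
    y = np.asarray(ds_rat_paralogs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired ds vectors required")
    if x.size < 3:
        raise ValueError("need at least 3 paired sets for the correlation")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        r, p = 1.0, 0.0
    else:
        r, p = stats.pearsonr(x, y)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    slope = (sy / sx if sx > 0 else np.nan) * (1.0 if r >= 0 else -1.0)
    intercept = y.mean() - slope * x.mean()
    pred_y = slope * x + intercept
    pred_x = (y - intercept) / slope if slope else np.full_like(x, np.nan)
    with np.errstate(invalid="ignore"):
        outlier = (y < ratio_threshold * pred_y) | (x < ratio_threshold * pred_x)
    return ConversionDiagnostic(
        r=float(r), p=float(p), n=int(x.size), outlier=outlier, slope=float(slope), intercept=float(intercept)
    )


def classify_old_new(
    sset: SextupletSet,
    synteny: dict[str, list[str]],
    window: int = 3,
    min_matches: int = 2,
) -> dict[str, str]:
    """Label the paralog in the ancestral genomic position as the original.

    The copy whose flanking neighbors (``window`` per side) share at least
    ``min_matches`` genes with the dog gene's neighborhood is the original;
    the other is novel.  Both or neither matching gives "unresolved" for both
    copies, and tandem duplicates (each paralog inside the other's
    neighborhood) are excluded as "tandem".
    """
    dog, m1, m2 = sset.genes["D"], sset.genes["M1"], sset.genes["M2"]
    unresolved = {"M1": "unresolved", "M2": "unresolved"}
    if dog not in synteny or m1 not in synteny or m2 not in synteny:
        return unresolved
    nb = {g: set(synteny[g][: 2 * window]) for g in (dog, m1, m2)}
    if m2 in nb[m1] or m1 in nb[m2]:
        return {"M1": "tandem", "M2": "tandem"}
    match1 = len(nb[m1] & nb[dog]) >= min_matches
    match2 = len(nb[m2] & nb[dog]) >= min_matches
    if match1 == match2:
        return unresolved
    if match1:
        return {"M1": "original", "M2": "novel"}
    return {"M1": "novel", "M2": "original"}


@dataclass
class NovelFastResult:
    n_fast_novel: int
    n_total: int
    fraction: float
    p_value: float


def novel_fast_test(n_fast_novel: int, n_total: int) -> NovelFastResult:
    """Exact one-sided binomial test that the fast copy tends to be the novel copy.

    Null: the fast-evolving copy is equally likely to be the original or the
    novel copy (p = 1/2); alternative: novel more often fast.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_fast_novel <= n_total:
        raise ValueError("n_fast_novel must be between 0 and n_total")
    res = stats.binomtest(n_fast_novel, n_total, p=0.5, alternative="greater")
    return NovelFastResult(
        n_fast_novel=n_fast_novel,
        n_total=n_total,
        fraction=n_fast_novel / n_total,
        p_value=float(res.pvalue),
    )


def summarize_by_lineage(records: list[DuplicationRecord]) -> pd.DataFrame:
    """Mean (SE) of δ_f and δ_s per lineage group, unflagged records only."""
    usable = [r for r in records if not r.flagged]
    rows = []
    for lineage in sorted({r.lineage for r in usable}):
        grp = [r for r in usable if r.lineage == lineage]
        df = np.array([r.delta_f for r in grp])
        dsl = np.array([r.delta_s for r in grp])
        n = len(grp)
        rows.append(
            {
                "lineage": lineage,
                "n": n,
                "mean_delta_f": df.mean(),
                "se_delta_f": df.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "mean_delta_s": dsl.mean(),
                "se_delta_s": dsl.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
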