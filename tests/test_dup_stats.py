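"""δ statistics, binning, diagnostics, synteny classification, exact test."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from dupaccel import bin_deltas, classify_old_new, gene_conversion_check, novel_fast_test
from dupaccel.dup_stats import (
    DuplicationRecord,
    compute_deltas_ml,
    compute_deltas_pairwise,
    duplication_age_ml,
    duplication_age_pairwise,
    summarize_by_lineage,
)
from dupaccel.fitting import BranchFit
from dupaccel.model import CodonModelParams, OMEGA_CLASSES
from dupaccel.pairwise import PairwiseDnDs
from dupaccel.set_builder import SextupletSet
from dupaccel.simulate import default_codon_freqs, make_synteny_fixture
from dupaccel.trees import BRANCHES, CLASS_OF_BRANCH, SextupletTree


def _fit(omegas: dict[str, float], branch_ds: dict[str, float] | None = None) -> BranchFit:
    """Assemble a BranchFit with prescribed class omegas and per-branch ds."""
    params = CodonModelParams(kappa=2.0, omega_by_class=dict(omegas), codon_freqs=default_codon_freqs())
    lengths = {b: 0.1 for b in BRANCHES}
    tree = SextupletTree(branch_lengths=lengths)
    ds = branch_ds or {b: 0.05 for b in BRANCHES}
    per_branch = {b: (ds[b] * omegas[CLASS_OF_BRANCH[b]], ds[b]) for b in BRANCHES}
    return BranchFit(
        params=params,
        tree=tree,
        log_likelihood=-100.0,
        per_branch_dnds=per_branch,
        converged=True,
        n_restarts_used=1,
    )


OMEGAS_A = {"preD": 0.15, "ipostD1": 0.40, "ipostD2": 0.30, "rpostD1": 0.30, "rpostD2": 0.10}


class TestMlDeltas:
    def test_direct_arithmetic(self):
        rec = compute_deltas_ml(_fit(OMEGAS_A), set_id="x")
        assert rec.delta_f == pytest.approx(0.15)
        assert rec.delta_s == pytest.approx(-0.05)
        assert rec.fast_copy == "copy1"
        assert rec.delta_if == pytest.approx(0.40 - 0.15)  # ipostD1 goes with the fast copy
        assert rec.delta_is == pytest.approx(0.30 - 0.15)

    def test_tied_recent_classes(self):
        omegas = dict(OMEGAS_A, rpostD1=0.2, rpostD2=0.2)
        rec = compute_deltas_ml(_fit(omegas))
        assert rec.delta_f == rec.delta_s

    def test_sum_identity(self):
        """delta_f + delta_s == (rpostD1 + rpostD2) - 2 preD, exactly."""
        rec = compute_deltas_ml(_fit(OMEGAS_A))
        expected = OMEGAS_A["rpostD1"] + OMEGAS_A["rpostD2"] - 2 * OMEGAS_A["preD"]
        assert rec.delta_f + rec.delta_s == pytest.approx(expected, abs=1e-12)

    def test_copy_relabeling_invariance(self):
        """Swapping copy 1 <-> copy 2 (classes and branches) leaves all four
        delta statistics unchanged."""
        swapped = {
            "preD": OMEGAS_A["preD"],
            "ipostD1": OMEGAS_A["ipostD2"],
            "ipostD2": OMEGAS_A["ipostD1"],
            "rpostD1": OMEGAS_A["rpostD2"],
            "rpostD2": OMEGAS_A["rpostD1"],
        }
        a = compute_deltas_ml(_fit(OMEGAS_A))
        b = compute_deltas_ml(_fit(swapped))
        assert (a.delta_f, a.delta_s, a.delta_if, a.delta_is) == (
            b.delta_f,
            b.delta_s,
            b.delta_if,
            b.delta_is,
        )
        assert a.fast_copy != b.fast_copy

    def test_unconverged_fit_flagged(self):
        fit = _fit(OMEGAS_A)
        fit.converged = False
        rec = compute_deltas_ml(fit)
        assert rec.flagged and "unconverged" in rec.flag_reason


def _pw(ds, omega, pair=("a", "b"), saturated=False):
    return PairwiseDnDs(
        pair=pair,
        dn=(0.0 if omega is None else omega * ds),
        ds=ds,
        omega=omega,
        method="NG86",
        saturated=saturated,
    )


def _five(o, p1, p2, age1=0.3, age2=0.3):
    return {
        "C-D": _pw(0.4, o),
        "M1-R1": _pw(0.2, p1),
        "M2-R2": _pw(0.2, p2),
        "M1-M2": _pw(age1, 0.1),
        "R1-R2": _pw(age2, 0.1),
    }


class TestPairwiseDeltas:
    def test_direct_arithmetic(self):
        rec = compute_deltas_pairwise(_five(0.2, 0.5, 0.2))
        assert rec.delta_f == pytest.approx(0.3)
        assert rec.delta_s == pytest.approx(0.0)
        assert rec.delta_if is None and rec.delta_is is None

    def test_identical_rates(self):
        rec = compute_deltas_pairwise(_five(0.3, 0.3, 0.3))
        assert rec.delta_f == rec.delta_s == pytest.approx(0.0)

    def test_age_is_mean_paralog_ds(self):
        rec = compute_deltas_pairwise(_five(0.2, 0.5, 0.2, age1=0.28, age2=0.32))
        assert rec.age == pytest.approx(0.30)

    def test_undefined_omega_flags_record(self):
        comps = _five(0.2, 0.5, 0.2)
        comps["C-D"] = _pw(0.0, None)
        rec = compute_deltas_pairwise(comps)
        assert rec.flagged


class TestDuplicationAge:
    def test_zero_branches(self):
        rec = compute_deltas_ml(_fit(OMEGAS_A, branch_ds={b: 0.0 for b in BRANCHES}))
        assert rec.age == 0.0

    def test_path_sum_arithmetic(self):
        # mouse path ds = 0.28, rat path ds = 0.32 -> age 0.30
        ds = {b: 0.0 for b in BRANCHES}
        ds.update({"M1": 0.10, "M2": 0.10, "n1": 0.05, "n2": 0.03})  # mouse: 0.28
        ds.update({"R1": 0.14, "R2": 0.10})  # rat: 0.14+0.05+0.03+0.10 = 0.32
        fit = _fit(OMEGAS_A, branch_ds=ds)
        assert duplication_age_ml(fit) == pytest.approx(0.30)

    def test_pairwise_age(self):
        assert duplication_age_pairwise(0.28, 0.32) == pytest.approx(0.30)
        with pytest.raises(ValueError):
            duplication_age_pairwise(-0.1, 0.3)


def _rec(set_id, delta_f, delta_s, age, lineage="synthetic", flagged=False):
    return DuplicationRecord(
        set_id=set_id, delta_f=delta_f, delta_s=delta_s, age=age, method="ML",
        lineage=lineage, flagged=flagged,
    )


class TestBinning:
    def test_single_record_lands_in_bin(self):
        bins, outside = bin_deltas([_rec("a", 0.1, 0.0, age=0.15)], [0.1, 0.2])
        assert bins[0].n == 1 and outside == 0

    def test_mean_and_se(self):
        recs = [_rec("a", 0.1, 0.0, 0.15), _rec("b", 0.2, 0.0, 0.18)]
        bins, _ = bin_deltas(recs, [0.1, 0.2])
        assert bins[0].mean_delta_f == pytest.approx(0.15)
        assert bins[0].se_delta_f == pytest.approx(0.05)

    def test_half_open_edges_and_outside_count(self):
        recs = [_rec("a", 0.1, 0.0, 0.2), _rec("b", 0.1, 0.0, 0.3), _rec("c", 0.1, 0.0, 0.05)]
        bins, outside = bin_deltas(recs, [0.1, 0.2, 0.3])
        assert bins[1].n == 1  # age 0.2 in [0.2, 0.3)
        assert outside == 2  # age 0.3 beyond last edge; 0.05 below first

    def test_flagged_records_excluded(self):
        recs = [_rec("a", 0.1, 0.0, 0.15), _rec("b", np.nan, np.nan, np.nan, flagged=True)]
        bins, _ = bin_deltas(recs, [0.1, 0.2])
        assert bins[0].n == 1

    def test_single_record_bin_has_undefined_se(self):
        bins, _ = bin_deltas([_rec("a", 0.1, 0.0, 0.15)], [0.1, 0.2])
        assert np.isnan(bins[0].se_delta_f)


class TestGeneConversionCheck:
    def test_identical_vectors_fully_correlated(self):
        x = [0.1, 0.2, 0.3, 0.4]
        diag = gene_conversion_check(x, x)
        assert diag.r == pytest.approx(1.0)
        assert not diag.outlier.any()

    def test_too_few_sets_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            gene_conversion_check([0.1, 0.2], [0.1, 0.2])

    def test_converted_set_is_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 0.6, size=20)
        y = x + rng.normal(0, 0.01, size=20)
        y[7] = 0.02  # whole-gene conversion in the rat lineage deflates ds
        diag = gene_conversion_check(x, y)
        assert diag.outlier[7]
        assert diag.outlier.sum() == 1


class TestClassifyOldNew:
    def _set(self, truth_row):
        return SextupletSet(
            genes={
                "C": "cowZ", "D": truth_row.dog,
                "M1": truth_row.copy1, "M2": truth_row.copy2,
                "R1": "ratZ1", "R2": "ratZ2",
            },
            source_cluster=truth_row.set_id,
        )

    def test_planted_truth_recovered(self):
        neighbors, truth = make_synteny_fixture(n_sets=26, frac_original_first=0.5, seed=12)
        for row in truth.itertuples():
            cls = classify_old_new(self._set(row), neighbors)
            original = "M1" if row.original == row.copy1 else "M2"
            novel = "M2" if original == "M1" else "M1"
            assert cls[original] == "original" and cls[novel] == "novel"

    def test_shuffled_neighborhoods_unresolved(self):
        neighbors, truth = make_synteny_fixture(n_sets=2, seed=3, n_unresolved=2)
        for row in truth.itertuples():
            cls = classify_old_new(self._set(row), neighbors)
            assert cls == {"M1": "unresolved", "M2": "unresolved"}

    def test_tandem_duplicates_excluded(self):
        neighbors, truth = make_synteny_fixture(n_sets=1, seed=4, n_tandem=1)
        row = next(truth.itertuples())
        assert classify_old_new(self._set(row), neighbors) == {"M1": "tandem", "M2": "tandem"}

    def test_missing_neighbor_data_unresolved(self):
        _, truth = make_synteny_fixture(n_sets=1, seed=5)
        row = next(truth.itertuples())
        assert classify_old_new(self._set(row), {}) == {"M1": "unresolved", "M2": "unresolved"}


def exact_binomial_tail(k: int, n: int) -> Fraction:
    """Oracle: rational-arithmetic upper tail P(X >= k), X ~ Binomial(n, 1/2)."""
    return Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2**n)


class TestNovelFastTest:
    def test_matches_rational_oracle_to_1e12(self):
        for n in range(1, 31):
            for k in range(n + 1):
                expected = float(exact_binomial_tail(k, n))
                got = novel_fast_test(k, n).p_value
                assert got == pytest.approx(expected, abs=1e-12), (k, n)

    def test_null_expectation_not_significant(self):
        assert novel_fast_test(13, 26).p_value > 0.5

    def test_perfect_enrichment_closed_form(self):
        assert novel_fast_test(26, 26).p_value == pytest.approx(2.0**-26, rel=1e-12)

    def test_observed_style_counts(self):
        """21 fast-novel of 26: exact one-sided p = 83,682 / 2^26 ~ 1.247e-3."""
        res = novel_fast_test(21, 26)
        assert exact_binomial_tail(21, 26) == Fraction(83_682, 67_108_864)
        assert res.p_value == pytest.approx(83_682 / 67_108_864, rel=1e-12)
        assert res.fraction == pytest.approx(21 / 26)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            novel_fast_test(5, 0)
        with pytest.raises(ValueError):
            novel_fast_test(7, 5)


class TestLineageSummary:
    def test_mean_and_se(self):
        recs = [
            _rec("a", 0.1, -0.02, 0.2, lineage="rodent"),
            _rec("b", 0.2, 0.02, 0.3, lineage="rodent"),
        ]
        out = summarize_by_lineage(recs)
        row = out[out["lineage"] == "rodent"].iloc[0]
        assert row["mean_delta_f"] == pytest.approx(0.15)
        assert row["se_delta_f"] == pytest.approx(0.05)

    def test_single_record_group(self):
        out = summarize_by_lineage([_rec("a", 0.1, 0.0, 0.2, lineage="primate")])
        row = out.iloc[0]
        assert row["mean_delta_f"] == pytest.approx(0.1)
        assert np.isnan(row["se_delta_f"])

    def test_flagged_records_excluded(self):
        recs = [
            _rec("a", 0.1, 0.0, 0.2, lineage="rodent"),
            _rec("b", np.nan, np.nan, np.nan, lineage="rodent", flagged=True),
        ]
        assert summarize_by_lineage(recs).iloc[0]["n"] == 1
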