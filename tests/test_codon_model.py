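"""Rate matrix, transition probabilities and the dn/ds decomposition."""

import numpy as np
import pytest
from Bio.Seq import Seq

from dupaccel.codons import CODON_INDEX, SENSE_CODONS, STOP_CODONS
from dupaccel.model import (
    CodonModelParams,
    build_rate_matrix,
    dn_ds_from_branch,
    substitution_fractions,
    transition_probabilities,
)

from conftest import random_model_params


def _params(kappa, omega, pi):
    return CodonModelParams(kappa=kappa, omega_by_class={"x": omega}, codon_freqs=pi)


class TestRateMatrix:
    def test_rows_sum_to_zero(self, uniform_params):
        q = build_rate_matrix(uniform_params, 0.5)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_multistep_entries_are_zero(self, uniform_params):
        q = build_rate_matrix(uniform_params, 0.5)
        assert q[CODON_INDEX["AAA"], CODON_INDEX["ACC"]] == 0.0

    def test_transition_vs_transversion_entry_ratio(self, uniform_params):
        # AAA->AAG is a synonymous transition, AAA->AAC a nonsynonymous
        # transversion: with uniform pi the ratio is kappa/omega = 2/0.5 = 4,
        # independent of the overall normalization.
        q = build_rate_matrix(uniform_params, 0.5)
        ratio = q[CODON_INDEX["AAA"], CODON_INDEX["AAG"]] / q[CODON_INDEX["AAA"], CODON_INDEX["AAC"]]
        assert ratio == pytest.approx(4.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_detailed_balance(self, seed):
        kappa, omega, pi = random_model_params(np.random.default_rng(seed))
        q = build_rate_matrix(_params(kappa, omega, pi), omega)
        flux = pi[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_unit_substitution_rate(self, cohort_params):
        q = build_rate_matrix(cohort_params, 0.25)
        assert -float(cohort_params.codon_freqs @ np.diag(q)) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_parameters_rejected(self, uniform_params):
        with pytest.raises(ValueError):
            build_rate_matrix(uniform_params, -0.1)
        with pytest.raises(ValueError):
            CodonModelParams(kappa=-1.0, omega_by_class={}, codon_freqs=uniform_params.codon_freqs)
        with pytest.raises(ValueError):
            CodonModelParams(kappa=2.0, omega_by_class={}, codon_freqs=np.full(61, 0.5))


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, cohort_params):
        q = build_rate_matrix(cohort_params, 0.4)
        p = transition_probabilities(q, 0.0, cohort_params.codon_freqs)
        assert np.abs(p - np.eye(61)).max() < 1e-12

    @pytest.mark.parametrize("t", [0.01, 0.3, 2.0])
    def test_rows_are_stochastic(self, cohort_params, t):
        q = build_rate_matrix(cohort_params, 0.4)
        p = transition_probabilities(q, t, cohort_params.codon_freqs)
        assert p.min() >= 0.0
        assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-10

    def test_matches_taylor_series(self, cohort_params):
        # independent oracle: truncated series sum_{k<=30} (Qt)^k / k!
        q = build_rate_matrix(cohort_params, 0.4)
        t = 0.05
        p = transition_probabilities(q, t, cohort_params.codon_freqs)
        series = np.eye(61)
        term = np.eye(61)
        for k in range(1, 31):
            term = term @ (q * t) / k
            series = series + term
        assert np.abs(p - series).max() < 1e-8

    def test_chapman_kolmogorov(self, cohort_params):
        q = build_rate_matrix(cohort_params, 0.7)
        pi = cohort_params.codon_freqs
        for s, t in [(0.01, 0.01), (0.01, 0.1), (0.1, 0.1)]:
            lhs = transition_probabilities(q, s, pi) @ transition_probabilities(q, t, pi)
            rhs = transition_probabilities(q, s + t, pi)
            assert np.abs(lhs - rhs).max() < 1e-8

    def test_negative_time_rejected(self, cohort_params):
        q = build_rate_matrix(cohort_params, 0.4)
        with pytest.raises(ValueError):
            transition_probabilities(q, -0.1, cohort_params.codon_freqs)


def _enumerate_fractions(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """Oracle: stationary nonsyn/syn substitution fractions by direct
    enumeration of every single-nucleotide codon change, classified with
    Biopython translation."""
    syn_flux = nonsyn_flux = 0.0
    for i, codon in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nuc in "ACGT":
                if nuc == codon[pos]:
                    continue
                mutant = codon[:pos] + nuc + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                j = CODON_INDEX[mutant]
                is_ts = {codon[pos], nuc} in ({"A", "G"}, {"C", "T"})
                rate = pi[i] * pi[j] * (kappa if is_ts else 1.0)
                if Seq(codon).translate() == Seq(mutant).translate():
                    syn_flux += rate
                else:
                    nonsyn_flux += rate * omega
    total = syn_flux + nonsyn_flux
    return nonsyn_flux / total, syn_flux / total


class TestDnDsDecomposition:
    def test_neutral_omega_gives_equal_rates(self, uniform_params):
        dn, ds = dn_ds_from_branch(0.3, 1.0, uniform_params)
        assert dn == pytest.approx(ds, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_ratio_identity(self, seed):
        kappa, omega, pi = random_model_params(np.random.default_rng(100 + seed))
        t = float(np.random.default_rng(seed).uniform(0.01, 2.0))
        dn, ds = dn_ds_from_branch(t, omega, _params(kappa, omega, pi))
        assert dn / ds == pytest.approx(omega, abs=1e-10)

    def test_matches_enumeration_oracle(self, uniform_params):
        # uniform pi, kappa=2, omega=0.5, t=0.2 against hand enumeration of
        # all single-nucleotide codon changes
        t, omega = 0.2, 0.5
        rho_n, rho_s = _enumerate_fractions(2.0, omega, uniform_params.codon_freqs)
        rho_n1, rho_s1 = _enumerate_fractions(2.0, 1.0, uniform_params.codon_freqs)
        expected_dn = t * rho_n / (3 * rho_n1)
        expected_ds = t * rho_s / (3 * rho_s1)
        dn, ds = dn_ds_from_branch(t, omega, uniform_params)
        assert dn == pytest.approx(expected_dn, abs=1e-12)
        assert ds == pytest.approx(expected_ds, abs=1e-12)

    def test_fractions_sum_to_one(self, cohort_params):
        rho_n, rho_s = substitution_fractions(cohort_params, 0.3)
        assert rho_n + rho_s == pytest.approx(1.0, abs=1e-12)
        assert 0 < rho_n < rho_s  # purifying selection: mostly synonymous
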