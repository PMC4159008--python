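import numpy as np
import pytest

from dupaccel import default_scenario, simulate_sextuplet
from dupaccel.codons import uniform_frequencies
from dupaccel.model import CodonModelParams
from dupaccel.simulate import default_codon_freqs, default_params


@pytest.fixture(scope="session")
def uniform_params() -> CodonModelParams:
    """kappa=2, omega=0.5, uniform codon frequencies (hand-checkable)."""
    return CodonModelParams(
        kappa=2.0, omega_by_class={"preD": 0.5}, codon_freqs=uniform_frequencies()
    )


@pytest.fixture(scope="session")
def cohort_params() -> CodonModelParams:
    return default_params()


@pytest.fixture(scope="session")
def small_alignment():
    """One simulated 200-codon sextuplet alignment under the default scenario."""
    scen = default_scenario(seed=20240, n_codons=200)
    aln, truth = simulate_sextuplet(scen)
    return aln, truth, scen


def random_model_params(rng: np.random.Generator) -> tuple[float, float, np.ndarray]:
    """A random (kappa, omega, pi) draw for property tests."""
    kappa = float(rng.uniform(0.5, 8.0))
    omega = float(rng.uniform(0.05, 3.0))
    pi = rng.dirichlet(np.full(61, 5.0))
    return kappa, omega, pi
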