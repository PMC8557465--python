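import pytest
from hypothesis import HealthCheck, settings

import evosparse as ev

settings.register_profile(
    "fixed",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def separable_sim():
    """Small alignment with perfectly clade-diagnostic positions."""
    return ev.simulate(
        S=40, p=200, G=5, n_diag_genes=2, n_diag_per_gene=5,
        clade_size=12, fidelity=1.0, leakage=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def noisy_sim():
    """Small alignment with strong but imperfect planted signal."""
    return ev.simulate(
        S=60, p=300, G=6, n_diag_genes=1, n_diag_per_gene=8,
        clade_size=20, fidelity=0.95, leakage=0.05, seed=11,
    )


@pytest.fixture(scope="session")
def noise_sim():
    """Alignment with no planted signal at all."""
    return ev.simulate(
        S=60, p=300, G=6, n_diag_genes=0, n_diag_per_gene=0,
        clade_size=20, fidelity=0.95, leakage=0.05, seed=13,
    )


@pytest.fixture(scope="session")
def noisy_design(noisy_sim):
    X, bg = ev.prepare_design(noisy_sim.alignment, noisy_sim.groups)
    y = ev.balance(ev.build_response(noisy_sim.alignment.taxa, noisy_sim.positives))
    return X, y, bg
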