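import numpy as np
import pytest

from prrtest import DesignSpec, SimulationConfig, build_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated study shared across read-only tests."""
    cfg = SimulationConfig(n_samples=80, n_taxa=30, seed=42)
    return build_experiment(cfg)


@pytest.fixture
def diet_design():
    """Four-group design: 3 interest dummies against an intercept, n=80."""
    rng = np.random.default_rng(7)
    diet = rng.integers(0, 4, 80)
    interest = np.column_stack([(diet == k).astype(float) for k in (1, 2, 3)])
    return DesignSpec(
        X_interest=interest,
        X_nuisance=np.ones((80, 1)),
        Z_interest=interest.copy(),
        Z_nuisance=np.ones((80, 1)),
    )


def random_counts(rng, n, family, s):
    """Counts roughly matched to a family's own assumptions, for fit tests."""
    mu = 0.01 * s * rng.lognormal(0.0, 0.3, n)
    if family.base == "poisson":
        y = rng.poisson(mu)
    elif family.base == "negbin":
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
    elif family.base == "binomial":
        y = rng.binomial(s.astype(int), np.clip(mu / s, 0, 1))
    else:  # betabinom
        p = np.clip(mu / s, 1e-4, 1 - 1e-4)
        rho = 0.003
        gam = (1 - rho) / rho
        y = rng.binomial(s.astype(int), rng.beta(p * gam, (1 - p) * gam))
    if family.zero_inflated:
        y = np.where(rng.random(n) < 0.3, 0, y)
    return np.minimum(y, s.astype(int))
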