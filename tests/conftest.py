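import numpy as np
import pandas as pd
import pytest

from sputodeconv import simulate


@pytest.fixture(scope="session")
def default_dataset():
    """The default cohort scenario (n=10/group, 2000 features/modality)."""
    return simulate.simulate_dataset(seed=20260930)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced cohort for fast structural tests."""
    cfg = simulate.ScenarioConfig(
        n_per_group={"asthma": 6, "COPD": 6, "control": 6},
        profiles=simulate.ProfileConfig(
            n_features_expr=300, n_features_meth=300, n_markers_per_type=5,
            effects=[simulate.EffectSpec("asthma", "AM", "methylation", 0.2, 10),
                     simulate.EffectSpec("asthma", "AM", "expression", 1.5, 10)]),
    )
    return simulate.simulate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def degraded_dataset():
    """Single-cohort scenario in the strong-degradation regime, where the
    RNA-integrity axis dominates the expression variance."""
    deg = simulate.DegradationModel.default()
    deg.frac_susceptible = 0.5
    deg.lambda_range = (0.05, 0.5)
    cfg = simulate.ScenarioConfig(n_per_group={"control": 24}, degradation=deg)
    return simulate.simulate_dataset(cfg, seed=31)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def asthma_fractions():
    """n=12 asthma-like fraction rows, fixed seed."""
    return simulate.generate_cell_fractions(
        "asthma", 12, simulate.FractionModel.default(), seed=11)
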