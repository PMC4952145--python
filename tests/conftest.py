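import dataclasses

import numpy as np
import pytest

from posdev.simulate import (
    CategoricalSpec,
    ContextSpec,
    MarginalSpec,
    MechanismSpec,
    OutcomeSpec,
    PlantedShift,
    SimulationConfig,
    StateSpec,
    default_study_config,
    generate_panel,
)


def make_small_config(
    seed: int = 0,
    sigma: float = 1.0,
    planted: tuple = (),
    n_per_state: int = 25,
    states: tuple[str, ...] = ("AA", "BB"),
) -> SimulationConfig:
    """A compact 2-state, 2-year configuration for fast unit tests:
    3 continuous + 1 categorical context variables, 2 mechanisms, 2 outcomes."""
    continuous = {
        "spend": MarginalSpec("lognorm", {"mu": 10.0, "sigma": 0.8}),
        "pop": MarginalSpec("lognorm", {"mu": 11.0, "sigma": 1.0}),
        "poverty": MarginalSpec("beta_pct", {"a": 4.0, "b": 12.0, "scale": 100.0}),
    }
    k = len(continuous)
    R = np.full((k, k), 0.2)
    np.fill_diagonal(R, 1.0)
    context = ContextSpec(
        continuous=continuous,
        correlation=tuple(tuple(r) for r in R),
        categorical={
            "community_type": CategoricalSpec(
                ("metropolitan", "micropolitan", "rural"), (0.5, 0.25, 0.25), "metropolitan"
            )
        },
    )
    mechanism = MechanismSpec(
        indicators={"alt_provider": 0.5},
        continuous={"service_score": MarginalSpec("norm", {"mean": 0.0, "sd": 1.0})},
    )
    outcomes = {
        "rate_a": OutcomeSpec(
            alpha=20.0,
            beta_context={"spend": -1.0, "poverty": 2.0, "community_type=rural": 1.5},
            beta_mechanism={"alt_provider": -0.8, "service_score": -1.0},
            sigma=sigma,
        ),
        "rate_b": OutcomeSpec(
            alpha=8.0,
            beta_context={"pop": 0.5, "poverty": 0.8, "community_type=micropolitan": 0.4},
            beta_mechanism={"service_score": -0.5},
            sigma=sigma,
        ),
    }
    reporting = {"percap_spend": MarginalSpec("lognorm", {"mu": 2.0, "sigma": 0.7})}
    return SimulationConfig(
        states=tuple(StateSpec(s, n_per_state) for s in states),
        years=(2009, 2010),
        context=context,
        mechanism=mechanism,
        outcomes=outcomes,
        reporting=reporting,
        planted=tuple(planted),
        seed=seed,
    )


@pytest.fixture
def small_config():
    return make_small_config(seed=11)


@pytest.fixture
def small_panel(small_config):
    panel, truth = generate_panel(small_config)
    return panel


@pytest.fixture(scope="session")
def default_run():
    """One default study-shaped panel with ground truth (seed 1)."""
    cfg = default_study_config(1)
    panel, truth = generate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def default_cells(default_run):
    from posdev.identify import run_all_cells

    _, panel, _ = default_run
    return run_all_cells(panel)
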