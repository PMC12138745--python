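import numpy as np
import pytest

from metatransport import (
    PropensityModelSet,
    SimulationConfig,
    TrialCollectionData,
    fit_propensity_models,
    simulate_dataset,
)


@pytest.fixture
def tiny_data() -> TrialCollectionData:
    """m=2 studies with 2 treated + 2 control rows each, plus 3 target rows."""
    nan = np.nan
    return TrialCollectionData(
        study=[1, 1, 1, 1, 2, 2, 2, 2, 0, 0, 0],
        arm=[1, 1, 0, 0, 1, 1, 0, 0, nan, nan, nan],
        outcome=[2.0, 4.0, 1.0, 3.0, 6.0, 5.0, 0.0, 2.0, nan, nan, nan],
        covariates=np.array([0.5, -0.2, 1.1, 0.0, 0.3, -1.0, 0.8, 0.1, 0.4, -0.6, 1.5])[:, None],
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small Setting-2 dataset with its fitted nuisance models."""
    cfg = SimulationConfig.from_setting(2, m=3, size_regime="small", seed=42)
    ds = simulate_dataset(cfg, seed=42)
    fits = fit_propensity_models(ds.data)
    return ds, fits


def constant_fits(data: TrialCollectionData, p_treat: float = 0.5) -> PropensityModelSet:
    """A hand-built model set with constant probabilities everywhere."""
    m = data.m
    P = np.full((data.n, m + 1), 1.0 / (m + 1))
    p1 = np.where(data.study_mask, p_treat, np.nan)
    return PropensityModelSet(
        fitted_treatment_prob=p1,
        fitted_membership_prob=P,
        convergence_flags={"membership": True},
    )
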