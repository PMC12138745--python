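import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from metatransport import (
    PropensityModelSet,
    SimulationConfig,
    StudyTateEstimate,
    TrialCollectionData,
    ValidationError,
    compute_unit_weights,
    estimate_pooled,
    estimate_study_tate,
    estimate_two_stage,
    estimate_two_stage_from_data,
    estimate_unadjusted,
    simulate_dataset,
)
from conftest import constant_fits

nan = np.nan


def _fits_from_probs(data, p_treat, membership):
    return PropensityModelSet(
        fitted_treatment_prob=np.asarray(p_treat, float),
        fitted_membership_prob=np.asarray(membership, float),
    )


# ---------------------------------------------------------------- weights
def test_study_specific_weight_substitution():
    """w = [1/e_a(x,s)] * [p(x,0)/p(x,s)] on a single treated record."""
    data = TrialCollectionData(
        study=[0, 1, 1], arm=[nan, 1.0, 0.0], outcome=[nan, 2.0, 1.0],
        covariates=np.zeros((3, 1)),
    )
    P = np.array([[0.2, 0.8], [0.2, 0.4], [0.2, 0.4]])  # columns: target, study 1
    fits = _fits_from_probs(data, [nan, 0.5, 0.5], P)
    w = compute_unit_weights(data, fits, "study_specific")
    assert w.w_treated[1] == pytest.approx((1 / 0.5) * (0.2 / 0.4))
    assert w.w_treated[2] == 0.0 and w.w_control[1] == 0.0  # off-arm indicator
    assert w.w_treated[0] == 0.0 and w.w_control[0] == 0.0  # target rows


def test_study_specific_weights_invariant_to_common_membership_scaling():
    data = TrialCollectionData(
        study=[0, 1, 1], arm=[nan, 1.0, 0.0], outcome=[nan, 2.0, 1.0],
        covariates=np.zeros((3, 1)),
    )
    P = np.array([[0.2, 0.8], [0.1, 0.3], [0.25, 0.5]])
    fits = _fits_from_probs(data, [nan, 0.4, 0.4], P)
    scaled = _fits_from_probs(data, [nan, 0.4, 0.4], P * 1.7)
    w = compute_unit_weights(data, fits, "study_specific")
    ws = compute_unit_weights(data, scaled, "study_specific")
    np.testing.assert_allclose(w.w_treated, ws.w_treated)
    np.testing.assert_allclose(w.w_control, ws.w_control)


# ------------------------------------------------------------- unadjusted
def test_unadjusted_fixture_arithmetic(tiny_data):
    """Treated {2,4,6,5}, control {1,3,0,2} -> 17/4 - 6/4."""
    assert estimate_unadjusted(tiny_data) == pytest.approx(17 / 4 - 6 / 4, abs=1e-12)


def test_unadjusted_matches_brute_force(small_sim):
    ds, _ = small_sim
    d = ds.data
    treated = d.outcome[(d.arm == 1.0) & d.study_mask]
    control = d.outcome[(d.arm == 0.0) & d.study_mask]
    assert estimate_unadjusted(d) == pytest.approx(treated.mean() - control.mean(), abs=1e-12)


def test_constant_outcomes_give_zero_effect(tiny_data):
    tiny_data.outcome[tiny_data.study_mask] = 3.7
    assert estimate_unadjusted(tiny_data) == pytest.approx(0.0, abs=1e-12)


# ----------------------------------------------------------------- pooled
def test_pooled_with_constant_probabilities_equals_unadjusted(tiny_data):
    fits = constant_fits(tiny_data)
    assert estimate_pooled(tiny_data, fits) == pytest.approx(
        estimate_unadjusted(tiny_data), abs=1e-12
    )


def test_pooled_hand_weights_fixture():
    """Treated weights {1,3} on outcomes {2,4}; control {1,1} on {1,3}:
    (2+12)/4 - (1+3)/2 = 1.5."""
    data = TrialCollectionData(
        study=[0, 1, 1, 1, 1], arm=[nan, 1, 1, 0, 0], outcome=[nan, 2, 4, 1, 3],
        covariates=np.zeros((5, 1)),
    )
    # odds p0/(1-p0) = 0.5 throughout; e chosen to yield the target weights
    p0 = 1 / 3
    P = np.column_stack([np.full(5, p0), np.full(5, 1 - p0)])
    p_treat = np.array([nan, 0.5, 1 / 6, 0.5, 0.5])
    fits = _fits_from_probs(data, p_treat, P)
    assert estimate_pooled(data, fits) == pytest.approx(1.5, abs=1e-12)


# ------------------------------------------------------ study-specific TATE
def test_equal_weights_reduce_to_arm_mean_difference(tiny_data):
    fits = constant_fits(tiny_data)
    est = estimate_study_tate(tiny_data, fits, 1)
    d = tiny_data
    s1 = d.study == 1
    expected = d.outcome[s1 & (d.arm == 1)].mean() - d.outcome[s1 & (d.arm == 0)].mean()
    assert est.delta_hat == pytest.approx(expected, abs=1e-12)
    assert est.effective_sample_sizes == (pytest.approx(2.0), pytest.approx(2.0))


def test_study_tate_hand_weights_fixture():
    """Treated weights {2,2} outcomes {1,3}; control {1,3} outcomes {0,4}:
    2 - 3 = -1."""
    data = TrialCollectionData(
        study=[0, 1, 1, 1, 1], arm=[nan, 1, 1, 0, 0], outcome=[nan, 1, 3, 0, 4],
        covariates=np.zeros((5, 1)),
    )
    # per-record membership ratios p0/p1 chosen to produce the weights
    P = np.array([[0.5, 0.5], [0.4, 0.4], [0.4, 0.4], [0.2, 0.4], [0.6, 0.4]])
    p_treat = np.array([nan, 0.5, 0.5, 0.5, 0.5])
    fits = _fits_from_probs(data, p_treat, P)
    est = estimate_study_tate(data, fits, 1)
    assert est.delta_hat == pytest.approx(-1.0, abs=1e-12)
    assert est.arm_weight_sums == (pytest.approx(4.0), pytest.approx(4.0))


def test_study_estimator_matches_quadrature_oracle():
    """With the true (not estimated) propensities plugged in, the
    transported study estimate at n~50,000 matches numerical integration
    of the conditional ATE over the target covariate density within 0.02."""
    rng = np.random.default_rng(77)
    n = 100_000
    b0, b1 = 0.3, -0.6  # study-1 membership logit vs target baseline
    theta = np.array([-0.5, -1.4, 0.8, -0.9])  # nu, gamma, lam, kappa
    x = rng.normal(size=n)
    p1x = 1 / (1 + np.exp(-(b0 + b1 * x)))
    s = (rng.random(n) < p1x).astype(int)
    arm = np.where(s == 1, rng.integers(0, 2, n).astype(float), nan)
    y = theta[0] + arm * theta[1] + x * theta[2] + arm * x * theta[3] + rng.normal(size=n)
    data = TrialCollectionData(
        study=s, arm=arm, outcome=np.where(s == 1, y, nan), covariates=x[:, None]
    )
    P = np.column_stack([1 - p1x, p1x])
    fits = _fits_from_probs(data, np.where(s == 1, 0.5, nan), P)
    est = estimate_study_tate(data, fits, 1)

    dens = lambda t: norm.pdf(t) * (1 - 1 / (1 + np.exp(-(b0 + b1 * t))))
    num = quad(lambda t: (theta[1] + theta[3] * t) * dens(t), -10, 10)[0]
    den = quad(dens, -10, 10)[0]
    assert est.delta_hat == pytest.approx(num / den, abs=0.02)


# -------------------------------------------------------------- two-stage
def test_two_stage_combinations():
    def mk(s, d):
        return StudyTateEstimate(s, d, (1.0, 1.0), (1.0, 1.0))

    assert estimate_two_stage([mk(1, 1), mk(2, 2), mk(3, 3)]).delta_hat == pytest.approx(2.0)
    weighted = estimate_two_stage([mk(1, 4), mk(2, 0), mk(3, 0)], [2, 1, 1])
    assert weighted.delta_hat == pytest.approx(2.0)
    assert estimate_two_stage([mk(1, -0.4)]).delta_hat == pytest.approx(-0.4)
    with pytest.raises(ValidationError, match="strictly positive"):
        estimate_two_stage([mk(1, 1), mk(2, 2)], [1.0, 0.0])
    with pytest.raises(ValidationError, match="at least one"):
        estimate_two_stage([])


def test_two_stage_exact_weighted_average(small_sim):
    ds, fits = small_sim
    two = estimate_two_stage_from_data(ds.data, fits)
    deltas = np.array([e.delta_hat for e in two.study_estimates])
    w = two.study_weights
    assert two.delta_hat == pytest.approx(np.dot(w, deltas) / w.sum(), abs=1e-12)


# ------------------------------------------------------------- properties
def test_arm_weight_scale_invariance(small_sim):
    """Multiplying one arm's weights by a positive constant leaves the
    self-normalized estimate unchanged."""
    ds, fits = small_sim
    w = compute_unit_weights(ds.data, fits, "study_specific")
    base = estimate_study_tate(ds.data, fits, 2, weights=w)
    import dataclasses

    scaled = dataclasses.replace(w, w_treated=w.w_treated * 13.7)
    est = estimate_study_tate(ds.data, fits, 2, weights=scaled)
    assert est.delta_hat == pytest.approx(base.delta_hat, abs=1e-12)


_EQUIVARIANCE_DATA = simulate_dataset(
    SimulationConfig.from_setting(1, m=2, size_regime="small", seed=8), seed=8
).data


@settings(deadline=None, max_examples=20)
@given(c=st.floats(-50, 50, allow_nan=False))
def test_location_equivariance(c):
    """Adding c to every outcome leaves Delta unchanged; adding c to the
    treated arm only shifts every Delta by c."""
    data = _EQUIVARIANCE_DATA
    fits = constant_fits(data, p_treat=0.6)
    base_ua = estimate_unadjusted(data)
    base_two = estimate_two_stage_from_data(data, fits).delta_hat

    shifted = TrialCollectionData(
        study=data.study, arm=data.arm, outcome=data.outcome + c,
        covariates=data.covariates,
    )
    assert estimate_unadjusted(shifted) == pytest.approx(base_ua, abs=1e-9)
    assert estimate_two_stage_from_data(shifted, fits).delta_hat == pytest.approx(
        base_two, abs=1e-9
    )
    treated_shift = np.where(data.arm == 1.0, data.outcome + c, data.outcome)
    shifted_t = TrialCollectionData(
        study=data.study, arm=data.arm, outcome=treated_shift, covariates=data.covariates
    )
    assert estimate_unadjusted(shifted_t) == pytest.approx(base_ua + c, abs=1e-9)
    assert estimate_two_stage_from_data(shifted_t, fits).delta_hat == pytest.approx(
        base_two + c, abs=1e-9
    )
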