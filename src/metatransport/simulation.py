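"""Synthetic multi-study data generator.

The generator emulates a collection of m two-arm randomized trials plus a
covariate-only target sample:

* a single covariate X ~ N(0, 1), i.i.d. across individuals;
* study membership S in {0, ..., m} from a multinomial logistic model with
  the target (S = 0) as the baseline category,
  P(S = s | X) proportional to exp(b_{s,0} + b_{s,1} X);
* completely randomized treatment within each study, P(A = 1 | S = s) = 0.5;
* study-level random coefficient vectors
  theta_s = (nu_s, gamma_s, lambda_s, kappa_s) ~ N(theta0, Sigma_theta)
  with theta0 = (-1, -1, 0.5, -0.5) and diagonal
  Sigma_theta = diag(0.5, Sigma_gamma, 0.5, Sigma_kappa);
* Gaussian linear outcomes
  Y = nu_S + A gamma_S + X lambda_S + A X kappa_S + eps, eps ~ N(0, 1).

The target population's coefficients are theta0, so the true TATE is

  Delta = gamma0 + kappa0 E(X | S = 0) = -1 - 0.5 E(X | S = 0),

with E(X | S = 0) computed from the membership model.  Membership
intercepts are calibrated numerically so the expected source fractions
match a requested sample-size pattern; the covariate slopes default to a
documented reconstruction in which the conditional center of X increases
across studies and the target sits at or above all of them.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.stats import norm

from .data_model import TrialCollectionData
from .errors import SimulationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "calibrate_intercepts",
    "simulate_dataset",
    "true_tate",
]

THETA0 = (-1.0, -1.0, 0.5, -0.5)

#: average sample sizes per regime: (target, per-study)
SIZE_REGIMES = {"large": (5500.0, 1500.0), "small": (200.0, 100.0)}

#: preset heterogeneity settings: (size_pattern, Sigma_gamma, Sigma_kappa)
SETTINGS = {
    1: ("similar", 0.1, 2.0),
    2: ("different", 0.1, 2.0),
    3: ("different", 2.0, 0.1),
}


def default_beta_slopes(m: int) -> np.ndarray:
    """Reconstructed membership-model covariate slopes.

    The exact values used in the original simulation experiments are not
    published; this default realizes their qualitative description: the
    conditional center of X increases from study 1 to study m, and the
    target population's conditional center lies at or above every study's.
    With baseline (target) slope fixed at zero, non-positive study slopes
    increasing to zero achieve both.
    """
    if m == 1:
        return np.array([-0.5])
    return np.linspace(-1.0, 0.0, m)


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic data-generating process."""

    m: int = 3
    size_regime: str = "large"
    size_pattern: str = "different"
    sigma_gamma: float = 0.1
    sigma_kappa: float = 2.0
    theta0: tuple[float, float, float, float] = THETA0
    fixed_variances: tuple[float, float] = (0.5, 0.5)  # variances of nu and lambda
    beta_slopes: np.ndarray | None = None
    beta_intercepts: np.ndarray | None = None
    size_ratio: float = 6.0  # largest/smallest expected study under 'different'
    target_size: float | None = None  # override the regime's expected target size
    study_size: float | None = None  # override the regime's expected mean study size
    epsilon_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError("m must be at least 1")
        if self.size_regime not in SIZE_REGIMES:
            raise ValidationError(f"unknown size regime {self.size_regime!r}")
        if self.size_pattern not in ("similar", "different"):
            raise ValidationError(f"unknown size pattern {self.size_pattern!r}")
        if self.sigma_gamma < 0 or self.sigma_kappa < 0:
            raise ValidationError("random-effect variances must be non-negative")
        if len(self.theta0) != 4:
            raise ValidationError("theta0 must have length 4")
        if self.beta_slopes is None:
            self.beta_slopes = default_beta_slopes(self.m)
        self.beta_slopes = np.asarray(self.beta_slopes, dtype=float)
        if self.beta_slopes.shape != (self.m,):
            raise ValidationError("beta_slopes must have one entry per study")

    @classmethod
    def from_setting(cls, setting: int, m: int = 3, size_regime: str = "large", **kw) -> "SimulationConfig":
        """Preset heterogeneity settings 1-3 (study-size pattern plus the
        dominant source of effect heterogeneity)."""
        if setting not in SETTINGS:
            raise ValidationError(f"unknown setting {setting}; choose 1, 2 or 3")
        pattern, sg, sk = SETTINGS[setting]
        return cls(
            m=m, size_regime=size_regime, size_pattern=pattern,
            sigma_gamma=sg, sigma_kappa=sk, **kw,
        )

    # -- expected sample-size structure ----------------------------------
    @property
    def expected_sizes(self) -> np.ndarray:
        """Expected sample size per source, index 0..m."""
        n0, nbar = SIZE_REGIMES[self.size_regime]
        if self.target_size is not None:
            n0 = float(self.target_size)
        if self.study_size is not None:
            nbar = float(self.study_size)
        if self.size_pattern == "similar":
            sizes = np.full(self.m, nbar)
        else:
            shape = np.linspace(1.0, self.size_ratio, self.m)
            sizes = shape / shape.mean() * nbar
        return np.concatenate([[n0], sizes])

    @property
    def fractions(self) -> np.ndarray:
        """Expected source fractions q_0..q_m (sum to 1)."""
        sizes = self.expected_sizes
        return sizes / sizes.sum()

    @property
    def n_total(self) -> int:
        return int(round(self.expected_sizes.sum()))

    @property
    def theta_variances(self) -> np.ndarray:
        return np.array(
            [self.fixed_variances[0], self.sigma_gamma, self.fixed_variances[1], self.sigma_kappa]
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("beta_slopes", "beta_intercepts"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        return d


def _grid_x(mc_size: int) -> np.ndarray:
    """Deterministic stratified standard-normal sample (midpoint quantiles)."""
    return norm.ppf((np.arange(mc_size) + 0.5) / mc_size)


def _membership_probs(x: np.ndarray, intercepts: np.ndarray, slopes: np.ndarray) -> np.ndarray:
    eta = intercepts[None, :] + np.outer(x, slopes)
    eta = np.column_stack([np.zeros(x.size), eta])
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=1, keepdims=True)


def calibrate_intercepts(
    config: SimulationConfig,
    mc_size: int = 200_000,
    tol: float = 0.02,
    max_iter: int = 500,
) -> np.ndarray:
    """Membership-model intercepts matching the requested source fractions.

    Solves for b_{s,0} such that the average over X ~ N(0,1) of the
    category probabilities equals ``config.fractions`` within relative
    tolerance ``tol``, by iterative proportional updating on a
    deterministic stratified normal grid of ``mc_size`` points.  With all
    slopes zero the closed form log(q_s / q_0) is exact and returned after
    the first pass.
    """
    q = config.fractions
    if (q <= 0).any():
        raise ValidationError("requested source fractions must all be positive")
    slopes = config.beta_slopes
    x = _grid_x(mc_size)
    beta0 = np.log(q[1:] / q[0])
    inner_tol = min(tol, 0.02) / 4.0
    for _ in range(max_iter):
        qhat = _membership_probs(x, beta0, slopes).mean(axis=0)
        rel = np.abs(qhat - q) / q
        if rel.max() < inner_tol:
            return beta0
        beta0 = beta0 + np.log(q[1:] / qhat[1:]) - np.log(q[0] / qhat[0])
    qhat = _membership_probs(x, beta0, slopes).mean(axis=0)
    if (np.abs(qhat - q) / q).max() < tol:
        return beta0
    raise SimulationError(
        f"intercept calibration did not converge; achieved fractions {qhat.round(4)}"
    )


def _ensure_intercepts(config: SimulationConfig) -> np.ndarray:
    if config.beta_intercepts is None:
        config.beta_intercepts = calibrate_intercepts(config)
    return np.asarray(config.beta_intercepts, dtype=float)


@dataclasses.dataclass
class SimulatedDataset:
    """Generated data plus the latent quantities behind it.

    ``theta`` has one row per source 0..m; row 0 holds the target
    population's coefficients theta0.  ``potential_outcomes`` stores
    (Y^0, Y^1) for every record, sharing the record's single noise draw, so
    the observed outcome equals the potential outcome of the assigned arm.
    """

    data: TrialCollectionData
    theta: np.ndarray  # (m+1, 4): nu, gamma, lambda, kappa
    potential_outcomes: np.ndarray  # (n, 2): Y^0, Y^1
    epsilon_sd: float
    config: SimulationConfig

    def conditional_ate(self, study: int, x: np.ndarray) -> np.ndarray:
        """gamma_s + kappa_s x for source ``study`` (0 = target)."""
        return self.theta[study, 1] + self.theta[study, 3] * np.asarray(x)


def simulate_dataset(
    config: SimulationConfig,
    seed: int | None = None,
    on_empty_arm: str = "resample",
) -> SimulatedDataset:
    """Draw one synthetic dataset from the configured process.

    Covariates, membership, arms, random effects and noise use independent
    child streams of ``seed``; the per-study random-effect streams are
    keyed by study label so increasing m leaves earlier studies unchanged.
    At tiny sample sizes a realized study can miss an arm; the default
    redraws that study's assignments (logged), ``on_empty_arm='error'``
    raises instead.
    """
    seed = config.seed if seed is None else int(seed)
    intercepts = _ensure_intercepts(config)
    m, n = config.m, config.n_total
    theta0 = np.asarray(config.theta0, dtype=float)

    x = np.random.default_rng([seed, 1]).normal(size=n)
    probs = _membership_probs(x, intercepts, config.beta_slopes)
    u = np.random.default_rng([seed, 2]).random(n)
    s = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    counts = np.bincount(s, minlength=m + 1)
    if (counts[1:] < 2).any() or counts[0] < 1:
        raise SimulationError(
            f"realized source sizes too small to populate both arms: {counts.tolist()}"
        )

    arm = np.full(n, np.nan)
    for lab in range(1, m + 1):
        rows = np.flatnonzero(s == lab)
        rng_a = np.random.default_rng([seed, 3, lab])
        draw = rng_a.integers(0, 2, size=rows.size).astype(float)
        tries = 0
        while draw.sum() in (0, rows.size):
            if on_empty_arm == "error":
                raise SimulationError(f"study {lab} realized a single arm")
            tries += 1
            if tries > 1000:
                raise SimulationError(f"study {lab}: could not populate both arms")
            draw = rng_a.integers(0, 2, size=rows.size).astype(float)
        if tries:
            logger.info("study %d: redrew treatment assignment %d time(s)", lab, tries)
        arm[rows] = draw

    sd = np.sqrt(config.theta_variances)
    theta = np.empty((m + 1, 4))
    theta[0] = theta0
    for lab in range(1, m + 1):
        rng_t = np.random.default_rng([seed, 4, lab])
        theta[lab] = theta0 + sd * rng_t.normal(size=4)

    eps = np.random.default_rng([seed, 5]).normal(scale=config.epsilon_sd, size=n)
    nu, gamma, lam, kappa = (theta[s, j] for j in range(4))
    y0 = nu + lam * x + eps
    y1 = nu + gamma + (lam + kappa) * x + eps
    outcome = np.where(s == 0, np.nan, np.where(arm == 1.0, y1, y0))

    data = TrialCollectionData(
        study=s, arm=arm, outcome=outcome, covariates=x[:, None], covariate_names=("x1",)
    )
    return SimulatedDataset(
        data=data,
        theta=theta,
        potential_outcomes=np.column_stack([y0, y1]),
        epsilon_sd=config.epsilon_sd,
        config=config,
    )


def target_covariate_mean(
    config: SimulationConfig, mc_size: int = 1_000_000, seed: int = 0
) -> float:
    """Monte Carlo estimate of E(X | S = 0) implied by the membership model."""
    intercepts = _ensure_intercepts(config)
    x = np.random.default_rng([seed, 6]).normal(size=mc_size)
    p0 = _membership_probs(x, intercepts, config.beta_slopes)[:, 0]
    return float(np.dot(x, p0) / p0.sum())


def true_tate(config: SimulationConfig, mc_size: int = 1_000_000, seed: int = 0) -> float:
    """True target-population average treatment effect,
    gamma0 + kappa0 * E(X | S = 0)."""
    ex = target_covariate_mean(config, mc_size=mc_size, seed=seed)
    return float(config.theta0[1] + config.theta0[3] * ex)
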