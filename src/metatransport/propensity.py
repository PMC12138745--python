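"""Nuisance models for weighting: per-study treatment-assignment logits and
a single multinomial study-membership model.

Two conditional probabilities drive the weights,

    e_a(x, s) = P(A = a | X = x, S = s)      (treatment propensity)
    p(x, s)   = P(S = s | X = x)             (membership probability)

The treatment propensity is estimated with a separate binomial logistic
regression inside each study, allowing assignment mechanisms to differ
across trials; ``e_{a'} = 1 - e_a``.  Membership over the target sample and
all studies is estimated jointly with one multinomial logistic regression
with the target population (``S = 0``) as the baseline category.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .data_model import TrialCollectionData
from .errors import ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PropensityModelSet",
    "fit_treatment_models",
    "fit_membership_model",
    "fit_propensity_models",
]

try:  # formula strings are supported when patsy is importable
    import patsy
except Exception:  # pragma: no cover
    patsy = None


def _design(data: TrialCollectionData, formula) -> tuple[np.ndarray, list[str]]:
    """Build an (intercept-first) design matrix from a formula spec.

    ``formula`` may be None (main effects of every covariate), a sequence of
    covariate names, or a patsy right-hand-side string such as
    ``"x1 + I(x1**2)"``.
    """
    if formula is None:
        X = np.column_stack([np.ones(data.n), data.covariates])
        return X, ["const", *data.covariate_names]
    if isinstance(formula, str):
        if patsy is None:  # pragma: no cover
            raise ValidationError("patsy is required for string formulas")
        dm = patsy.dmatrix(formula, data.to_frame(), return_type="dataframe")
        return dm.to_numpy(float), list(dm.columns)
    cols = list(formula)
    idx = [data.covariate_names.index(c) for c in cols]
    X = np.column_stack([np.ones(data.n), data.covariates[:, idx]])
    return X, ["const", *cols]


@dataclasses.dataclass
class PropensityModelSet:
    """Fitted nuisance models and their per-record predictions.

    ``fitted_treatment_prob`` stores P(A=1 | X_i, S_i) for study rows (NaN on
    target rows); ``fitted_membership_prob`` stores the full probability
    vector (p(X_i,0), ..., p(X_i,m)) for every record.
    """

    treatment_coefficients: dict[int, np.ndarray] = dataclasses.field(default_factory=dict)
    membership_coefficients: np.ndarray | None = None  # (m, k), baseline study 0
    fitted_treatment_prob: np.ndarray | None = None
    fitted_membership_prob: np.ndarray | None = None
    convergence_flags: dict[str, bool] = dataclasses.field(default_factory=dict)
    design_names: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return all(self.convergence_flags.values())

    def treatment_prob_own_arm(self) -> np.ndarray:
        """ê_{A_i}(X_i, S_i): probability of the arm actually received."""
        p1 = self.fitted_treatment_prob
        if p1 is None:
            raise ValidationError("treatment models are not fitted")
        return p1  # caller combines with the arm indicator

    def check_invariants(self, tol: float = 1e-8) -> None:
        if self.fitted_membership_prob is not None:
            P = self.fitted_membership_prob
            if (P <= 0).any():
                raise ValidationError("membership probabilities must be strictly positive")
            if np.abs(P.sum(axis=1) - 1.0).max() > tol:
                raise ValidationError("membership probabilities must sum to 1 per record")

    def merge(self, other: "PropensityModelSet") -> "PropensityModelSet":
        out = PropensityModelSet(
            treatment_coefficients={**self.treatment_coefficients, **other.treatment_coefficients},
            membership_coefficients=(
                other.membership_coefficients
                if other.membership_coefficients is not None
                else self.membership_coefficients
            ),
            fitted_treatment_prob=(
                other.fitted_treatment_prob
                if other.fitted_treatment_prob is not None
                else self.fitted_treatment_prob
            ),
            fitted_membership_prob=(
                other.fitted_membership_prob
                if other.fitted_membership_prob is not None
                else self.fitted_membership_prob
            ),
            convergence_flags={**self.convergence_flags, **other.convergence_flags},
            design_names={**self.design_names, **other.design_names},
        )
        return out


def _clip_probs(p: np.ndarray, floor: float | None) -> np.ndarray:
    if floor is None:
        return p
    return np.clip(p, floor, 1.0 - floor)


def _fit_binary_logit(y, X, max_iter, tol, ridge):
    """Return (coef, converged). Ridge path uses scikit-learn (intercept
    unpenalized); otherwise a statsmodels Newton fit."""
    if ridge and ridge > 0:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=tol)
        clf.fit(X[:, 1:], y)
        coef = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        return coef, int(clf.n_iter_[0]) < max_iter
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.Logit(y, X).fit(method="newton", maxiter=max_iter, tol=tol, disp=0)
    separated = any("separation" in str(w.message).lower() for w in caught)
    converged = bool(res.mle_retvals.get("converged", False)) and not separated
    return np.asarray(res.params, float), converged


def fit_treatment_models(
    data: TrialCollectionData,
    formula=None,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
    ridge: float = 0.0,
    prob_floor: float | None = None,
    allow_nonconvergence: bool = False,
) -> PropensityModelSet:
    """Fit one treatment-assignment logistic regression per study.

    Returns a partial :class:`PropensityModelSet` with per-record fitted
    probabilities P(A=1 | X, S) on study rows.  Non-convergence or perfect
    separation raises :class:`ConvergenceError` naming the study unless
    ``allow_nonconvergence``; the flag is always recorded.
    """
    X_all, names = _design(data, formula)
    fits = PropensityModelSet(design_names={"treatment": names})
    p1 = np.full(data.n, np.nan)
    for s in data.study_labels:
        rows = data.study == s
        arm_s = data.arm[rows]
        if not (arm_s == 1.0).any() or not (arm_s == 0.0).any():
            raise ValidationError(f"single-arm study: study {s}")
        coef, converged = _fit_binary_logit(arm_s, X_all[rows], max_iter, tol, ridge)
        fits.treatment_coefficients[int(s)] = coef
        fits.convergence_flags[f"treatment:{s}"] = converged
        if not converged:
            if not allow_nonconvergence:
                raise ConvergenceError(
                    f"treatment model for study {s} failed to converge or separated"
                )
            logger.warning("treatment model for study %s flagged non-converged", s)
        p1[rows] = _clip_probs(expit(X_all[rows] @ coef), prob_floor)
    fits.fitted_treatment_prob = p1
    return fits


def _softmax_baseline(eta_nonbase: np.ndarray) -> np.ndarray:
    """Probabilities for categories 0..m from non-baseline linear predictors
    (baseline category 0 has linear predictor 0)."""
    eta = np.column_stack([np.zeros(eta_nonbase.shape[0]), eta_nonbase])
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=1, keepdims=True)


def fit_membership_model(
    data: TrialCollectionData,
    formula=None,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
    ridge: float = 0.0,
    prob_floor: float | None = None,
    allow_nonconvergence: bool = False,
) -> PropensityModelSet:
    """Fit the multinomial logistic study-membership model with the target
    population as the baseline category.

    Returns a partial :class:`PropensityModelSet` with an ``(n, m+1)``
    matrix of fitted membership probabilities (strictly positive, rows sum
    to one).
    """
    X, names = _design(data, formula)
    fits = PropensityModelSet(design_names={"membership": names})
    if ridge and ridge > 0:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=tol)
        clf.fit(X[:, 1:], data.study)
        # symmetric softmax parameterization -> baseline-0 relative
        inter = clf.intercept_ - clf.intercept_[0]
        slopes = clf.coef_ - clf.coef_[0]
        coefs = np.column_stack([inter[1:], slopes[1:]])
        converged = int(np.max(clf.n_iter_)) < max_iter
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.MNLogit(data.study, X).fit(
                method="newton", maxiter=max_iter, gtol=tol, disp=0
            )
        separated = any("separation" in str(w.message).lower() for w in caught)
        converged = bool(res.mle_retvals.get("converged", False)) and not separated
        coefs = np.asarray(res.params, float).T  # (m, k)
    fits.membership_coefficients = coefs
    fits.convergence_flags["membership"] = converged
    if not converged and not allow_nonconvergence:
        raise ConvergenceError("membership model failed to converge or separated")
    P = _softmax_baseline(X @ coefs.T)
    if prob_floor is not None:
        P = np.clip(P, prob_floor, None)
        P = P / P.sum(axis=1, keepdims=True)
    fits.fitted_membership_prob = P
    fits.check_invariants()
    return fits


def fit_propensity_models(
    data: TrialCollectionData,
    treatment_formula=None,
    membership_formula=None,
    **kwargs,
) -> PropensityModelSet:
    """Fit both nuisance-model families and merge into one set.

    Keyword arguments (``max_iter``, ``tol``, ``ridge``, ``prob_floor``,
    ``allow_nonconvergence``) are forwarded to both fitters.
    """
    t = fit_treatment_models(data, treatment_formula, **kwargs)
    p = fit_membership_model(data, membership_formula, **kwargs)
    return t.merge(p)
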