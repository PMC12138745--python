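"""Point estimators of the target-population average treatment effect (TATE).

All estimators are self-normalized (Hajek) weighted contrasts

    Delta_hat = sum_i w_i(1) Y_i / sum_i w_i(1) - sum_i w_i(0) Y_i / sum_i w_i(0)

and differ only in the unit weights:

* ``unadjusted`` — arm indicators over the pooled study sample; no
  adjustment for treatment assignment or study selection.
* ``pooled`` — inverse-probability-of-treatment weight times the inverse
  odds of study participation, P(S=0|X) / (1 - P(S=0|X)); the studies are
  treated as one sample.
* ``study_specific`` — within study s, the IPTW times the inverse odds of
  being in study s rather than the target, P(S=0|X) / P(S=s|X).  The
  per-study transported estimates are then combined by strictly positive
  study-level weights (equal by default) into the two-stage estimate.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .data_model import TrialCollectionData
from .errors import DegenerateWeightsError, PositivityError, ValidationError
from .propensity import PropensityModelSet

__all__ = [
    "UnitWeightSet",
    "StudyTateEstimate",
    "TwoStageEstimate",
    "compute_unit_weights",
    "estimate_unadjusted",
    "estimate_pooled",
    "estimate_study_tate",
    "estimate_two_stage",
    "estimate_two_stage_from_data",
]

SCHEMES = ("unadjusted", "pooled", "study_specific")
_DEGENERATE_TOL = 1e-12
_POSITIVITY_TOL = 1e-300  # denominators at/under double underflow are treated as zero


@dataclasses.dataclass
class UnitWeightSet:
    """Per-record weights for each arm under one weighting scheme.

    ``w_treated[i]`` is the weight record ``i`` contributes to the treated
    arm mean (zero unless ``A_i = 1`` and ``S_i != 0``), similarly
    ``w_control``.  Under the study-specific scheme the stored weight is the
    one for the record's own study.
    """

    scheme: str
    w_treated: np.ndarray
    w_control: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown weighting scheme {self.scheme!r}")
        if (self.w_treated < 0).any() or (self.w_control < 0).any():
            raise ValidationError("weights must be non-negative")


@dataclasses.dataclass
class StudyTateEstimate:
    """A single study's transported (target-weighted) effect estimate."""

    study: int
    delta_hat: float
    arm_weight_sums: tuple[float, float]  # (treated, control)
    effective_sample_sizes: tuple[float, float]

    def __post_init__(self) -> None:
        if min(self.arm_weight_sums) <= 0:
            raise ValidationError(f"study {self.study}: arm weight sums must be positive")


@dataclasses.dataclass
class TwoStageEstimate:
    """Study-level weighted average of transported study estimates."""

    study_estimates: list[StudyTateEstimate]
    study_weights: np.ndarray
    delta_hat: float

    def __post_init__(self) -> None:
        if (np.asarray(self.study_weights) <= 0).any():
            raise ValidationError("study-level weights must be strictly positive")


def _check_positive(denom: np.ndarray, rows: np.ndarray, what: str) -> None:
    bad = denom <= _POSITIVITY_TOL
    if bad.any():
        i = int(np.flatnonzero(rows)[np.argmax(bad)])
        raise PositivityError(f"zero {what} for record {i}")


def compute_unit_weights(
    data: TrialCollectionData,
    fits: PropensityModelSet | None,
    scheme: str,
) -> UnitWeightSet:
    """Compute per-record arm weights under the requested scheme.

    Raises :class:`PositivityError` if any required denominator probability
    is (numerically) zero.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown weighting scheme {scheme!r}")
    in_study = data.study_mask
    treated = in_study & (data.arm == 1.0)
    control = in_study & (data.arm == 0.0)
    if scheme == "unadjusted":
        return UnitWeightSet(scheme, treated.astype(float), control.astype(float))

    if fits is None or fits.fitted_treatment_prob is None or fits.fitted_membership_prob is None:
        raise ValidationError(f"scheme {scheme!r} requires fitted propensity models")
    p1 = fits.fitted_treatment_prob  # P(A=1 | X, S)
    P = fits.fitted_membership_prob
    p0x = P[:, 0]

    w1 = np.zeros(data.n)
    w0 = np.zeros(data.n)
    if scheme == "pooled":
        denom_t = p1[treated]
        denom_c = 1.0 - p1[control]
        _check_positive(denom_t, treated, "treatment propensity")
        _check_positive(denom_c, control, "control propensity")
        odds_denom = 1.0 - p0x[in_study]
        _check_positive(odds_denom, in_study, "study-participation probability")
        odds = p0x[in_study] / (1.0 - p0x[in_study])
        iosw = np.zeros(data.n)
        iosw[in_study] = odds
        w1[treated] = iosw[treated] / denom_t
        w0[control] = iosw[control] / denom_c
    else:  # study_specific
        ps = P[np.arange(data.n), data.study]  # P(S = S_i | X_i)
        _check_positive(ps[in_study], in_study, "study-membership probability")
        denom_t = p1[treated]
        denom_c = 1.0 - p1[control]
        _check_positive(denom_t, treated, "treatment propensity")
        _check_positive(denom_c, control, "control propensity")
        ratio = np.zeros(data.n)
        ratio[in_study] = p0x[in_study] / ps[in_study]
        w1[treated] = ratio[treated] / denom_t
        w0[control] = ratio[control] / denom_c
    return UnitWeightSet(scheme, w1, w0)


def _hajek_contrast(y: np.ndarray, w1: np.ndarray, w0: np.ndarray, label: str) -> float:
    s1, s0 = w1.sum(), w0.sum()
    if s1 <= _DEGENERATE_TOL:
        raise DegenerateWeightsError(f"{label}: treated arm has zero total weight")
    if s0 <= _DEGENERATE_TOL:
        raise DegenerateWeightsError(f"{label}: control arm has zero total weight")
    return float(np.dot(w1, y) / s1 - np.dot(w0, y) / s0)


def estimate_unadjusted(data: TrialCollectionData) -> float:
    """Difference of raw arm means over the pooled study sample."""
    w = compute_unit_weights(data, None, "unadjusted")
    y = np.where(data.study_mask, data.outcome, 0.0)
    return _hajek_contrast(y, w.w_treated, w.w_control, "unadjusted")


def estimate_pooled(data: TrialCollectionData, fits: PropensityModelSet) -> float:
    """IPTW x inverse-odds-of-participation weighted contrast over the
    pooled study sample."""
    w = compute_unit_weights(data, fits, "pooled")
    y = np.where(data.study_mask, data.outcome, 0.0)
    return _hajek_contrast(y, w.w_treated, w.w_control, "pooled")


def _ess(w: np.ndarray) -> float:
    s = w.sum()
    q = np.dot(w, w)
    return float(s * s / q) if q > 0 else 0.0


def estimate_study_tate(
    data: TrialCollectionData,
    fits: PropensityModelSet,
    study: int,
    weights: UnitWeightSet | None = None,
) -> StudyTateEstimate:
    """Transported effect estimate for one study (self-normalized within
    each arm of that study)."""
    if study not in set(data.study_labels.tolist()):
        raise ValidationError(f"unknown study label {study}")
    w = weights if weights is not None else compute_unit_weights(data, fits, "study_specific")
    rows = data.study == study
    y = data.outcome[rows]
    w1 = w.w_treated[rows]
    w0 = w.w_control[rows]
    delta = _hajek_contrast(y, w1, w0, f"study {study}")
    return StudyTateEstimate(
        study=int(study),
        delta_hat=delta,
        arm_weight_sums=(float(w1.sum()), float(w0.sum())),
        effective_sample_sizes=(_ess(w1), _ess(w0)),
    )


def estimate_two_stage(
    study_estimates: Sequence[StudyTateEstimate],
    study_weights: Sequence[float] | Mapping[int, float] | None = None,
) -> TwoStageEstimate:
    """Combine per-study transported estimates with strictly positive
    study-level weights (equal weights by default)."""
    if not study_estimates:
        raise ValidationError("at least one study estimate is required")
    ests = list(study_estimates)
    if study_weights is None:
        w = np.ones(len(ests))
    elif isinstance(study_weights, Mapping):
        w = np.array([float(study_weights[e.study]) for e in ests])
    else:
        w = np.asarray(list(study_weights), dtype=float)
        if w.shape[0] != len(ests):
            raise ValidationError("study_weights length does not match estimates")
    if (w <= 0).any():
        raise ValidationError("study-level weights must be strictly positive")
    deltas = np.array([e.delta_hat for e in ests])
    delta = float(np.dot(w, deltas) / w.sum())
    return TwoStageEstimate(study_estimates=ests, study_weights=w, delta_hat=delta)


def estimate_two_stage_from_data(
    data: TrialCollectionData,
    fits: PropensityModelSet,
    study_weights=None,
    on_degenerate: str = "raise",
) -> TwoStageEstimate:
    """Full first+second stage from data and fitted nuisance models.

    ``on_degenerate='skip'`` drops studies whose arm weight mass vanished
    instead of raising; if all studies are dropped the error propagates.
    """
    w = compute_unit_weights(data, fits, "study_specific")
    ests: list[StudyTateEstimate] = []
    for s in data.study_labels:
        try:
            ests.append(estimate_study_tate(data, fits, int(s), weights=w))
        except DegenerateWeightsError:
            if on_degenerate == "raise":
                raise
    if not ests:
        raise DegenerateWeightsError("all study estimates degenerate")
    return estimate_two_stage(ests, study_weights)
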