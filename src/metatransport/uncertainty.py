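"""Stratified bootstrap uncertainty quantification for TATE estimators.

The resampling scheme mirrors the assumed data-generating hierarchy:

1. the target sample is resampled with replacement at its original size;
2. the m studies are drawn with replacement with equal probability
   (capturing between-study heterogeneity);
3. within each drawn study, each treatment arm is resampled with
   replacement at its original arm size, preserving the observed designs.

A study drawn more than once enters the replicate as distinct relabeled
studies, so the membership model and the (equal) study-level weights see m
studies in every replicate.  All nuisance models are refitted on every
replicate so the standard error reflects their estimation uncertainty.
Replicates on which estimation fails (positivity, degenerate weights,
non-convergence) are recorded as missing, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable

import numpy as np

from .data_model import TrialCollectionData
from .errors import (
    ConvergenceError,
    DegenerateWeightsError,
    PositivityError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapSummary",
    "stratified_bootstrap",
    "resample_collection",
    "percentile_interval",
    "missing_sensitivity",
]

_RECOVERABLE = (
    PositivityError,
    DegenerateWeightsError,
    ConvergenceError,
    np.linalg.LinAlgError,
    FloatingPointError,
)


@dataclasses.dataclass
class BootstrapSummary:
    """Replicate estimates (NaN = missing) with summary statistics."""

    replicate_estimates: np.ndarray
    B: int
    se_hat: float
    percentile_ci: tuple[float, float]
    n_missing: int
    seed: int
    level: float = 0.95
    failure_log: list[str] = dataclasses.field(default_factory=list)

    @property
    def missing_rate(self) -> float:
        return self.n_missing / self.B


def resample_collection(data: TrialCollectionData, rng: np.random.Generator) -> TrialCollectionData:
    """One stratified bootstrap replicate of the data (see module docstring).

    Drawn studies are relabeled 1..m in draw order.
    """
    m = data.m
    target_idx = np.flatnonzero(data.target_mask)
    pieces = [rng.choice(target_idx, size=target_idx.size, replace=True)]
    labels = [np.zeros(target_idx.size, dtype=int)]
    drawn = rng.integers(1, m + 1, size=m)
    for new_label, s in enumerate(drawn, start=1):
        for arm in (1.0, 0.0):
            idx = np.flatnonzero((data.study == s) & (data.arm == arm))
            pieces.append(rng.choice(idx, size=idx.size, replace=True))
            labels.append(np.full(idx.size, new_label, dtype=int))
    rows = np.concatenate(pieces)
    return TrialCollectionData(
        study=np.concatenate(labels),
        arm=data.arm[rows],
        outcome=data.outcome[rows],
        covariates=data.covariates[rows],
        covariate_names=data.covariate_names,
    )


def stratified_bootstrap(
    data: TrialCollectionData,
    estimator: Callable[[TrialCollectionData], float],
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapSummary:
    """Run ``B`` stratified bootstrap replicates of ``estimator``.

    ``estimator`` maps a :class:`TrialCollectionData` to a point estimate
    and is expected to refit any nuisance models internally.  Each replicate
    uses an independent child stream of ``seed``, so results are identical
    for identical inputs and reproducible under parallel execution.
    """
    if B < 1:
        raise ValidationError("B must be at least 1")
    estimates = np.full(B, np.nan)
    failures: list[str] = []
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        replicate = resample_collection(data, rng)
        try:
            estimates[b] = float(estimator(replicate))
        except _RECOVERABLE as exc:
            failures.append(f"replicate {b}: {type(exc).__name__}: {exc}")
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
    ok = np.isfinite(estimates)
    n_missing = int(B - ok.sum())
    if ok.sum() >= 2:
        se = float(np.std(estimates[ok], ddof=1))
        ci = percentile_interval(estimates, level)
    elif ok.sum() == 1:
        se, ci = 0.0, (float(estimates[ok][0]), float(estimates[ok][0]))
    else:
        raise DegenerateWeightsError("every bootstrap replicate failed")
    return BootstrapSummary(
        replicate_estimates=estimates,
        B=B,
        se_hat=se,
        percentile_ci=ci,
        n_missing=n_missing,
        seed=seed,
        level=level,
        failure_log=failures,
    )


def percentile_interval(replicates: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """(alpha/2, 1-alpha/2) empirical percentiles of the non-missing
    replicates, linearly interpolated between order statistics."""
    vals = np.asarray(replicates, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValidationError("at least 2 non-missing replicates are required")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    alpha = 1.0 - level
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)], method="linear")
    return float(lo), float(hi)


def missing_sensitivity(
    summary: BootstrapSummary, level: float | None = None
) -> dict[str, tuple[float, float]]:
    """Sensitivity of the percentile interval to missing replicates.

    Recomputes the interval three times with the missing replicates imputed
    (a) strictly below the minimum non-missing estimate, (b) at the mean of
    the non-missing estimates, and (c) strictly above the maximum.  With no
    missing replicates all three equal the primary interval.
    """
    level = summary.level if level is None else level
    vals = summary.replicate_estimates
    ok = np.isfinite(vals)
    observed = vals[ok]
    spread = observed.std(ddof=1) if observed.size > 1 else 1.0
    offset = spread if spread > 0 else 1.0
    out = {}
    for key, fill in (
        ("lower_than_all", observed.min() - offset),
        ("at_mean", observed.mean()),
        ("higher_than_all", observed.max() + offset),
    ):
        imputed = np.where(ok, vals, fill)
        out[key] = percentile_interval(imputed, level)
    return out
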