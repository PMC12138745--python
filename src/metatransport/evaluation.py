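"""Simulation-study harness: performance metrics with Monte Carlo standard
errors, and positivity diagnostics for fitted membership models.

Metric conventions (K = number of non-missing replicates, est_k the
replicate estimates, Delta the truth):

* bias    = mean(est) - Delta;               MCSE = EmpSE / sqrt(K)
* EmpSE   = SD(est) (ddof = 1);              MCSE = EmpSE / sqrt(2 (K - 1))
* MSE     = mean((est - Delta)^2);           MCSE = SD((est - Delta)^2) / sqrt(K)
* coverage = fraction of intervals containing Delta;
             MCSE = sqrt(c (1 - c) / K)
* relative SE error = 100 (ModSE / EmpSE - 1), ModSE = sqrt(mean(boot_se^2));
             MCSE by leave-one-replicate-out jackknife
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import TrialCollectionData
from .errors import TransportError, ValidationError
from .estimators import (
    estimate_pooled,
    estimate_two_stage_from_data,
    estimate_unadjusted,
)
from .propensity import PropensityModelSet, fit_propensity_models
from .simulation import SimulationConfig, simulate_dataset, true_tate
from .uncertainty import stratified_bootstrap

logger = logging.getLogger(__name__)

__all__ = [
    "PerformanceTable",
    "PositivityReport",
    "compute_metrics",
    "run_simulation_study",
    "positivity_diagnostics",
    "make_estimator",
]

ESTIMATORS = ("unadjusted", "pooled", "two_stage")

METRIC_COLUMNS = [
    "bias", "bias_mcse", "empse", "empse_mcse", "mse", "mse_mcse",
    "coverage", "coverage_mcse", "rel_error_pct", "rel_error_mcse",
    "n_used", "n_missing",
]


@dataclasses.dataclass
class PerformanceTable:
    """Per-estimator metric rows, the replication count and the truth."""

    frame: pd.DataFrame
    K: int
    truth: float

    def __post_init__(self) -> None:
        f = self.frame
        if (f["mse"].dropna() < 0).any() or (f["empse"].dropna() < 0).any():
            raise ValidationError("MSE and EmpSE must be non-negative")
        cov = f["coverage"].dropna()
        if ((cov < 0) | (cov > 1)).any():
            raise ValidationError("coverage must lie in [0, 1]")


@dataclasses.dataclass
class PositivityReport:
    """Per-study summaries of predicted participation probabilities among
    target-sample members, plus records flagged under the floor."""

    frame: pd.DataFrame  # index: study; columns mean, sd, min, max
    flags: list[tuple[int, int, float]]  # (study, record index, probability)
    floor: float


def compute_metrics(
    estimates: Sequence[float],
    truth: float,
    intervals: Sequence[tuple[float, float]] | None = None,
    boot_ses: Sequence[float] | None = None,
) -> dict[str, float]:
    """One performance-table row from per-replicate results.

    Missing (NaN) estimates are excluded and counted; interval/SE vectors,
    when given, must align with ``estimates`` replicate-for-replicate.
    """
    est = np.asarray(estimates, dtype=float)
    if intervals is not None and len(intervals) != est.size:
        raise ValidationError("intervals length does not match estimates")
    if boot_ses is not None and len(boot_ses) != est.size:
        raise ValidationError("boot_ses length does not match estimates")
    ok = np.isfinite(est)
    k = int(ok.sum())
    if k < 2:
        raise ValidationError("at least 2 non-missing estimates are required")
    e = est[ok]
    err = e - truth
    empse = float(np.std(e, ddof=1))
    row: dict[str, float] = {
        "bias": float(err.mean()),
        "bias_mcse": empse / np.sqrt(k),
        "empse": empse,
        "empse_mcse": empse / np.sqrt(2 * (k - 1)),
        "mse": float(np.mean(err**2)),
        "mse_mcse": float(np.std(err**2, ddof=1) / np.sqrt(k)),
        "coverage": np.nan,
        "coverage_mcse": np.nan,
        "rel_error_pct": np.nan,
        "rel_error_mcse": np.nan,
        "n_used": k,
        "n_missing": int(est.size - k),
    }
    if intervals is not None:
        arr = np.asarray(intervals, dtype=float)[ok]
        hit = (arr[:, 0] <= truth) & (truth <= arr[:, 1])
        c = float(hit.mean())
        row["coverage"] = c
        row["coverage_mcse"] = float(np.sqrt(c * (1 - c) / k))
    if boot_ses is not None:
        ses = np.asarray(boot_ses, dtype=float)[ok]
        if not np.isfinite(ses).all():
            raise ValidationError("boot_ses must be non-missing where estimates are")
        modse = float(np.sqrt(np.mean(ses**2)))
        row["rel_error_pct"] = 100.0 * (modse / empse - 1.0)
        # leave-one-out jackknife for the MCSE of the relative error
        jk = np.empty(k)
        sum_sq_se = np.sum(ses**2)
        for i in range(k):
            e_i = np.delete(e, i)
            empse_i = np.std(e_i, ddof=1)
            modse_i = np.sqrt((sum_sq_se - ses[i] ** 2) / (k - 1))
            jk[i] = 100.0 * (modse_i / empse_i - 1.0)
        row["rel_error_mcse"] = float(np.sqrt((k - 1) / k * np.sum((jk - jk.mean()) ** 2)))
    return row


def make_estimator(scheme: str, **fit_kwargs):
    """A ``data -> point estimate`` callable for one weighting scheme,
    refitting all nuisance models internally (bootstrap contract)."""
    if scheme == "unadjusted":
        return estimate_unadjusted
    if scheme == "pooled":
        def _pooled(data: TrialCollectionData) -> float:
            return estimate_pooled(data, fit_propensity_models(data, **fit_kwargs))
        return _pooled
    if scheme == "two_stage":
        def _two(data: TrialCollectionData) -> float:
            fits = fit_propensity_models(data, **fit_kwargs)
            return estimate_two_stage_from_data(data, fits).delta_hat
        return _two
    raise ValidationError(f"unknown estimator {scheme!r}")


def run_simulation_study(
    config: SimulationConfig,
    K: int,
    estimators: Sequence[str] = ESTIMATORS,
    bootstrap: Mapping[str, float] | None = None,
    seed: int = 0,
    mc_truth_size: int = 1_000_000,
    fit_kwargs: Mapping | None = None,
) -> PerformanceTable:
    """Replicate the full pipeline K times and summarize estimator
    performance against the analytic truth.

    Per replicate: simulate a dataset, fit the nuisance models, evaluate
    each requested estimator, and (optionally, when ``bootstrap`` supplies
    ``{"B": ..., "level": ...}``) run the stratified bootstrap to obtain a
    standard error and percentile interval.  Failed replicates are recorded
    missing and excluded from the metrics with a logged rate.
    """
    if K < 2:
        raise ValidationError("K must be at least 2")
    unknown = set(estimators) - set(ESTIMATORS)
    if unknown:
        raise ValidationError(f"unknown estimators {sorted(unknown)}")
    fit_kwargs = dict(fit_kwargs or {})
    truth = true_tate(config, mc_size=mc_truth_size, seed=seed)

    est_values = {name: np.full(K, np.nan) for name in estimators}
    ci_values = {name: np.full((K, 2), np.nan) for name in estimators}
    se_values = {name: np.full(K, np.nan) for name in estimators}
    for k in range(K):
        rep_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)
        try:
            ds = simulate_dataset(config, seed=rep_seed)
        except TransportError as exc:
            logger.warning("replication %d: simulation failed: %s", k, exc)
            continue
        fits: PropensityModelSet | None = None
        need_fits = {"pooled", "two_stage"} & set(estimators)
        if need_fits:
            try:
                fits = fit_propensity_models(ds.data, **fit_kwargs)
            except TransportError as exc:
                logger.warning("replication %d: propensity fit failed: %s", k, exc)
        for name in estimators:
            try:
                if name == "unadjusted":
                    est_values[name][k] = estimate_unadjusted(ds.data)
                elif fits is None:
                    continue
                elif name == "pooled":
                    est_values[name][k] = estimate_pooled(ds.data, fits)
                else:
                    est_values[name][k] = estimate_two_stage_from_data(ds.data, fits).delta_hat
            except TransportError as exc:
                logger.warning("replication %d: %s failed: %s", k, name, exc)
                continue
            if bootstrap is not None and np.isfinite(est_values[name][k]):
                summary = stratified_bootstrap(
                    ds.data,
                    make_estimator(name, **fit_kwargs),
                    B=int(bootstrap.get("B", 1000)),
                    seed=rep_seed,
                    level=float(bootstrap.get("level", 0.95)),
                )
                ci_values[name][k] = summary.percentile_ci
                se_values[name][k] = summary.se_hat

    rows = {}
    for name in estimators:
        est = est_values[name]
        if np.isfinite(est).sum() < 2:
            raise TransportError(f"all replications failed for estimator {name!r}")
        kwargs = {}
        if bootstrap is not None:
            kwargs = {"intervals": ci_values[name], "boot_ses": se_values[name]}
        rows[name] = compute_metrics(est, truth, **kwargs)
        miss = rows[name]["n_missing"]
        if miss:
            logger.info("estimator %s: %d/%d replications missing", name, miss, K)
    frame = pd.DataFrame.from_dict(rows, orient="index")[METRIC_COLUMNS]
    frame.index.name = "estimator"
    return PerformanceTable(frame=frame, K=K, truth=truth)


def positivity_diagnostics(
    data: TrialCollectionData,
    fits: PropensityModelSet,
    floor: float = 0.01,
) -> PositivityReport:
    """Summarize predicted study-participation probabilities for target rows.

    For each study s the report gives the mean, SD and range of the fitted
    membership probability p_hat(x, s) over the target sample; entries below
    ``floor`` are flagged as practical positivity concerns.
    """
    if fits.fitted_membership_prob is None:
        raise ValidationError("membership model is not fitted")
    tgt = np.flatnonzero(data.target_mask)
    if tgt.size == 0:
        raise ValidationError("no target rows")
    P = fits.fitted_membership_prob[tgt]
    rows = {}
    flags: list[tuple[int, int, float]] = []
    for s in data.study_labels:
        p = P[:, s]
        rows[int(s)] = {
            "mean": float(p.mean()),
            "sd": float(p.std(ddof=1)) if p.size > 1 else 0.0,
            "min": float(p.min()),
            "max": float(p.max()),
        }
        for j in np.flatnonzero(p < floor):
            flags.append((int(s), int(tgt[j]), float(p[j])))
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "study"
    return PositivityReport(frame=frame, flags=flags, floor=floor)
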