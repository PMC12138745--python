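"""Individual-participant-data container for a collection of randomized
trials plus a covariate-only sample from a target population.

The unified table has one row per individual.  Study membership is coded by
an integer label ``S`` in ``0..m`` where ``S = 0`` marks the target sample;
target rows carry baseline covariates only (treatment arm and outcome are
structurally missing), study rows carry a binary arm (1 = treatment,
0 = control), an outcome and complete covariates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = ["TrialCollectionData", "load_ipd", "write_ipd"]

#: default column names for the delimited-text dialect
DEFAULT_SCHEMA = {"study": "study", "arm": "arm", "outcome": "outcome"}


@dataclasses.dataclass
class TrialCollectionData:
    """Validated IPD for ``m`` two-arm trials and one target sample.

    Parameters
    ----------
    study
        Integer labels, shape ``(n,)``; ``0`` is the target sample and
        ``1..m`` are studies.  Labels must be contiguous.
    arm
        Float array, shape ``(n,)``; ``1.0`` treatment, ``0.0`` control,
        ``NaN`` on target rows.
    outcome
        Float array, shape ``(n,)``; ``NaN`` on target rows.
    covariates
        Float array, shape ``(n, p)``, no missing entries.
    covariate_names
        Column names for the covariates, length ``p``.
    """

    study: np.ndarray
    arm: np.ndarray
    outcome: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.study = np.asarray(self.study, dtype=int)
        self.arm = np.asarray(self.arm, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.study.shape[0]:
            self.covariates = self.covariates.T
        if not self.covariate_names:
            self.covariate_names = tuple(
                f"x{j + 1}" for j in range(self.covariates.shape[1])
            )
        else:
            self.covariate_names = tuple(self.covariate_names)
        self.validate()

    # -- basic shape accessors -------------------------------------------
    @property
    def n(self) -> int:
        return int(self.study.shape[0])

    @property
    def m(self) -> int:
        """Number of studies (target sample excluded)."""
        return int(self.study.max())

    @property
    def p(self) -> int:
        return int(self.covariates.shape[1])

    @property
    def n_s(self) -> np.ndarray:
        """Sample size per source, index ``0..m``."""
        return np.bincount(self.study, minlength=self.m + 1)

    @property
    def target_mask(self) -> np.ndarray:
        return self.study == 0

    @property
    def study_mask(self) -> np.ndarray:
        return self.study != 0

    @property
    def study_labels(self) -> np.ndarray:
        return np.arange(1, self.m + 1)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check every structural invariant; raise ValidationError on the
        first violation, naming the rule and offending study."""
        if self.study.ndim != 1 or self.arm.ndim != 1 or self.outcome.ndim != 1:
            raise ValidationError("study, arm and outcome must be 1-d")
        n = self.study.shape[0]
        if self.arm.shape[0] != n or self.outcome.shape[0] != n:
            raise ValidationError("study, arm and outcome lengths differ")
        if self.covariates.shape != (n, len(self.covariate_names)):
            raise ValidationError(
                "covariate matrix shape does not match records/names"
            )
        if n == 0:
            raise ValidationError("empty data")
        if self.study.min() < 0:
            raise ValidationError("study labels must be non-negative")
        labels = np.unique(self.study)
        m = int(self.study.max())
        if m < 1:
            raise ValidationError("at least one study (label >= 1) is required")
        missing_labels = set(range(m + 1)) - set(labels.tolist())
        if missing_labels:
            raise ValidationError(
                f"study labels must be contiguous 0..{m}; missing {sorted(missing_labels)}"
            )
        if not np.all(np.isfinite(self.covariates)):
            raise ValidationError("covariates must be complete (no missing values)")

        tgt = self.study == 0
        if not tgt.any():
            raise ValidationError("a target sample (study 0) is required")
        if np.isfinite(self.outcome[tgt]).any():
            raise ValidationError("target rows must not carry outcomes")
        if np.isfinite(self.arm[tgt]).any():
            raise ValidationError("target rows must not carry treatment arms")

        for s in range(1, m + 1):
            rows = self.study == s
            arm_s = self.arm[rows]
            if not np.all(np.isfinite(arm_s)):
                raise ValidationError(f"study {s}: treatment arm is missing on some rows")
            if not np.isin(arm_s, (0.0, 1.0)).all():
                raise ValidationError(f"study {s}: arm codes must be 0 or 1")
            if not np.all(np.isfinite(self.outcome[rows])):
                raise ValidationError(f"study {s}: outcome is missing on some rows")
            if not (arm_s == 1.0).any() or not (arm_s == 0.0).any():
                raise ValidationError(f"single-arm study: study {s} lacks one arm")

    # -- conversions ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"study": self.study, "arm": self.arm, "outcome": self.outcome})
        for j, name in enumerate(self.covariate_names):
            frame[name] = self.covariates[:, j]
        return frame

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        schema: Mapping[str, object] | None = None,
        drop_incomplete: bool = False,
    ) -> "TrialCollectionData":
        """Build a validated container from a DataFrame.

        ``schema`` may remap the ``study``/``arm``/``outcome`` columns and
        list the covariate columns (key ``covariates``); by default every
        other column is a covariate.  With ``drop_incomplete`` rows with
        missing covariates are dropped (count logged) instead of rejected.
        """
        schema = dict(DEFAULT_SCHEMA, **(schema or {}))
        for key in ("study", "arm", "outcome"):
            if schema[key] not in frame.columns:
                raise ParseError(f"required column {schema[key]!r} not found")
        cov_cols = schema.get("covariates")
        if cov_cols is None:
            reserved = {schema["study"], schema["arm"], schema["outcome"]}
            cov_cols = [c for c in frame.columns if c not in reserved]
        cov_cols = list(cov_cols)
        if not cov_cols:
            raise ParseError("no covariate columns found")

        study_raw = pd.to_numeric(frame[schema["study"]], errors="coerce")
        if study_raw.isna().any():
            row = int(study_raw.index[study_raw.isna()][0])
            raise ParseError(f"non-numeric or missing study label at row {row}")
        cov = frame[cov_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
        if drop_incomplete:
            keep = np.isfinite(cov).all(axis=1)
            dropped = int((~keep).sum())
            if dropped:
                import logging

                logging.getLogger(__name__).warning(
                    "dropped %d rows with incomplete covariates", dropped
                )
            frame = frame.loc[keep]
            cov = cov[keep]
            study_raw = study_raw.loc[keep]
        return cls(
            study=study_raw.to_numpy(int),
            arm=pd.to_numeric(frame[schema["arm"]], errors="coerce").to_numpy(float),
            outcome=pd.to_numeric(frame[schema["outcome"]], errors="coerce").to_numpy(float),
            covariates=cov,
            covariate_names=tuple(str(c) for c in cov_cols),
        )

    def subset(self, mask: np.ndarray) -> pd.DataFrame:
        """Row-subset view as a DataFrame (no revalidation)."""
        return self.to_frame().loc[np.asarray(mask)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialCollectionData):
            return NotImplemented
        return (
            np.array_equal(self.study, other.study)
            and np.array_equal(self.arm, other.arm, equal_nan=True)
            and np.array_equal(self.outcome, other.outcome, equal_nan=True)
            and np.array_equal(self.covariates, other.covariates)
            and self.covariate_names == other.covariate_names
        )


def load_ipd(
    path: str | Path,
    schema: Mapping[str, object] | None = None,
    drop_incomplete: bool = False,
) -> TrialCollectionData:
    """Read a validated :class:`TrialCollectionData` from a CSV file.

    Missing values may be written as empty fields or as the literal ``NA``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        frame = pd.read_csv(
            path,
            keep_default_na=True,
            na_values=["NA", ""],
            comment="#",
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"malformed delimited file {path}: {exc}") from exc
    if frame.empty:
        raise ParseError(f"empty file: {path}")
    return TrialCollectionData.from_frame(frame, schema=schema, drop_incomplete=drop_incomplete)


def write_ipd(data: TrialCollectionData, path: str | Path) -> None:
    """Write the container as CSV; missing fields are written empty."""
    data.to_frame().to_csv(path, index=False, na_rep="")


def concat_target(
    data_frame: pd.DataFrame,
    target_frame: pd.DataFrame,
    schema: Mapping[str, object] | None = None,
) -> TrialCollectionData:
    """Combine a study-only table with a separate covariate-only target
    table, relabeling the latter to study 0."""
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    target = target_frame.copy()
    target[schema["study"]] = 0
    for col in (schema["arm"], schema["outcome"]):
        target[col] = np.nan
    combined = pd.concat([data_frame, target], ignore_index=True, sort=False)
    return TrialCollectionData.from_frame(combined, schema=schema)
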