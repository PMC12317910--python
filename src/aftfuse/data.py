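"""Core data container and CSV/JSON interchange.

A :class:`SurvivalDataset` holds one row per subject: the observed (possibly
censored) time ``T = min(T~, C)``, the event indicator ``delta = 1{T~ <= C}``,
the binary treatment ``A``, the source flag ``S`` (1 = randomized trial,
0 = real-world data) and a covariate matrix ``X`` without an intercept column
(estimators append unpenalized intercepts internally). Times are stored on the
natural scale; all model fitting happens on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "Violation",
    "read_dataset",
    "write_dataset",
    "validate",
]

#: default CSV column names for the four subject-level vectors
DEFAULT_COLUMNS = {"time": "time", "event": "event", "treatment": "treatment", "source": "source"}


@dataclass(frozen=True)
class Violation:
    """A single validation finding. ``level`` is 'error' or 'warning'."""

    level: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.field}: {self.message}"


@dataclass
class SurvivalDataset:
    """Aligned per-subject vectors plus the covariate matrix.

    Parameters
    ----------
    time : (n,) strictly positive observed times.
    event : (n,) indicator, 1 = failure observed, 0 = censored.
    treatment : (n,) binary treatment A.
    source : (n,) binary source S, 1 = RCT, 0 = RWD.
    covariates : (n, p) real matrix, no intercept column.
    covariate_names : optional column labels (default x1..xp).
    """

    time: np.ndarray
    event: np.ndarray
    treatment: np.ndarray
    source: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.treatment = np.asarray(self.treatment, dtype=int)
        self.source = np.asarray(self.source, dtype=int)
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(len(self.time), -1) if cov.size else cov.reshape(len(self.time), 0)
        self.covariates = cov
        if self.covariate_names is None:
            self.covariate_names = [f"x{j + 1}" for j in range(self.p)]

    @property
    def n(self) -> int:
        return int(self.time.shape[0])

    @property
    def p(self) -> int:
        return int(self.covariates.shape[1])

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        """Row subset (boolean mask or integer indices), covariates preserved."""
        return SurvivalDataset(
            time=self.time[idx],
            event=self.event[idx],
            treatment=self.treatment[idx],
            source=self.source[idx],
            covariates=self.covariates[idx],
            covariate_names=list(self.covariate_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.time,
                "event": self.event,
                "treatment": self.treatment,
                "source": self.source,
            }
        )
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df


def validate(dataset: SurvivalDataset) -> list[Violation]:
    """Check the container invariants; returns findings, never raises.

    Error-level findings break estimation contracts; the single warning-level
    finding (single-source data) still permits an RCT-only or RWD-only fit.
    """
    out: list[Violation] = []
    n = dataset.n
    for name in ("time", "event", "treatment", "source"):
        vec = getattr(dataset, name)
        if vec.shape[0] != n:
            out.append(Violation("error", name, f"length {vec.shape[0]} != n={n}"))
    if dataset.covariates.shape[0] != n:
        out.append(Violation("error", "covariates", f"{dataset.covariates.shape[0]} rows != n={n}"))
    if n == 0:
        out.append(Violation("error", "time", "empty dataset"))
        return out
    bad = np.flatnonzero(~(dataset.time > 0) | ~np.isfinite(dataset.time))
    if bad.size:
        out.append(Violation("error", "time", f"nonpositive or non-finite time at row {bad[0] + 1}"))
    for name in ("event", "treatment", "source"):
        vec = getattr(dataset, name)
        bad = np.flatnonzero(~np.isin(vec, (0, 1)))
        if bad.size:
            out.append(Violation("error", name, f"non-binary value {vec[bad[0]]} at row {bad[0] + 1}"))
    if not np.all(np.isfinite(dataset.covariates)):
        i, j = np.argwhere(~np.isfinite(dataset.covariates))[0]
        out.append(Violation("error", "covariates", f"missing/non-finite value at row {i + 1}, column {dataset.covariate_names[j]}"))
    if np.all(dataset.source == 1):
        out.append(Violation("warning", "source", "no RWD subjects (S=0); only RCT-only fitting is possible"))
    elif np.all(dataset.source == 0):
        out.append(Violation("warning", "source", "no RCT subjects (S=1); integrative fitting unavailable"))
    return out


class DatasetValidationError(ValueError):
    """Raised by read_dataset when a hard invariant fails."""


def _raise_on_errors(violations: Sequence[Violation]) -> None:
    errors = [v for v in violations if v.level == "error"]
    if errors:
        raise DatasetValidationError("; ".join(str(v) for v in errors))


def read_dataset(path, column_map: Mapping[str, str] | None = None) -> SurvivalDataset:
    """Read a header-ed CSV into a validated :class:`SurvivalDataset`.

    ``column_map`` maps the roles 'time', 'event', 'treatment', 'source' to CSV
    column names; every remaining column is taken as a covariate, in file
    order. An explicit ``column_map['covariates']`` (list of names) restricts
    and orders the covariate columns.
    """
    cmap = dict(DEFAULT_COLUMNS)
    cov_names: list[str] | None = None
    if column_map:
        cov_names = list(column_map["covariates"]) if "covariates" in column_map else None
        cmap.update({k: v for k, v in column_map.items() if k in DEFAULT_COLUMNS})
    df = pd.read_csv(path)
    for role, col in cmap.items():
        if col not in df.columns:
            raise DatasetValidationError(f"missing column '{col}' (role: {role})")
    if cov_names is None:
        cov_names = [c for c in df.columns if c not in set(cmap.values())]
    else:
        missing = [c for c in cov_names if c not in df.columns]
        if missing:
            raise DatasetValidationError(f"missing covariate column(s): {missing}")
    na_cells = df[list(cmap.values()) + cov_names].isna()
    if na_cells.to_numpy().any():
        i = int(np.argwhere(na_cells.to_numpy())[0, 0])
        col = na_cells.columns[int(np.argwhere(na_cells.to_numpy())[0, 1])]
        raise DatasetValidationError(f"NA cell at row {i + 1}, column {col}")
    ds = SurvivalDataset(
        time=df[cmap["time"]].to_numpy(float),
        event=df[cmap["event"]].to_numpy(),
        treatment=df[cmap["treatment"]].to_numpy(),
        source=df[cmap["source"]].to_numpy(),
        covariates=df[cov_names].to_numpy(float) if cov_names else np.empty((len(df), 0)),
        covariate_names=cov_names,
    )
    _raise_on_errors(validate(ds))
    return ds


def write_dataset(dataset: SurvivalDataset, path) -> None:
    """Write the dataset as a comma-separated, '.'-decimal, UTF-8 CSV.

    Column order is deterministic: time, event, treatment, source, then the
    covariates in stored order, so ``read_dataset(write_dataset(ds))`` is the
    identity.
    """
    dataset.to_frame().to_csv(path, index=False)
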