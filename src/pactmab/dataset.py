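"""Replicate confluence datasets and their tidy-CSV representation.

The experimental unit is one condition (regimen + doses) measured as
fractional confluence in 8 replicate wells every 3 hours for 4 days.  The
calibration consumes the per-timepoint mean and 95% confidence-interval
half-width (t-distribution on n-1 degrees of freedom; 8 replicates is a
small sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ConfluenceDataset", "read_confluence_csv", "write_confluence_csv"]

CSV_COLUMNS = ["condition", "replicate", "time_days", "confluence"]


class DatasetError(ValueError):
    """Malformed confluence data."""


def _ci_halfwidth(values: np.ndarray, level: float = 0.95) -> np.ndarray:
    """95% CI half-width of the mean across replicates (axis 0)."""
    n = values.shape[0]
    if n < 2:
        return np.zeros(values.shape[1])
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    sd = values.std(axis=0, ddof=1)
    return tcrit * sd / np.sqrt(n)


@dataclass
class ConfluenceDataset:
    """Longitudinal confluence measurements for one condition.

    ``replicate_values`` has shape (n_replicates, n_times).  ``mean`` and
    ``ci_halfwidth`` are derived per timepoint unless given explicitly.
    """

    condition: str
    times: np.ndarray
    replicate_values: np.ndarray
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    ci_halfwidth: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.replicate_values = np.atleast_2d(np.asarray(self.replicate_values, dtype=float))
        if self.replicate_values.shape[1] != len(self.times):
            raise DatasetError("replicate_values must have one column per timepoint")
        if np.any(np.diff(self.times) <= 0):
            raise DatasetError("times must be strictly increasing")
        if self.mean is None:
            self.mean = self.replicate_values.mean(axis=0)
        else:
            self.mean = np.asarray(self.mean, dtype=float)
        if self.ci_halfwidth is None:
            self.ci_halfwidth = _ci_halfwidth(self.replicate_values)
        else:
            self.ci_halfwidth = np.asarray(self.ci_halfwidth, dtype=float)

    @property
    def n_replicates(self) -> int:
        return self.replicate_values.shape[0]

    def window(self, t_min: float = -np.inf, t_max: float = np.inf) -> "ConfluenceDataset":
        """Subset to timepoints in [t_min, t_max] (both endpoints included)."""
        mask = (self.times >= t_min - 1e-12) & (self.times <= t_max + 1e-12)
        if not mask.any():
            raise DatasetError(f"no timepoints in [{t_min}, {t_max}]")
        return ConfluenceDataset(
            condition=self.condition,
            times=self.times[mask],
            replicate_values=self.replicate_values[:, mask],
            mean=self.mean[mask],
            ci_halfwidth=self.ci_halfwidth[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_replicates):
            for j, t in enumerate(self.times):
                rows.append((self.condition, r, t, self.replicate_values[r, j]))
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_confluence_csv(datasets, path) -> None:
    """Write one or more datasets as a tidy CSV (condition, replicate,
    time_days, confluence)."""
    if isinstance(datasets, ConfluenceDataset):
        datasets = [datasets]
    pd.concat([d.to_frame() for d in datasets], ignore_index=True).to_csv(path, index=False)


def read_confluence_csv(path, condition: Optional[str] = None):
    """Read a tidy confluence CSV into :class:`ConfluenceDataset` objects.

    Returns a single dataset if ``condition`` is given (or the file holds only
    one condition), else a dict keyed by condition name.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DatasetError(f"{path}: file is empty")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")
    for col in ("replicate", "time_days", "confluence"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            rows = list((df.index[bad | df[col].isna()] + 2)[:5])
            raise DatasetError(f"{path}: non-numeric or missing {col!r} at rows {rows}")
        df[col] = pd.to_numeric(df[col])
    out_of_range = (df["confluence"] < 0) | (df["confluence"] > 1.05)
    if out_of_range.any():
        rows = list((df.index[out_of_range] + 2)[:5])
        raise DatasetError(f"{path}: confluence outside [0, 1.05] at rows {rows}")

    result = {}
    for name, grp in df.groupby("condition", sort=False):
        dup = grp.duplicated(subset=["replicate", "time_days"])
        if dup.any():
            rows = list((grp.index[dup] + 2)[:5])
            raise DatasetError(f"{path}: duplicate (replicate, time) pairs at rows {rows}")
        wide = grp.pivot(index="replicate", columns="time_days", values="confluence")
        wide = wide.sort_index(axis=0).sort_index(axis=1)
        if wide.isna().any().any():
            raise DatasetError(f"{path}: condition {name!r} has unequal replicate grids")
        result[str(name)] = ConfluenceDataset(
            condition=str(name),
            times=wide.columns.to_numpy(dtype=float),
            replicate_values=wide.to_numpy(dtype=float),
        )
    if condition is not None:
        if condition not in result:
            raise DatasetError(f"{path}: condition {condition!r} not present")
        return result[condition]
    if len(result) == 1:
        return next(iter(result.values()))
    return result
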