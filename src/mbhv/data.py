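"""Grouped multivariate observations: loading, validation, centering.

Observations are rows of a numeric matrix ``Y`` (one column per variable)
with a group label per row — e.g. vegetation plots nested in survey squares.
The pooled sample covariance of the raw data, :func:`raw_covariance`, doubles
as the Wishart prior scale for the samplers in :mod:`mbhv.inference`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DegenerateDataError

__all__ = [
    "GroupedObservations",
    "CenteringTransform",
    "load_grouped_csv",
    "center",
    "raw_covariance",
]


@dataclass(frozen=True)
class GroupedObservations:
    """An N x J data matrix with a group code per row.

    Parameters
    ----------
    values
        Float matrix of shape ``(N, J)``; all entries must be finite.
    groups
        Integer codes of shape ``(N,)`` in ``0..K-1``; every code in that
        range must occur at least once.
    variable_names
        ``J`` column labels.
    group_names
        ``K`` group labels, parallel to the codes.
    """

    values: np.ndarray
    groups: np.ndarray
    variable_names: tuple[str, ...]
    group_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        groups = np.asarray(self.groups, dtype=np.intp)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "variable_names", tuple(map(str, self.variable_names)))
        object.__setattr__(self, "group_names", tuple(map(str, self.group_names)))

        if values.ndim != 2:
            raise DataError(f"values must be 2-D, got shape {values.shape}")
        n, j = values.shape
        if len(self.variable_names) != j:
            raise DataError(
                f"{len(self.variable_names)} variable names for {j} columns"
            )
        if groups.shape != (n,):
            raise DataError("groups must be a vector with one entry per row")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite value at row {bad[0]}, "
                f"variable {self.variable_names[bad[1]]!r}"
            )
        k = len(self.group_names)
        if k < 1:
            raise DataError("at least one group is required")
        present = np.unique(groups)
        if present.size != k or present[0] != 0 or present[-1] != k - 1:
            raise DataError(
                "group codes must map bijectively onto 0..K-1 with every "
                "group non-empty"
            )
        if j < 1:
            raise DataError("at least one variable is required")
        if j == 1:
            warnings.warn(
                "J = 1: a single variable defines an interval, not a "
                "hypervolume; proceeding anyway",
                UserWarning,
                stacklevel=2,
            )
        # A singular sample covariance is guaranteed below N = J + 1; between
        # J + 1 and J + 2 it is estimable but fragile.
        if n < j + 1:
            raise DataError(
                f"N = {n} rows cannot identify a {j}x{j} covariance "
                f"(need N >= J + 1 = {j + 1})"
            )
        if n < j + 2:
            warnings.warn(
                f"N = {n} is barely sufficient for J = {j} variables "
                f"(recommend N >= J + 2)",
                UserWarning,
                stacklevel=2,
            )

    # -- basic shape accessors -------------------------------------------

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def group_sizes(self) -> np.ndarray:
        """Observation count per group, shape ``(K,)``."""
        return np.bincount(self.groups, minlength=self.n_groups)

    def group_means(self) -> np.ndarray:
        """Sample mean per group, shape ``(K, J)``."""
        sums = np.zeros((self.n_groups, self.n_vars))
        np.add.at(sums, self.groups, self.values)
        return sums / self.group_sizes()[:, None]

    # -- I/O --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.variable_names))
        df["group"] = [self.group_names[g] for g in self.groups]
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write the observations back to CSV (variables, then a ``group`` column)."""
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CenteringTransform:
    """Per-variable affine transform ``x -> (x - offsets) / scales``.

    ``scales`` defaults to ones (centering only); standardization to unit
    variance is deliberately opt-in, since hypervolume axes are meant to stay
    in the original measurement units.
    """

    offsets: np.ndarray
    scales: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        offsets = np.atleast_1d(np.asarray(self.offsets, dtype=float))
        scales = self.scales
        if scales is None:
            scales = np.ones_like(offsets)
        scales = np.atleast_1d(np.asarray(scales, dtype=float))
        if scales.shape != offsets.shape:
            raise ConfigurationError("offsets and scales must have equal length")
        if np.any(scales <= 0):
            raise ConfigurationError("scales must be strictly positive")
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "scales", scales)

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.offsets) / self.scales

    def invert(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.scales + self.offsets

    def to_json(self) -> str:
        return json.dumps(
            {"offsets": self.offsets.tolist(), "scales": self.scales.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "CenteringTransform":
        obj = json.loads(text)
        return cls(np.asarray(obj["offsets"]), np.asarray(obj["scales"]))


def load_grouped_csv(
    path: str | Path,
    variable_columns: list[str],
    group_column: str,
) -> GroupedObservations:
    """Read grouped observations from a CSV file.

    Group labels are encoded in first-appearance order. Missing or
    non-numeric cells are rejected with the offending row and column named
    (row numbers count the header as line 1, matching what a spreadsheet
    shows).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    try:
        # round_trip parsing keeps write -> read -> write bit-stable
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty file: {path}") from exc
    if df.empty:
        raise DataError(f"no data rows in {path}")

    missing = [c for c in [*variable_columns, group_column] if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"column(s) {missing} not found in {path}; available: "
            f"{list(df.columns)}"
        )
    if len(variable_columns) == 0:
        raise ConfigurationError("at least one variable column is required")

    values = np.empty((len(df), len(variable_columns)), dtype=float)
    for col_idx, col in enumerate(variable_columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad) > 0:
            row = int(bad[0])
            cell = df[col].iloc[row]
            what = "missing value" if pd.isna(cell) else f"non-numeric value {cell!r}"
            raise DataError(
                f"{what} in column {col!r}, data row {row + 1} "
                f"(file line {row + 2})"
            )
        values[:, col_idx] = numeric.to_numpy(dtype=float)

    labels = df[group_column].astype(str)
    group_names = list(pd.unique(labels))
    code_of = {name: i for i, name in enumerate(group_names)}
    codes = labels.map(code_of).to_numpy(dtype=np.intp)

    return GroupedObservations(
        values=values,
        groups=codes,
        variable_names=tuple(variable_columns),
        group_names=tuple(group_names),
    )


def center(
    data: GroupedObservations, scale: bool = False
) -> tuple[GroupedObservations, CenteringTransform]:
    """Subtract each variable's grand mean (optionally divide by its SD).

    Centering is global, not per-group: the hierarchical model's random
    intercepts absorb group-level shifts, and global centering keeps the
    covariance untouched while improving sampler conditioning.
    """
    offsets = data.values.mean(axis=0)
    scales = data.values.std(axis=0, ddof=1) if scale else np.ones(data.n_vars)
    if scale and np.any(scales <= 0):
        raise DegenerateDataError("cannot standardize a constant column")
    transform = CenteringTransform(offsets=offsets, scales=scales)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # shape warnings already issued
        centered = GroupedObservations(
            values=transform.apply(data.values),
            groups=data.groups,
            variable_names=data.variable_names,
            group_names=data.group_names,
        )
    return centered, transform


def raw_covariance(data: GroupedObservations) -> np.ndarray:
    """Pooled sample covariance of the raw data (denominator ``N - 1``).

    This is the structure-blind covariance the empirical model converges to,
    and the Wishart prior scale for both samplers — hence it must be strictly
    positive definite.

    Raises
    ------
    DegenerateDataError
        If the result is singular or indefinite (e.g. a constant column or
        two perfectly collinear columns).
    """
    cov = np.cov(data.values, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    cov = (cov + cov.T) / 2.0
    eigs = np.linalg.eigvalsh(cov)
    if eigs[0] <= eigs[-1] * 1e-10 or eigs[-1] <= 0:
        raise DegenerateDataError(
            "pooled sample covariance is singular or indefinite (smallest "
            f"eigenvalue {eigs[0]:.3e}); remove constant or collinear columns"
        )
    return cov
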