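"""Domain types and CSV readers/writers for curve matrices, covariate tables
and result tables.

Curve matrices are wide-format CSV (one row per observation, columns
``id, t_0001 .. t_K``); covariate tables are plain CSV with columns
``id, ndi, age, neck_length, sex``.  All files are RFC-4180, UTF-8, '.'
decimal separator, and numeric output is written at full double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

RESPONSE_LABELS = ("angle", "velocity", "acceleration")

#: measurement units per kinematic response
RESPONSE_UNITS = {"angle": "deg", "velocity": "deg/s", "acceleration": "deg/s2"}

RESULT_COLUMNS = (
    "response",
    "coefficient",
    "time",
    "method",
    "beta",
    "se",
    "t",
    "p_raw",
    "p_bh",
    "p_by",
)


@dataclass(frozen=True)
class TimeGrid:
    """An ordered grid of K normalized times in [0, 1].

    The default grid is K equally spaced points including both endpoints,
    so landmarks at normalized times 0, 0.5 and 1 are addressable exactly.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("a time grid needs at least two points")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if pts[0] < -1e-12 or pts[-1] > 1 + 1e-12:
            raise ValueError("grid points must lie within [0, 1]")

    @classmethod
    def uniform(cls, k: int) -> "TimeGrid":
        """Equally spaced grid of ``k`` points on [0, 1] inclusive."""
        if k < 2:
            raise ValueError("a time grid needs at least two points")
        return cls(np.linspace(0.0, 1.0, k))

    @property
    def k(self) -> int:
        return self.points.size

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TimeGrid) and np.array_equal(self.points, other.points)

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.points.size, float(self.points[0]), float(self.points[-1])))


@dataclass
class CurveSet:
    """n kinematic curves sampled on a common time grid (one response)."""

    grid: TimeGrid
    values: np.ndarray  # (n, K)
    response_label: str
    observation_ids: Sequence[str]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.response_label not in RESPONSE_LABELS:
            raise ValueError(
                f"response_label must be one of {RESPONSE_LABELS}, got {self.response_label!r}"
            )
        if not self.units:
            self.units = RESPONSE_UNITS[self.response_label]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n, K) matrix")
        n, k = self.values.shape
        if n < 1:
            raise ValueError("a curve set needs at least one observation")
        if k != self.grid.k:
            raise ValueError(f"values have {k} columns but the grid has {self.grid.k} points")
        self.observation_ids = [str(i) for i in self.observation_ids]
        if len(self.observation_ids) != n:
            raise ValueError("observation_ids length must match the number of rows")
        if len(set(self.observation_ids)) != n:
            raise ValueError("observation ids must be unique")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite value for observation {self.observation_ids[i]!r} "
                f"at grid column {j + 1}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class CovariateTable:
    """Per-observation scalar predictors.

    ``ndi`` is the Neck Disability Index on its 0-50 scale, ``age`` in years,
    ``neck_length`` in cm, and ``sex`` coded 0 (female, the reference level)
    or 1 (male).
    """

    observation_ids: Sequence[str]
    ndi: np.ndarray
    age: np.ndarray
    neck_length: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.observation_ids = [str(i) for i in self.observation_ids]
        n = len(self.observation_ids)
        if n < 1:
            raise ValueError("a covariate table needs at least one observation")
        dupes = sorted({i for i in self.observation_ids if self.observation_ids.count(i) > 1})
        if dupes:
            raise ValueError(f"observation ids must be unique; duplicates: {dupes}")
        for name in ("ndi", "age", "neck_length", "sex"):
            col = np.asarray(getattr(self, name), dtype=float)
            if col.shape != (n,):
                raise ValueError(f"column {name!r} must have length {n}")
            if not np.all(np.isfinite(col)):
                raise ValueError(f"missing value in column {name!r}")
            setattr(self, name, col)
        if np.any((self.ndi < 0) | (self.ndi > 50)):
            bad = self.observation_ids[int(np.argmax((self.ndi < 0) | (self.ndi > 50)))]
            raise ValueError(
                f"NDI is scored on a 0-50 scale; observation {bad!r} has ndi={self.ndi[self.observation_ids.index(bad)]}"
            )
        if not np.all(np.isin(self.sex, (0.0, 1.0))):
            raise ValueError("sex must be coded 0 (female) or 1 (male)")

    @property
    def n(self) -> int:
        return len(self.observation_ids)

    def column(self, name: str) -> np.ndarray:
        if name not in ("ndi", "age", "neck_length", "sex"):
            raise KeyError(f"unknown covariate {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.observation_ids,
                "ndi": self.ndi,
                "age": self.age,
                "neck_length": self.neck_length,
                "sex": self.sex.astype(int),
            }
        )


@dataclass
class ResultTable:
    """Long-format inference results.

    One row per (response, coefficient, time, method) with method one of
    ``ols`` / ``moderated``; columns beta, se, t, p_raw, p_bh, p_by.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in RESULT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"result table missing columns {missing}")
        if len(df) == 0:
            raise ValueError("result table is empty")
        self.frame = df.loc[:, list(RESULT_COLUMNS)].reset_index(drop=True)
        df = self.frame
        for col in ("p_raw", "p_bh", "p_by"):
            v = df[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{col} values must lie in [0, 1]")
        if np.any(df["p_bh"].to_numpy() < df["p_raw"].to_numpy() - 1e-15):
            raise ValueError("p_bh must be >= p_raw row-wise")
        if np.any(df["p_by"].to_numpy() < df["p_bh"].to_numpy() - 1e-15):
            raise ValueError("p_by must be >= p_bh row-wise")
        # the moderation never touches the coefficients themselves
        pivot = df.pivot_table(
            index=["response", "coefficient", "time"], columns="method", values="beta"
        )
        if {"ols", "moderated"}.issubset(pivot.columns):
            both = pivot.dropna()
            if not np.array_equal(both["ols"].to_numpy(), both["moderated"].to_numpy()):
                raise ValueError("beta must be identical across methods at each (coefficient, time)")


def read_curve_matrix(path: str | Path, response_label: str) -> CurveSet:
    """Read a wide-format curve CSV into a :class:`CurveSet`.

    The header must be ``id, t_0001, ..., t_K``; the grid is the default
    equally spaced K-point grid on [0, 1].  Missing cells and ragged rows
    are hard errors naming the offending location.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={0: str}, on_bad_lines="error", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged row in {path}: {exc}") from exc
    if df.shape[1] < 3 or df.columns[0] != "id":
        raise ValueError(f"{path}: expected header 'id,t_0001,...'")
    time_cols = list(df.columns[1:])
    body = df[time_cols].apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        i = int(np.argmax(body.isna().any(axis=1).to_numpy()))
        j = body.columns[int(np.argmax(body.iloc[i].isna().to_numpy()))]
        raise ValueError(
            f"{path}: missing or non-numeric value for id {df['id'].iloc[i]!r}, column {j!r}"
        )
    values = body.to_numpy(dtype=float)
    grid = TimeGrid.uniform(values.shape[1])
    return CurveSet(grid, values, response_label, list(df["id"]))


def write_curve_matrix(cs: CurveSet, path: str | Path) -> None:
    """Write a :class:`CurveSet` as wide-format CSV (full double precision)."""
    width = max(4, len(str(cs.grid.k)))
    cols = [f"t_{i + 1:0{width}d}" for i in range(cs.grid.k)]
    df = pd.DataFrame(cs.values, columns=cols)
    df.insert(0, "id", cs.observation_ids)
    df.to_csv(path, index=False)


_SEX_TOKENS = {"0": 0, "1": 1, "f": 0, "m": 1, "female": 0, "male": 1}


def read_covariate_table(path: str | Path) -> CovariateTable:
    """Read and validate a covariate CSV (columns id, ndi, age, neck_length, sex).

    ``sex`` may be coded {0, 1} or {F, M}; M maps to 1 (female is the
    reference level).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = ["id", "ndi", "age", "neck_length", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sex = []
    for raw in df["sex"]:
        token = str(raw).strip().lower()
        if token not in _SEX_TOKENS:
            raise ValueError(f"{path}: unknown sex token {raw!r} (expected 0/1 or F/M)")
        sex.append(_SEX_TOKENS[token])
    return CovariateTable(
        observation_ids=list(df["id"]),
        ndi=df["ndi"].to_numpy().astype(float),
        age=df["age"].to_numpy().astype(float),
        neck_length=df["neck_length"].to_numpy().astype(float),
        sex=np.asarray(sex, dtype=float),
    )


def write_covariate_table(cov: CovariateTable, path: str | Path) -> None:
    cov.to_frame().to_csv(path, index=False)


def write_result_table(results: ResultTable, path: str | Path) -> None:
    """Write a :class:`ResultTable` as long-format CSV with a fixed column order."""
    results.frame.to_csv(path, index=False, columns=list(RESULT_COLUMNS))


def read_result_table(path: str | Path) -> ResultTable:
    df = pd.read_csv(
        path,
        dtype={"response": str, "coefficient": str, "method": str},
        float_precision="round_trip",
    )
    return ResultTable(df)
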