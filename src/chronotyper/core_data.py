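"""Shared data model: abundance and environment tables, temporal-grid
alignment, normalizations and dissimilarity primitives.

The central container is :class:`AbundanceMatrix`, a dense vOTU x time grid of
RPKM values (reads per kilobase per million mapped reads).  Field surveys are
rarely perfectly monthly, so series are first snapped to the nearest monthly
grid point and gaps are filled by linear interpolation
(:func:`align_to_grid`); every downstream periodicity test assumes an
equidistant grid with no missing cells.  Environmental parameters are min-max
scaled to [0, 1] so that Euclidean distances between months weight each
parameter equally.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis

__all__ = [
    "AbundanceMatrix",
    "EnvMatrix",
    "SeriesVector",
    "read_abundance_table",
    "write_abundance_table",
    "read_env_table",
    "write_env_table",
    "align_to_grid",
    "zscore",
    "zscore_matrix",
    "minmax_scale",
    "bray_curtis",
    "euclidean_consecutive",
    "date_to_month_position",
]

_FLOAT_FMT = "%.17g"  # shortest-exact is not available via float_format; 17 significant digits round-trips binary64 exactly


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """vOTU x timepoint abundance grid (RPKM).

    ``month_index`` holds integer month offsets from the first timepoint once
    aligned; before alignment it holds the snapped month position of each
    original sample date.  ``interpolated_mask`` marks grid cells that were
    filled by interpolation rather than observed.
    """

    votu_ids: list[str]
    dates: list[str]
    month_index: np.ndarray
    values: np.ndarray
    interpolated_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.month_index = np.asarray(self.month_index, dtype=int)
        if self.values.shape != (len(self.votu_ids), len(self.dates)):
            raise ValueError("values shape does not match ids/dates")
        if np.any(self.values < 0):
            raise ValueError("negative abundance")
        if len(set(self.votu_ids)) != len(self.votu_ids):
            raise ValueError("duplicate vOTU")
        if self.interpolated_mask is not None:
            self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
            if self.interpolated_mask.shape != self.values.shape:
                raise ValueError("interpolated_mask shape mismatch")

    @property
    def n_votus(self) -> int:
        return len(self.votu_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.dates)

    @property
    def is_aligned(self) -> bool:
        d = np.diff(self.month_index)
        return self.interpolated_mask is not None and d.size > 0 and np.all(d == d[0])

    def original_timepoints(self) -> np.ndarray:
        """Boolean mask of timepoints that were observed (no column fully
        interpolated)."""
        if self.interpolated_mask is None:
            return np.ones(self.n_timepoints, dtype=bool)
        return ~self.interpolated_mask.all(axis=0)

    def row(self, votu_id: str) -> np.ndarray:
        return self.values[self.votu_ids.index(votu_id)]

    def subset(self, votu_ids: list[str]) -> "AbundanceMatrix":
        idx = [self.votu_ids.index(v) for v in votu_ids]
        mask = None if self.interpolated_mask is None else self.interpolated_mask[idx]
        return AbundanceMatrix(list(votu_ids), list(self.dates),
                               self.month_index.copy(), self.values[idx], mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.votu_ids, name="votu_id"),
                            columns=self.dates)


@dataclass
class EnvMatrix:
    """Environmental parameter x timepoint table.

    ``raw`` holds the measured values; ``scaled`` is filled by
    :func:`minmax_scale` with each parameter mapped onto [0, 1].
    """

    parameters: list[str]
    dates: list[str]
    month_index: np.ndarray
    raw: np.ndarray
    scaled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.month_index = np.asarray(self.month_index, dtype=int)
        if self.raw.shape != (len(self.parameters), len(self.dates)):
            raise ValueError("raw shape does not match parameters/dates")

    @property
    def n_timepoints(self) -> int:
        return len(self.dates)

    def to_frame(self, scaled: bool = False) -> pd.DataFrame:
        vals = self.scaled if scaled else self.raw
        return pd.DataFrame(vals, index=pd.Index(self.parameters, name="parameter"),
                            columns=self.dates)


@dataclass
class SeriesVector:
    """A single ordered series with its normalization tag."""

    values: np.ndarray
    normalization: str = "raw"  # {"raw", "zscore"}
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _parse_iso(date: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(date))
    except ValueError as exc:
        raise ValueError(f"malformed date header {date!r}: expected YYYY-MM-DD") from exc


def date_to_month_position(date: str) -> float:
    """Fractional month position of a calendar date (continuous month axis).

    Integer positions fall on the first day of each month; the day of month
    contributes its fraction of that month's length.
    """
    d = _parse_iso(date)
    ndays = calendar.monthrange(d.year, d.month)[1]
    return d.year * 12 + (d.month - 1) + (d.day - 1) / ndays


def read_abundance_table(path) -> AbundanceMatrix:
    """Read a tab-delimited abundance table (rows vOTUs, columns ISO dates)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    dates = [str(c) for c in df.columns]
    for d in dates:
        _parse_iso(d)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate vOTU id {dup!r}")
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("non-numeric or missing abundance cell")
    if np.any(values < 0):
        raise ValueError("negative abundance")
    positions = np.array([date_to_month_position(d) for d in dates])
    order = np.argsort(positions, kind="stable")
    month_index = snap_to_months(positions[order])
    return AbundanceMatrix([str(i) for i in df.index], [dates[i] for i in order],
                           month_index, values[:, order])


def write_abundance_table(matrix: AbundanceMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_env_table(path) -> EnvMatrix:
    """Read a tab-delimited environment table (rows ISO dates, columns
    parameters); stored transposed as parameter x timepoint."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    dates = [str(i) for i in df.index]
    positions = np.array([date_to_month_position(d) for d in dates])
    order = np.argsort(positions, kind="stable")
    month_index = snap_to_months(positions[order])
    return EnvMatrix([str(c) for c in df.columns], [dates[i] for i in order],
                     month_index, df.to_numpy(dtype=float).T[:, order])


def write_env_table(env: EnvMatrix, path, scaled: bool = False) -> None:
    env.to_frame(scaled=scaled).T.rename_axis("date").to_csv(
        path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# grid alignment
# ---------------------------------------------------------------------------

def snap_to_months(positions: np.ndarray) -> np.ndarray:
    """Snap fractional month positions to nearest month midpoint, ties toward
    the earlier month, re-based to start at 0."""
    # midpoint of month m sits at m + 0.5 on the continuous axis; half-down
    # rounding implements nearest-midpoint with ties toward the earlier month
    x = np.asarray(positions, dtype=float)
    snapped = np.floor(x + 0.5 - 1e-9).astype(int)
    return snapped - snapped.min() if snapped.size else snapped


def align_to_grid(matrix: AbundanceMatrix, step_months: int = 1) -> AbundanceMatrix:
    """Assign samples to the nearest monthly grid point and fill empty months
    by per-vOTU linear interpolation.

    Raises on a grid collision (two samples snapping to one month) and never
    extrapolates: the grid runs from the first to the last observed month.
    Idempotent on already-aligned input.
    """
    if matrix.n_timepoints < 3:
        raise ValueError("need >= 3 samples to align")
    positions = np.array([date_to_month_position(d) for d in matrix.dates])
    snapped = snap_to_months(positions / step_months)
    if len(np.unique(snapped)) != len(snapped):
        vals, counts = np.unique(snapped, return_counts=True)
        clash = vals[counts > 1][0]
        dates = [d for d, s in zip(matrix.dates, snapped) if s == clash]
        raise ValueError(f"grid collision: samples {dates} map to the same month")
    span = snapped.max() - snapped.min()
    if span < 2:
        raise ValueError("samples must span >= 2 grid steps")
    grid = np.arange(span + 1)
    observed = np.isin(grid, snapped)
    values = np.empty((matrix.n_votus, len(grid)))
    values[:, snapped] = matrix.values
    for i in range(matrix.n_votus):
        values[i, ~observed] = np.interp(grid[~observed], snapped, matrix.values[i])
    mask = np.zeros_like(values, dtype=bool)
    mask[:, ~observed] = True
    if matrix.interpolated_mask is not None:
        mask[:, observed] |= matrix.interpolated_mask
    date_by_month = dict(zip(snapped, matrix.dates))
    first = _parse_iso(matrix.dates[0])
    base = first.year * 12 + first.month - 1
    grid_dates = []
    for g in grid:
        if g in date_by_month:
            grid_dates.append(date_by_month[g])
        else:
            y, m = divmod(base + int(g) * step_months, 12)
            grid_dates.append(f"{y:04d}-{m + 1:02d}-15")
    return AbundanceMatrix(list(matrix.votu_ids), grid_dates, grid, values, mask)


# ---------------------------------------------------------------------------
# normalizations & dissimilarities
# ---------------------------------------------------------------------------

def zscore(series) -> SeriesVector:
    """Z-score a series (sample sd).  A constant series becomes all-zero and
    is flagged degenerate.  Idempotent."""
    x = series.values if isinstance(series, SeriesVector) else np.asarray(series, float)
    if x.size < 2:
        raise ValueError("zscore requires length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        return SeriesVector(np.zeros_like(x), "zscore", degenerate=True)
    return SeriesVector((x - x.mean()) / sd, "zscore")


def zscore_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-score; returns (matrix, degenerate row mask)."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd[:, 0] == 0)
    sd[degenerate] = 1.0
    out = (values - mu) / sd
    out[degenerate] = 0.0
    return out, degenerate


def minmax_scale(env: EnvMatrix) -> EnvMatrix:
    """Scale each parameter onto [0, 1] by its min and max:
    X' = (x - min(x)) / (max(x) - min(x))."""
    lo = env.raw.min(axis=1, keepdims=True)
    hi = env.raw.max(axis=1, keepdims=True)
    if np.any(hi == lo):
        bad = [p for p, l, h in zip(env.parameters, lo[:, 0], hi[:, 0]) if l == h]
        raise ValueError(f"constant parameter column(s): {bad}")
    return replace(env, scaled=(env.raw - lo) / (hi - lo))


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) between two nonnegative
    abundance vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundances must be nonnegative")
    if not (a.any() or b.any()):
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(a, b))


def euclidean_consecutive(env: EnvMatrix) -> np.ndarray:
    """Euclidean distance between consecutive months of the scaled table."""
    if env.scaled is None:
        raise ValueError("environment table must be min-max scaled first")
    if env.n_timepoints < 2:
        raise ValueError("need >= 2 timepoints")
    return np.linalg.norm(np.diff(env.scaled, axis=1), axis=0)
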