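"""Seasonality screening and community time-decay analysis.

Each vOTU abundance series is tested for a hidden periodicity with the exact
Fisher G-test: the statistic is the largest periodogram ordinate divided by
the periodogram total, and its null distribution under Gaussian white noise
has the closed-form tail

    P(G > g) = sum_{j=1}^{floor(1/g)} (-1)^(j-1) C(m, j) (1 - j g)^(m-1)

with m periodogram ordinates.  Community-level annual recurrence is assessed
by a Bray-Curtis time-decay curve (mean dissimilarity per month gap between
observed samples) and a first-harmonic sinusoidal regression on that curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_data import AbundanceMatrix, SeriesVector, bray_curtis

__all__ = [
    "SeasonalityResult",
    "TimeDecayCurve",
    "periodogram",
    "fisher_g_pvalue",
    "fisher_g_test",
    "classify_collection",
    "quartile_fractions",
    "time_decay",
    "harmonic_regression",
]


@dataclass
class SeasonalityResult:
    votu_id: str
    g_statistic: float
    p_value: float
    dominant_period_months: float
    label: str  # {"seasonal", "non-seasonal"}


@dataclass
class TimeDecayCurve:
    lags: np.ndarray
    mean_dissimilarity: np.ndarray
    n_pairs: np.ndarray
    harmonic_fit: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_months": self.lags,
                             "mean_bray_curtis": self.mean_dissimilarity,
                             "n_pairs": self.n_pairs})


# ---------------------------------------------------------------------------
# Fisher G-test
# ---------------------------------------------------------------------------

def periodogram(series) -> np.ndarray:
    """Periodogram ordinates I(w_k) = |sum_t x_t e^{-i 2 pi k t / T}|^2 / T
    for k = 1..floor((T-1)/2), after mean-centering.

    Raises on a constant series (all ordinates zero).
    """
    x = series.values if isinstance(series, SeriesVector) else np.asarray(series, float)
    T = x.size
    if T < 6:
        raise ValueError("periodogram requires series length >= 6")
    x = x - x.mean()
    m = (T - 1) // 2
    spec = np.fft.rfft(x)[1:m + 1]
    ordinates = (spec.real ** 2 + spec.imag ** 2) / T
    if not np.any(ordinates > 0):
        raise ValueError("constant series: all periodogram ordinates are zero")
    return ordinates


def periodogram_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise periodogram of a series matrix (constant rows give all-zero
    ordinate rows rather than raising)."""
    x = np.asarray(values, dtype=float)
    T = x.shape[1]
    m = (T - 1) // 2
    x = x - x.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(x, axis=1)[:, 1:m + 1]
    return (spec.real ** 2 + spec.imag ** 2) / T


def fisher_g_pvalue(g: float, m: int) -> float:
    """Exact upper-tail probability of the Fisher G statistic with m
    ordinates."""
    if not (0 < g <= 1):
        raise ValueError("g must lie in (0, 1]")
    jmax = min(m, int(math.floor(1.0 / g + 1e-12)))
    p = 0.0
    for j in range(1, jmax + 1):
        term = math.comb(m, j) * (1.0 - j * g) ** (m - 1)
        p += term if j % 2 == 1 else -term
    return float(min(1.0, max(0.0, p)))


def fisher_g_test(series, alpha: float = 0.05, votu_id: str = "",
                  mode: str = "global", period: float = 12.0) -> SeasonalityResult:
    """Fisher G-test of a single series.

    mode "global" uses the periodogram maximum over all frequencies (the
    classical test); mode "annual" restricts the numerator to the ordinate
    whose period is nearest ``period`` months and uses the Beta(1, m-1) tail
    P = (1 - g)^(m-1) exact for a pre-specified frequency.

    A constant series is labelled non-seasonal with p = 1 (warning), matching
    the absence of any periodic signal.
    """
    x = series.values if isinstance(series, SeriesVector) else np.asarray(series, float)
    T = x.size
    try:
        I = periodogram(x)
    except ValueError as exc:
        if "constant" not in str(exc):
            raise
        warnings.warn(f"constant series {votu_id!r}: labelled non-seasonal")
        return SeasonalityResult(votu_id, float("nan"), 1.0, float("nan"), "non-seasonal")
    m = I.size
    total = I.sum()
    if mode == "global":
        k = int(np.argmax(I)) + 1
        g = float(I[k - 1] / total)
        p = fisher_g_pvalue(g, m)
    elif mode == "annual":
        k = int(np.argmin(np.abs(T / np.arange(1, m + 1) - period))) + 1
        g = float(I[k - 1] / total)
        p = float((1.0 - g) ** (m - 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    label = "seasonal" if p < alpha else "non-seasonal"
    return SeasonalityResult(votu_id, g, p, T / k, label)


def classify_collection(matrix: AbundanceMatrix, alpha: float = 0.05,
                        mode: str = "global") -> tuple[list[str], list[str], pd.DataFrame]:
    """Partition every vOTU into seasonal / non-seasonal fractions.

    Returns (seasonal ids, non-seasonal ids, per-vOTU result table).
    """
    rows = []
    for vid, series in zip(matrix.votu_ids, matrix.values):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = fisher_g_test(series, alpha=alpha, votu_id=vid, mode=mode)
        rows.append((r.votu_id, r.g_statistic, r.p_value,
                     r.dominant_period_months, r.label))
    df = pd.DataFrame(rows, columns=["votu_id", "g", "p", "period_months", "label"])
    seasonal = df.loc[df.label == "seasonal", "votu_id"].tolist()
    non_seasonal = df.loc[df.label == "non-seasonal", "votu_id"].tolist()
    return seasonal, non_seasonal, df


def quartile_fractions(matrix: AbundanceMatrix) -> dict[str, list[str]]:
    """Split vOTUs by mean RPKM into bottom quartile, interquartile range and
    top quartile (rank cut, ties broken by (mean, votu_id))."""
    n = matrix.n_votus
    if n < 4:
        raise ValueError("quartile split requires >= 4 vOTUs")
    means = matrix.values.mean(axis=1)
    order = sorted(range(n), key=lambda i: (means[i], matrix.votu_ids[i]))
    nq = n // 4
    ids = [matrix.votu_ids[i] for i in order]
    return {"bottom": ids[:nq], "middle": ids[nq:n - nq], "top": ids[n - nq:]}


# ---------------------------------------------------------------------------
# time decay
# ---------------------------------------------------------------------------

def time_decay(matrix: AbundanceMatrix, votu_subset: list[str] | None = None) -> TimeDecayCurve:
    """Mean Bray-Curtis dissimilarity per month gap over all pairs of
    observed (non-interpolated) samples."""
    sub = matrix if votu_subset is None else matrix.subset(votu_subset)
    keep = sub.original_timepoints()
    months = sub.month_index[keep]
    cols = sub.values[:, keep]
    if months.size < 2:
        raise ValueError("need >= 2 observed samples")
    acc: dict[int, list[float]] = {}
    for i in range(months.size):
        for j in range(i + 1, months.size):
            lag = int(months[j] - months[i])
            acc.setdefault(lag, []).append(bray_curtis(cols[:, i], cols[:, j]))
    lags = np.array(sorted(acc))
    return TimeDecayCurve(lags,
                          np.array([float(np.mean(acc[l])) for l in lags]),
                          np.array([len(acc[l]) for l in lags]))


def harmonic_regression(curve: TimeDecayCurve, period: float = 12.0) -> dict:
    """First-harmonic sinusoidal OLS of the time-decay curve:
    y ~ 1 + sin(2 pi lag / period) + cos(2 pi lag / period).

    The amplitude significance is the joint F-test of the two harmonic
    coefficients.  The fit is stored on the curve and returned.
    """
    lags = np.asarray(curve.lags, dtype=float)
    if lags.size < 6 or np.unique(lags).size < 4:
        raise ValueError("harmonic regression requires >= 6 distinct lag points")
    X = sm.add_constant(np.column_stack([np.sin(2 * np.pi * lags / period),
                                         np.cos(2 * np.pi * lags / period)]))
    res = sm.OLS(curve.mean_dissimilarity, X).fit()
    ftest = res.f_test(np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]))
    fit = {
        "intercept": float(res.params[0]),
        "sin_coef": float(res.params[1]),
        "cos_coef": float(res.params[2]),
        "amplitude": float(np.hypot(res.params[1], res.params[2])),
        "p_value": float(ftest.pvalue),
        "r_squared": float(res.rsquared),
    }
    curve.harmonic_fit = fit
    return fit
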