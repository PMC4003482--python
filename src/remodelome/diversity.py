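"""Metabolite-diversity statistics and survival utilities.

Metabolite diversity is the number of features detected (intensity > 0)
in a sample — the analysis' proxy for the breadth of the metabolome,
including low-abundance species that cross the detection limit as
damage accumulates.  The module computes per-sample diversity and total
signal, polynomial age trends, the late-life plateau age of the fitted
trend, and basic survivorship quantities (interval deaths, mean
lifespan, log-rank comparison).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank

from .io import FeatureTable, LifespanCurve
from .screen import rm_anova_feature

__all__ = [
    "LifespanCurve",
    "count_detected",
    "total_signal",
    "diversity_series",
    "fit_polynomial_trend",
    "diversity_age_anova",
    "plateau_age",
    "deaths_per_interval",
    "mean_lifespan",
    "log_rank_test",
]


def _per_sample_frame(table: FeatureTable, values: np.ndarray, name: str) -> pd.DataFrame:
    out = table.metadata.copy()
    out[name] = values
    return out.reset_index(names="sample")


def count_detected(table: FeatureTable) -> pd.DataFrame:
    """Per-sample count of strictly positive intensities."""
    counts = (table.intensities.to_numpy() > 0).sum(axis=0)
    return _per_sample_frame(table, counts, "detected_count")


def total_signal(table: FeatureTable) -> pd.DataFrame:
    """Per-sample column sum of intensities."""
    totals = table.intensities.to_numpy().sum(axis=0)
    return _per_sample_frame(table, totals, "total_signal")


def diversity_series(table: FeatureTable) -> pd.DataFrame:
    """Detected count and total signal per sample, one tidy frame."""
    out = count_detected(table)
    out["total_signal"] = table.intensities.to_numpy().sum(axis=0)
    return out


def fit_polynomial_trend(
    x: Sequence[float], y: Sequence[float], degree: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial through all replicate points.

    Returns (coefficients highest-order first, fitted values at x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < degree + 1:
        raise ValueError(f"need at least {degree + 1} distinct x values")
    coeffs = np.polyfit(x, y, degree)
    return coeffs, np.polyval(coeffs, x)


def diversity_age_anova(series: pd.DataFrame, diet: str | None = None) -> tuple[float, float]:
    """Repeated-measures ANOVA of detected count on age.

    Age is the within factor and the replicate index the subject
    followed across ages; the design must be balanced.
    """
    sub = series if diet is None else series[series["diet"] == diet]
    if sub["diet"].nunique() != 1:
        raise ValueError("series spans several diets; pass diet=...")
    pivot = sub.pivot(index="age_days", columns="replicate", values="detected_count")
    if pivot.isna().any().any():
        raise ValueError("unbalanced design: missing (age, replicate) cells")
    return rm_anova_feature(pivot.to_numpy(dtype=float))


def plateau_age(
    cubic_coeffs: Sequence[float], age_range: tuple[float, float]
) -> float | None:
    """Age where the fitted cubic levels off, if it does.

    Returns the smallest root of the fitted derivative inside the
    observed range at which curvature is negative (a maximum of the
    trend), or None when the fit has no such stationary point.
    """
    coeffs = np.asarray(cubic_coeffs, dtype=float)
    deriv = np.polyder(coeffs)
    curv = np.polyder(deriv)
    lo, hi = age_range
    candidates = []
    for r in np.roots(deriv):
        if abs(r.imag) < 1e-9 and lo - 1e-9 <= r.real <= hi + 1e-9:
            if np.polyval(curv, r.real) < 0:
                candidates.append(float(r.real))
    return min(candidates) if candidates else None


def deaths_per_interval(curve: LifespanCurve) -> np.ndarray:
    """Death counts per inter-observation interval.

    Counts are cohort_size times the survivorship decrement, so they
    are non-negative and sum to cohort_size * (1 - final fraction).
    """
    if curve.cohort_size is None:
        raise ValueError("curve has no cohort_size")
    dec = -np.diff(curve.fraction_alive)
    if (dec < -1e-12).any():
        raise ValueError("fraction_alive increases; invalid curve")
    return curve.cohort_size * np.clip(dec, 0.0, None)


def mean_lifespan(death_times: Sequence[float]) -> float:
    deaths = np.asarray(death_times, dtype=float)
    if deaths.size == 0:
        raise ValueError("empty cohort")
    return float(deaths.mean())


def log_rank_test(
    deaths_a: Sequence[float], deaths_b: Sequence[float]
) -> tuple[float, float]:
    """Standard log-rank chi-square (1 df) between two fully observed
    cohorts (no censoring)."""
    a = np.asarray(deaths_a, dtype=float)
    b = np.asarray(deaths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty cohort")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return 0.0, 1.0
    res = _lifelines_logrank(a, b)
    return float(res.test_statistic), float(res.p_value)
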