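"""Per-feature repeated-measures ANOVA screen for age association.

Each feature detected in every sample of a diet is tested with a
one-way within-subject ANOVA: age is the within factor and the
replicate batch the subject followed across ages.  Features that
register zero in any of the diet's samples belong to the
detection-diversity analysis and are excluded from the screen
(flagged ineligible, not tested).

The significance threshold may be fixed (default p < 0.0014,
corresponding to <0.2% false positives among null features) or
calibrated from the observed p-value distribution by locating the knee
of the estimated error-rate curve — the transition between the linear
and exponential rise of the expected false-positive fraction.  The
accompanying FDR estimate is the pi0=1 plug-in alpha*m / #{p <= alpha}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable

__all__ = [
    "AgeAssocConfig",
    "ThresholdCalibration",
    "OverlapResult",
    "rm_anova_feature",
    "rm_anova_matrix",
    "rm_anova_table",
    "calibrate_threshold",
    "plug_in_fdr",
    "diet_overlap",
]


@dataclass(frozen=True)
class AgeAssocConfig:
    """Screen parameters.

    ``alpha_metabolites`` / ``alpha_transcripts`` are the default
    significance thresholds for the two feature kinds; the transcript
    path is the identical code with its own threshold.
    """

    alpha_metabolites: float = 0.0014
    alpha_transcripts: float = 0.0013
    auto_calibrate: bool = False
    fdr_report: bool = True
    alpha_cap: float = 0.05
    n_grid: int = 100

    def __post_init__(self) -> None:
        for a in (self.alpha_metabolites, self.alpha_transcripts, self.alpha_cap):
            if not 0.0 < a < 1.0:
                raise ValueError("significance thresholds must lie in (0, 1)")

    def alpha(self, kind: str = "metabolite") -> float:
        return self.alpha_metabolites if kind == "metabolite" else self.alpha_transcripts


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def rm_anova_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way RM-ANOVA over a stack of age x subject matrices.

    ``values`` has shape (n_features, n_ages, n_subjects); the design
    must be balanced and finite.  Returns (F, p) arrays.  Degenerate
    cases: zero age variation gives F=0, p=1; a perfectly additive
    matrix (zero residual but nonzero age effect) gives an infinite-F
    sentinel with p=0.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim == 2:
        vals = vals[None]
    if vals.ndim != 3:
        raise ValueError("expected (n_features, n_ages, n_subjects)")
    n, a, s = vals.shape
    if a < 2 or s < 2:
        raise ValueError("need at least 2 ages and 2 subjects")
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values in ANOVA input")

    grand = vals.mean(axis=(1, 2), keepdims=True)
    age_means = vals.mean(axis=2, keepdims=True)
    subj_means = vals.mean(axis=1, keepdims=True)
    ss_total = ((vals - grand) ** 2).sum(axis=(1, 2))
    ss_age = (s * (age_means - grand) ** 2).sum(axis=(1, 2))
    ss_subj = (a * (subj_means - grand) ** 2).sum(axis=(1, 2))
    ss_res = np.clip(ss_total - ss_age - ss_subj, 0.0, None)

    df_age, df_res = a - 1, (a - 1) * (s - 1)
    scale = np.maximum(ss_total, 1.0)  # relative tolerance for exact-zero detection
    age_zero = ss_age <= 1e-12 * scale
    res_zero = ss_res <= 1e-12 * scale

    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_age / df_age) / (ss_res / df_res)
    F = np.where(age_zero, 0.0, F)
    F = np.where(~age_zero & res_zero, np.inf, F)
    p = np.where(
        age_zero, 1.0, np.where(res_zero, 0.0, stats.f.sf(np.where(np.isfinite(F), F, 1.0), df_age, df_res))
    )
    p = np.where(~age_zero & res_zero, 0.0, p)
    return F, p


def rm_anova_feature(values: np.ndarray) -> tuple[float, float]:
    """RM-ANOVA of one balanced age x subject matrix; returns (F, p)."""
    F, p = rm_anova_matrix(np.asarray(values, dtype=float)[None])
    return float(F[0]), float(p[0])


def rm_anova_table(
    table: FeatureTable, diet: str, alpha: float = 0.0014
) -> pd.DataFrame:
    """Screen every eligible feature of one diet.

    Eligible features are detected (>0) in all of the diet's samples;
    others are flagged ``eligible=False`` with NaN statistics.  Returns
    a frame indexed by feature id with F, p, eligible, significant.
    """
    arr = table.design_array(diet)
    eligible = (arr > 0).all(axis=(1, 2))
    if not eligible.any():
        raise ValueError(f"no eligible features for diet {diet!r}")
    F = np.full(len(arr), np.nan)
    p = np.full(len(arr), np.nan)
    F[eligible], p[eligible] = rm_anova_matrix(np.log10(arr[eligible]))
    out = pd.DataFrame(
        {
            "eligible": eligible,
            "F": F,
            "p": p,
            "significant": eligible & (p < alpha),
        },
        index=table.feature_ids,
    )
    out.attrs["alpha"] = alpha
    out.attrs["diet"] = diet
    return out


# ---------------------------------------------------------------------------
# threshold calibration and plug-in FDR


@dataclass(frozen=True)
class ThresholdCalibration:
    alpha_star: float
    no_signal: bool
    grid: np.ndarray = field(repr=False)
    fdr_hat: np.ndarray = field(repr=False)


def calibrate_threshold(
    pvalues: np.ndarray, cap: float = 0.05, n_grid: int = 100
) -> ThresholdCalibration:
    """Locate the knee of the estimated error-rate curve.

    On a log-spaced alpha grid from 1/m to ``cap``, the estimated FDR
    is E(alpha)/max(R(alpha), 1) with E = alpha*m expected false
    positives and R the realized discoveries.  The returned threshold
    is the grid point of maximum perpendicular distance to the chord
    joining the curve's endpoints in (log10 alpha, log10 FDRhat) space
    — the transition between the linear and the exponential rise of
    the error rate.  A flat near-unit curve (no signal) returns the cap
    with ``no_signal`` set.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("threshold calibration needs at least 100 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    grid = np.logspace(np.log10(1.0 / m), np.log10(cap), n_grid)
    R = np.searchsorted(np.sort(p), grid, side="right")
    fdr_hat = np.minimum(grid * m / np.maximum(R, 1), 1.0)
    # a pure-null curve sits near 1 everywhere (up to small-R noise at
    # the left edge); the median over the grid is a stable detector
    if np.median(fdr_hat) > 0.5:
        return ThresholdCalibration(cap, True, grid, fdr_hat)
    x = np.log10(grid)
    y = np.log10(np.maximum(fdr_hat, 1.0 / (10.0 * m)))
    chord = np.array([x[-1] - x[0], y[-1] - y[0]])
    chord /= np.hypot(*chord)
    dx, dy = x - x[0], y - y[0]
    dist = np.abs(dx * chord[1] - dy * chord[0])
    return ThresholdCalibration(float(grid[np.argmax(dist)]), False, grid, fdr_hat)


def plug_in_fdr(pvalues: np.ndarray, alpha: float) -> float:
    """pi0=1 plug-in FDR estimate alpha*m / #{p <= alpha}.

    Returns NaN (undefined) when there are no discoveries.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    R = int((p <= alpha).sum())
    if R == 0:
        return float("nan")
    return min(alpha * m / R, 1.0)


# ---------------------------------------------------------------------------
# cross-diet overlap


@dataclass(frozen=True)
class OverlapResult:
    a_only: int
    both: int
    b_only: int
    both_ids: tuple[str, ...]
    labels: pd.Series = field(repr=False)  # per feature: both / A-only / B-only / neither


def diet_overlap(res_a: pd.DataFrame, res_b: pd.DataFrame) -> OverlapResult:
    """Venn counts of significant features across two diets."""
    if not res_a.index.equals(res_b.index):
        raise ValueError("screens cover different feature universes")
    sig_a = res_a["significant"].to_numpy(bool)
    sig_b = res_b["significant"].to_numpy(bool)
    labels = np.where(
        sig_a & sig_b, "both", np.where(sig_a, "A-only", np.where(sig_b, "B-only", "neither"))
    )
    both_ids = tuple(res_a.index[sig_a & sig_b])
    return OverlapResult(
        int((sig_a & ~sig_b).sum()),
        int((sig_a & sig_b).sum()),
        int((~sig_a & sig_b).sum()),
        both_ids,
        pd.Series(labels, index=res_a.index, name="overlap"),
    )
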