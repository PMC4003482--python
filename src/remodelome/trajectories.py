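"""Replicate-averaged age trajectories: scaling, concordance, fold changes.

A trajectory is a feature's replicate-averaged value across the sampled
ages within one diet.  The module z-scores trajectories within or
across diets, measures cross-diet concordance of matched features
(Pearson correlation per feature, with a re-pairing permutation null
for the median), correlates trajectories with the survivorship curve,
and computes orientation-free intra- and inter-diet fold changes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import FeatureTable, LifespanCurve

__all__ = [
    "TrajectoryMatrix",
    "average_replicates",
    "scale",
    "diet_pair_correlations",
    "permutation_concordance",
    "lifespan_correlation",
    "fold_changes",
]

SCALING_MODES = ("none", "within_diet", "across_diets")


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Per-diet (features x ages) replicate-averaged value matrices."""

    ages: np.ndarray
    data: dict[str, pd.DataFrame]
    scaling: str = "none"
    log10: bool = False

    @property
    def diets(self) -> list[str]:
        return list(self.data)

    @property
    def feature_ids(self) -> pd.Index:
        return next(iter(self.data.values())).index

    def subset(self, feature_ids) -> "TrajectoryMatrix":
        return replace(self, data={d: m.loc[feature_ids] for d, m in self.data.items()})

    def concatenated(self) -> pd.DataFrame:
        """Features x (diets * ages), diet blocks in diet order."""
        return pd.concat(
            [self.data[d].add_prefix(f"{d}:") for d in self.diets], axis=1
        )


def average_replicates(
    table: FeatureTable, feature_ids=None, log10: bool = False
) -> TrajectoryMatrix:
    """Arithmetic mean across replicates per (feature, diet, age).

    With ``log10=True`` intensities are log10-transformed first (every
    selected feature must then be detected in all samples).
    """
    ids = table.feature_ids if feature_ids is None else pd.Index(feature_ids)
    data: dict[str, pd.DataFrame] = {}
    for diet in table.diets:
        arr = table.subset(diet).intensities.loc[ids].to_numpy(dtype=float)
        sub = table.metadata[table.metadata["diet"] == diet].sort_values(
            ["age_days", "replicate"]
        )
        n_ages = sub["age_days"].nunique()
        arr = arr.reshape(len(ids), n_ages, -1)
        if log10:
            if (arr <= 0).any():
                raise ValueError("log10 averaging requires strictly positive values")
            arr = np.log10(arr)
        ages = np.sort(sub["age_days"].unique())
        data[diet] = pd.DataFrame(arr.mean(axis=2), index=ids, columns=ages)
    return TrajectoryMatrix(ages, data, "none", log10)


def scale(matrix: TrajectoryMatrix, mode: str) -> TrajectoryMatrix:
    """Z-score trajectories (sample sd, ddof=1).

    ``within_diet``: each feature row scaled separately per diet;
    ``across_diets``: each feature's concatenated two-diet row scaled
    as one.  Constant rows carry no trajectory information and are
    dropped (their ids recorded in ``.attrs['dropped_constant']``).
    """
    if mode not in ("within_diet", "across_diets"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    diets = matrix.diets
    stacked = np.concatenate([matrix.data[d].to_numpy(float) for d in diets], axis=1)
    if mode == "within_diet":
        constant = np.zeros(len(stacked), dtype=bool)
        for d in diets:
            arr = matrix.data[d].to_numpy(float)
            constant |= arr.std(axis=1, ddof=1) == 0
    else:
        constant = stacked.std(axis=1, ddof=1) == 0
    keep = ~constant
    dropped = matrix.feature_ids[constant]

    out: dict[str, pd.DataFrame] = {}
    if mode == "within_diet":
        for d in diets:
            df = matrix.data[d].loc[matrix.feature_ids[keep]]
            arr = df.to_numpy(float)
            z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, ddof=1, keepdims=True)
            out[d] = pd.DataFrame(z, index=df.index, columns=df.columns)
    else:
        arr = stacked[keep]
        z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, ddof=1, keepdims=True)
        n_ages = matrix.data[diets[0]].shape[1]
        for i, d in enumerate(diets):
            df = matrix.data[d].loc[matrix.feature_ids[keep]]
            out[d] = pd.DataFrame(
                z[:, i * n_ages : (i + 1) * n_ages], index=df.index, columns=df.columns
            )
    result = replace(matrix, data=out, scaling=mode)
    for df in result.data.values():
        df.attrs["dropped_constant"] = list(dropped)
    return result


# ---------------------------------------------------------------------------
# concordance


def _row_normalize(arr: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; constant rows become NaN."""
    c = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return c / norms


def diet_pair_correlations(
    matrix: TrajectoryMatrix, feature_ids=None
) -> pd.DataFrame:
    """Pearson r between the two diets' trajectories per matched feature.

    Constant trajectories have undefined r and are flagged
    ``defined=False``.  The frame's attrs carry the median r of the
    defined features.
    """
    if len(matrix.diets) != 2:
        raise ValueError("needs exactly two diets")
    m = matrix if feature_ids is None else matrix.subset(feature_ids)
    if m.data[m.diets[0]].shape[1] < 3:
        raise ValueError("needs at least 3 ages")
    a = _row_normalize(m.data[m.diets[0]].to_numpy(float))
    b = _row_normalize(m.data[m.diets[1]].to_numpy(float))
    r = np.einsum("ij,ij->i", a, b)
    out = pd.DataFrame({"r": r, "defined": np.isfinite(r)}, index=m.feature_ids)
    out.attrs["median_r"] = float(np.nanmedian(r)) if out["defined"].any() else float("nan")
    return out


def permutation_concordance(
    matrix: TrajectoryMatrix,
    n_perm: int = 1999,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> dict:
    """Median matched-pair r against a feature re-pairing null.

    The statistic is the median Pearson r over matched feature pairs.
    The null re-pairs diet-B trajectories by a random permutation of
    feature identity; p = (1 + #{null median >= observed}) / (n_perm + 1).
    ``exhaustive=True`` enumerates all pairings (tiny feature sets
    only) and returns the exact enumeration p-value.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    diets = matrix.diets
    if len(diets) != 2:
        raise ValueError("needs exactly two diets")
    a = _row_normalize(matrix.data[diets[0]].to_numpy(float))
    b = _row_normalize(matrix.data[diets[1]].to_numpy(float))
    n = len(a)
    if n < 2 or (n < 10 and not exhaustive):
        raise ValueError("too few matched features for a re-pairing null")
    rmat = a @ b.T  # r between every A feature and every B feature
    observed = float(np.median(np.diag(rmat)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if exhaustive:
        null = np.array(
            [np.median(rmat[np.arange(n), list(perm)]) for perm in itertools.permutations(range(n))]
        )
        n_perm = len(null)
        p = (1 + int((null >= observed - 1e-12).sum())) / (n_perm + 1)
    else:
        null = np.empty(n_perm)
        rows = np.arange(n)
        for i in range(n_perm):
            null[i] = np.median(rmat[rows, rng.permutation(n)])
        p = (1 + int((null >= observed - 1e-12).sum())) / (n_perm + 1)
    return {
        "observed_median_r": observed,
        "p": float(p),
        "n_perm": int(n_perm),
        "null_medians": null,
        "n_features": n,
    }


def lifespan_correlation(
    matrix: TrajectoryMatrix,
    curves: dict[str, LifespanCurve],
    strong_threshold: float = 0.75,
) -> pd.DataFrame:
    """Pearson r between each trajectory and interpolated survivorship.

    Survivorship is linearly interpolated at the sampled ages; features
    with |r| above the threshold are flagged strong.
    """
    frames = []
    for diet, m in matrix.data.items():
        curve = curves[diet]
        ages = m.columns.to_numpy(float)
        if ages.min() > curve.days.max() or ages.max() < curve.days.min():
            raise ValueError("sampled ages fall outside the survivorship curve")
        surv = curve.interpolate(ages)
        sz = (surv - surv.mean()) / np.linalg.norm(surv - surv.mean())
        tz = _row_normalize(m.to_numpy(float))
        r = tz @ sz
        frames.append(
            pd.DataFrame(
                {
                    "diet": diet,
                    "r": r,
                    "strong": np.abs(r) > strong_threshold,
                    "defined": np.isfinite(r),
                },
                index=m.index,
            )
        )
    return pd.concat(frames)


def fold_changes(matrix: TrajectoryMatrix) -> pd.DataFrame:
    """Orientation-free fold changes from an unscaled trajectory matrix.

    Intra-diet: max/min of the replicate-averaged trajectory per diet.
    Inter-diet: larger lifespan-averaged mean over smaller, with the
    twofold flag on that ratio.  Values must be strictly positive
    (zero-containing features are excluded upstream).
    """
    if matrix.scaling != "none" or matrix.log10:
        raise ValueError("fold changes need unscaled linear intensities")
    diets = matrix.diets
    if len(diets) != 2:
        raise ValueError("needs exactly two diets")
    out = pd.DataFrame(index=matrix.feature_ids)
    means = {}
    for d in diets:
        arr = matrix.data[d].to_numpy(float)
        if (arr <= 0).any():
            raise ValueError("nonpositive trajectory value; exclude censored features")
        out[f"intradiet_{d}"] = arr.max(axis=1) / arr.min(axis=1)
        means[d] = arr.mean(axis=1)
    ratio = means[diets[1]] / means[diets[0]]
    out["interdiet"] = np.maximum(ratio, 1.0 / ratio)
    out["below_twofold"] = out["interdiet"] < 2.0
    return out
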