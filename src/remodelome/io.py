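"""Feature-table and survivorship I/O, validation, and normalization.

The in-memory containers follow the conventions of untargeted LC-MS
feature tables: a dense non-negative matrix of peak intensities
(features x samples) where an intensity of exactly 0 means the feature
was *not detected* in that sample (left-censoring at the instrument's
detection limit), never "missing".  Sample metadata maps each sample
column to a (diet, age_days, replicate) design cell.

Canonical on-disk formats are plain TSV (comma also accepted on read):

* feature matrix -- header row of sample names, first column ``feature_id``;
* sample metadata -- columns ``sample, diet, age_days, replicate``;
* survivorship  -- columns ``diet, day, fraction_alive`` (optional
  ``cohort_size``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleKey",
    "FeatureTable",
    "NormalizationSpec",
    "LifespanCurve",
    "read_feature_table",
    "write_feature_table",
    "normalize_intensities",
    "log_display_transform",
    "read_survivorship",
    "write_survivorship",
]

METADATA_COLUMNS = ("diet", "age_days", "replicate")


class SampleKey(NamedTuple):
    """Design coordinates of one sample column."""

    diet: str
    age_days: float
    replicate_id: int


@dataclass(frozen=True)
class NormalizationSpec:
    """How to normalize a feature table.

    internal_standard_ids
        Feature ids of spiked-in internal standards; every sample is
        divided by the per-sample mean of their intensities.  May be
        empty.  Standards must be detected (>0) in every sample.
    total_signal
        If True, each sample is additionally divided by its
        (post-standard-division) total signal, so columns sum to 1.
    """

    internal_standard_ids: tuple[str, ...] = ()
    total_signal: bool = True


@dataclass(frozen=True)
class LifespanCurve:
    """Survivorship of one cohort: fraction alive per observation day."""

    days: np.ndarray
    fraction_alive: np.ndarray
    cohort_size: int | None = None
    diet: str | None = None

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        frac = np.asarray(self.fraction_alive, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "fraction_alive", frac)
        if days.ndim != 1 or frac.shape != days.shape:
            raise ValueError("days and fraction_alive must be matching 1-D arrays")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(np.diff(frac) > 1e-12):
            raise ValueError("fraction_alive must be non-increasing")
        if frac[0] > 1 + 1e-12 or frac[-1] < -1e-12:
            raise ValueError("fraction_alive must lie in [0, 1]")

    def interpolate(self, at_days: np.ndarray) -> np.ndarray:
        """Linearly interpolated fraction alive at the given days."""
        return np.interp(np.asarray(at_days, dtype=float), self.days, self.fraction_alive)


@dataclass
class FeatureTable:
    """Dense intensity matrix plus per-sample design metadata.

    ``intensities`` is features x samples; ``metadata`` is indexed by
    sample name with columns diet, age_days, replicate.  A cell of
    exactly 0 encodes non-detection; negative or missing cells are
    contract violations.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------
    def validate(self) -> None:
        mat = self.intensities
        meta = self.metadata
        if mat.index.duplicated().any():
            dups = mat.index[mat.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if mat.isna().any().any():
            raise ValueError(
                "missing cells are not allowed; non-detection must be an explicit 0"
            )
        if (mat.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        missing_meta = [c for c in mat.columns if c not in meta.index]
        if missing_meta:
            raise ValueError(f"sample columns without metadata rows: {missing_meta[:5]}")
        for col in METADATA_COLUMNS:
            if col not in meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        meta = meta.loc[list(mat.columns)]
        keys = list(zip(meta["diet"], meta["age_days"], meta["replicate"]))
        if len(set(keys)) != len(keys):
            raise ValueError("(diet, age_days, replicate) keys must be unique")
        if (meta["age_days"] <= 0).any():
            raise ValueError("age_days must be positive")
        ages_by_diet = {
            diet: frozenset(sub["age_days"]) for diet, sub in meta.groupby("diet")
        }
        if len(set(ages_by_diet.values())) > 1:
            raise ValueError("every diet must share the same set of age_days values")
        self.metadata = meta

    # -- accessors --------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def diets(self) -> list[str]:
        return sorted(self.metadata["diet"].unique())

    @property
    def ages(self) -> np.ndarray:
        return np.sort(self.metadata["age_days"].unique())

    def sample_keys(self) -> list[SampleKey]:
        return [
            SampleKey(str(r["diet"]), float(r["age_days"]), int(r["replicate"]))
            for _, r in self.metadata.iterrows()
        ]

    def columns_for(self, diet: str) -> list[str]:
        """Sample names of one diet ordered by (age, replicate)."""
        sub = self.metadata[self.metadata["diet"] == diet]
        sub = sub.sort_values(["age_days", "replicate"])
        if sub.empty:
            raise KeyError(f"no samples for diet {diet!r}")
        return list(sub.index)

    def subset(self, diet: str) -> "FeatureTable":
        cols = self.columns_for(diet)
        return FeatureTable(
            self.intensities[cols].copy(), self.metadata.loc[cols].copy(), self.normalized
        )

    def design_array(self, diet: str) -> np.ndarray:
        """Intensities of one diet as (n_features, n_ages, n_replicates).

        Requires a balanced design (same replicate count at every age).
        """
        sub = self.metadata[self.metadata["diet"] == diet]
        counts = sub.groupby("age_days")["replicate"].count()
        if counts.nunique() != 1:
            raise ValueError(f"unbalanced design for diet {diet!r}: {dict(counts)}")
        cols = self.columns_for(diet)
        n_ages, n_reps = len(counts), int(counts.iloc[0])
        arr = self.intensities[cols].to_numpy(dtype=float)
        return arr.reshape(len(self.intensities), n_ages, n_reps)


# ---------------------------------------------------------------------------
# reading / writing


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read TSV (canonical) or CSV (accepted) with the first column as index."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_feature_table(path: str | Path, metadata_path: str | Path) -> FeatureTable:
    """Read and validate a feature matrix plus its sample metadata.

    Raises ``ValueError`` on duplicate feature ids, sample columns with
    no metadata row, negative values, or missing cells.
    """
    mat = _read_delimited(path)
    mat.index = mat.index.astype(str)
    meta = _read_delimited(metadata_path)
    meta.index = meta.index.astype(str)
    meta = meta.rename(columns={"replicate_id": "replicate"})
    return FeatureTable(mat, meta)


def write_feature_table(
    table: FeatureTable, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    mat = table.intensities.copy()
    mat.index.name = "feature_id"
    mat.to_csv(path, sep="\t", float_format="%.10g")
    if metadata_path is not None:
        meta = table.metadata.copy()
        meta.index.name = "sample"
        meta.to_csv(metadata_path, sep="\t")


def read_survivorship(path: str | Path) -> dict[str, LifespanCurve]:
    df = pd.read_csv(path, sep=None, engine="python")
    curves: dict[str, LifespanCurve] = {}
    for diet, sub in df.groupby("diet"):
        sub = sub.sort_values("day")
        size = None
        if "cohort_size" in sub.columns and sub["cohort_size"].notna().any():
            size = int(sub["cohort_size"].iloc[0])
        curves[str(diet)] = LifespanCurve(
            sub["day"].to_numpy(float), sub["fraction_alive"].to_numpy(float), size, str(diet)
        )
    return curves


def write_survivorship(curves: Mapping[str, LifespanCurve], path: str | Path) -> None:
    rows = []
    for diet, c in curves.items():
        for d, f in zip(c.days, c.fraction_alive):
            rows.append(
                {"diet": diet, "day": d, "fraction_alive": f, "cohort_size": c.cohort_size}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization


def normalize_intensities(table: FeatureTable, spec: NormalizationSpec) -> FeatureTable:
    """Normalize per sample to internal standards, then to total signal.

    Standards first: every intensity in a sample is divided by the mean
    intensity of that sample's internal standards (which must all be
    detected).  Then, if ``spec.total_signal``, each sample is divided
    by its remaining column total so the column sums to 1.  Zeros stay
    exactly zero throughout; detection status is never altered.
    """
    mat = table.intensities.copy().astype(float)
    ids = list(spec.internal_standard_ids)
    unknown = [i for i in ids if i not in mat.index]
    if unknown:
        raise ValueError(f"internal standards not in table: {unknown}")
    if ids:
        std = mat.loc[ids]
        bad = std.columns[(std.to_numpy() <= 0).any(axis=0)]
        if len(bad):
            raise ValueError(
                f"internal standard non-detected in samples: {list(bad)[:5]}"
            )
        mat = mat / std.mean(axis=0)
    if spec.total_signal:
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot total-signal normalize an all-zero sample")
        mat = mat / totals
    return FeatureTable(mat, table.metadata.copy(), normalized=True)


def log_display_transform(
    table: FeatureTable, pseudo: float = 1e-5
) -> pd.DataFrame:
    """Log10 matrix for visualization, zeros replaced by ``pseudo``.

    Display-only: the substitution re-introduces censored values on an
    arbitrary floor, so the result must never feed statistics.
    """
    if pseudo <= 0:
        raise ValueError("pseudo count must be positive")
    mat = table.intensities.copy().astype(float)
    arr = mat.to_numpy()
    arr = np.where(arr == 0, pseudo, arr)
    return pd.DataFrame(np.log10(arr), index=mat.index, columns=mat.columns)
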