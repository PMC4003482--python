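"""Synthetic study generator with planted, recoverable structure.

Emulates a two-diet *Drosophila* aging metabolomics design: per diet,
7 age groups x 3 replicates of an untargeted LC-MS feature table, plus
cohort survivorship.  Every generated feature carries ground-truth
labels (trajectory class, diet-dependence class, onset age, planted
inter-diet fold change) so each downstream stage of the analysis can be
tested as a recovery problem instead of against downloaded data.

The planted structure mirrors the study conditions the analysis
assumes:

* a fixed fraction of features follows age trajectories (monotone up,
  early monotone down, or rare mid-life reversals) that rise or fall
  linearly in log10 intensity until a plateau age, then stay level;
* the long-lived diet's trajectory is the short-lived diet's template
  evaluated at ``t * delay_factor`` (a time warp: remodeling is delayed
  in proportion to the lifespan ratio);
* "damage onset" features sit below the detection limit early in life
  and cross it at a feature-specific onset age, so the number of
  *detected* features rises with age and levels off near the plateau
  (declining slightly afterwards);
* diet-dependence is planted as log10 level offsets on the long-lived
  diet: none (independent), at every age (progressive), or at a single
  age (intermittent);
* total signal decays slowly with age through a biomass factor;
* lifespans are Gompertz with the hazard level calibrated so the mean
  lifespan matches each diet's target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .io import FeatureTable, LifespanCurve

__all__ = [
    "TRAJECTORY_CLASSES",
    "DIET_DEPENDENCE_CLASSES",
    "GompertzParams",
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "calibrate_gompertz",
    "simulate_lifespan",
    "trajectory_template",
    "generate_study",
]

TRAJECTORY_CLASSES = (
    "flat",
    "monotone_up",
    "monotone_down_early",
    "midlife_reversal",
    "damage_onset",
)
DIET_DEPENDENCE_CLASSES = ("independent", "progressive", "intermittent")


# ---------------------------------------------------------------------------
# Gompertz survivorship


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard h(t) = a * exp(b t); survivorship
    S(t) = exp(-(a/b) (e^{bt} - 1))."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Gompertz parameters a, b must be positive")

    def survival(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(-(self.a / self.b) * np.expm1(self.b * t))

    def mean_lifespan(self) -> float:
        """Mean survival time by numerical quadrature of S(t)."""
        upper = self.inverse_survival(1e-12)
        val, _ = integrate.quad(lambda t: float(self.survival(t)), 0.0, upper, limit=200)
        return val

    def inverse_survival(self, s: float) -> float:
        """Time at which survivorship reaches s (0 < s <= 1)."""
        return math.log1p(-(self.b / self.a) * math.log(s)) / self.b

    def sample_death_times(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling of i.i.d. death times."""
        u = rng.uniform(size=n)
        return np.log1p(-(self.b / self.a) * np.log(u)) / self.b


def calibrate_gompertz(target_mean_days: float, b_fixed: float = 0.1) -> GompertzParams:
    """Find the hazard level ``a`` whose Gompertz mean lifespan (at fixed
    ``b``) equals the target, to within 0.05 d.

    The mean is monotone decreasing in ``a``, so a 1-D root bracket
    suffices.
    """
    if target_mean_days <= 0:
        raise ValueError("target mean lifespan must be positive")

    def f(log_a: float) -> float:
        return GompertzParams(math.exp(log_a), b_fixed).mean_lifespan() - target_mean_days

    lo, hi = math.log(1e-10), math.log(50.0)
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError("no root in search bracket for the requested mean lifespan")
    log_a = optimize.brentq(f, lo, hi, xtol=1e-12)
    params = GompertzParams(math.exp(log_a), b_fixed)
    if abs(params.mean_lifespan() - target_mean_days) > 0.05:
        raise RuntimeError("Gompertz calibration did not converge to 0.05 d")
    return params


def simulate_lifespan(
    params: GompertzParams, n_flies: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, LifespanCurve]:
    """Simulate a cohort and return (death times, empirical curve).

    The curve records the fraction alive at each whole day from 0 to
    the last death.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    deaths = params.sample_death_times(n_flies, rng)
    days = np.arange(0.0, math.ceil(deaths.max()) + 1)
    frac = (deaths[None, :] > days[:, None]).mean(axis=1)
    return deaths, LifespanCurve(days, frac, cohort_size=n_flies)


# ---------------------------------------------------------------------------
# trajectory templates


def trajectory_template(
    trajectory_class: str,
    ages: Sequence[float],
    plateau_age: float,
    delay_factor: float = 1.0,
    amplitude: float = 1.0,
    *,
    onset_age: float | None = None,
    onset_slope: float = 0.08,
    onset_cap: float = np.inf,
    late_decline: float = 0.0,
    start_age: float = 3.0,
) -> np.ndarray:
    """Mean log10-intensity deviation over the sampled ages.

    The template is expressed in effective time ``t' = t * delay_factor``:
    the long-lived diet (delay_factor < 1) traverses the identical
    trajectory proportionally later.  Monotone classes change linearly
    in log10 until ``plateau_age`` (in effective time) and are constant
    after; ``midlife_reversal`` rises to the midpoint of the rising
    phase and falls back; ``damage_onset`` crosses zero (the detection
    limit, when added to a log10 LOD baseline) at ``onset_age`` and
    declines at ``late_decline`` per day after the plateau.
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    t = ages * delay_factor
    a0 = float(start_age)
    if trajectory_class == "flat":
        return np.zeros_like(t)
    if trajectory_class in ("monotone_up", "monotone_down_early"):
        frac = np.clip((t - a0) / (plateau_age - a0), 0.0, 1.0)
        sign = 1.0 if trajectory_class == "monotone_up" else -1.0
        return sign * amplitude * frac
    if trajectory_class == "midlife_reversal":
        mid = 0.5 * (a0 + plateau_age)
        tri = np.clip(1.0 - np.abs(t - mid) / (mid - a0), 0.0, 1.0)
        tri = np.where(t >= plateau_age, 0.0, tri)
        return amplitude * tri
    if trajectory_class == "damage_onset":
        if onset_age is None:
            raise ValueError("damage_onset requires an onset_age")
        rise = np.minimum(
            onset_slope * (np.minimum(t, plateau_age) - onset_age), onset_cap
        )
        fall = late_decline * np.clip(t - plateau_age, 0.0, None)
        return rise - fall
    raise ValueError(f"unknown trajectory class {trajectory_class!r}")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneratorConfig:
    """Study design and planted-effect parameters.

    Defaults are the desk-scale stand-in for the emulated study: 2 diets
    x 7 ages x 3 replicates, 2000 features of which 14% are
    age-associated and 300 are damage-onset, lifespans averaging
    50.8 d (standard) and 64.4 d (defined).
    """

    n_features: int = 2000
    n_damage: int = 300
    frac_age_associated: float = 0.14
    frac_diet_independent: float = 0.62
    frac_interdiet_below_twofold: float = 0.76
    ages_days: tuple[float, ...] = (3, 10, 25, 40, 50, 60, 63)
    n_replicates: int = 3
    noise_sd_log10: float = 0.1
    lod: float = 100.0
    plateau_age: Mapping[str, float] = field(
        default_factory=lambda: {"standard": 50.0, "defined": 60.0}
    )
    delay_factor: float = 50.8 / 64.4
    biomass_slope: float = 0.003
    seed: int = 0
    diets: tuple[str, str] = ("standard", "defined")
    mean_lifespans: Mapping[str, float] = field(
        default_factory=lambda: {"standard": 50.8, "defined": 64.4}
    )
    gompertz_b: float = 0.1
    n_flies: int = 200
    # planted-intensity details
    amplitude_log10: tuple[float, float] = (0.55, 0.9)
    baseline_log10: tuple[float, float] = (3.5, 0.3)
    baseline_bounds: tuple[float, float] = (3.2, 4.5)
    flat_baseline_log10: tuple[float, float] = (4.0, 0.5)
    flat_baseline_bounds: tuple[float, float] = (1.9, 5.5)
    onset_slope_log10: float = 0.08
    onset_cap_log10: float = 0.6
    late_decline_log10: float = 0.03
    trajectory_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "monotone_up": 0.5,
            "monotone_down_early": 0.42,
            "midlife_reversal": 0.08,
        }
    )
    progressive_offset_log10: tuple[float, float] = (0.5, 0.8)
    intermittent_offset_log10: tuple[float, float] = (0.6, 0.75)
    intermittent_offset_age_index: tuple[int, ...] = (3,)
    n_internal_standards: int = 2
    standard_log10: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "frac_age_associated",
            "frac_diet_independent",
            "frac_interdiet_below_twofold",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        ages = np.asarray(self.ages_days, dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages_days must be strictly increasing")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_age_associated + self.n_damage > self.n_features:
            raise ValueError("n_damage plus age-associated features exceed n_features")
        if self.frac_interdiet_below_twofold < self.frac_diet_independent:
            raise ValueError(
                "below-twofold fraction cannot be smaller than the diet-independent "
                "fraction (independent features have ~unit inter-diet ratio)"
            )

    @property
    def n_age_associated(self) -> int:
        return int(round(self.frac_age_associated * self.n_features))


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-feature planted labels for recovery testing."""

    table: pd.DataFrame  # indexed by feature_id

    @property
    def age_associated_ids(self) -> pd.Index:
        return self.table.index[self.table["age_associated"]]

    def class_fractions(self) -> pd.Series:
        """Diet-dependence fractions among age-associated features."""
        sub = self.table.loc[self.age_associated_ids, "diet_dependence"]
        return sub.value_counts(normalize=True)


@dataclass(frozen=True)
class SyntheticStudy:
    tables: dict[str, FeatureTable]
    truth: SyntheticTruth
    curves: dict[str, LifespanCurve]
    death_times: dict[str, np.ndarray]
    config: GeneratorConfig

    @property
    def internal_standard_ids(self) -> tuple[str, ...]:
        t = self.truth.table
        return tuple(t.index[t["is_standard"]])


# ---------------------------------------------------------------------------
# study generation


def _largest_remainder_counts(fracs: Mapping[str, float], n: int) -> dict[str, int]:
    raw = {k: v * n for k, v in fracs.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    rem = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rem]:
        counts[k] += 1
    return counts


def generate_study(cfg: GeneratorConfig) -> SyntheticStudy:
    """Generate per-diet feature tables, truth labels, and lifespans.

    Deterministic under ``cfg.seed``.  Raises if censoring at the
    detection limit wipes out the whole table (mis-scaled config).
    """
    rng = np.random.default_rng(cfg.seed)
    ages = np.asarray(cfg.ages_days, dtype=float)
    n_ages, n_reps = len(ages), cfg.n_replicates
    short_diet, long_diet = cfg.diets
    n_age = cfg.n_age_associated
    n_flat = cfg.n_features - n_age - cfg.n_damage
    lod_log = math.log10(cfg.lod)

    # ---- feature labels ------------------------------------------------
    traj_counts = _largest_remainder_counts(cfg.trajectory_mix, n_age)
    traj_classes = np.concatenate(
        [np.repeat(k, c) for k, c in traj_counts.items()]
        + [np.repeat("damage_onset", cfg.n_damage), np.repeat("flat", n_flat)]
    )
    n_indep = int(round(cfg.frac_diet_independent * n_age))
    n_prog = int(round((1.0 - cfg.frac_interdiet_below_twofold) * n_age))
    n_inter = n_age - n_indep - n_prog
    dep = np.array([None] * cfg.n_features, dtype=object)
    dep_labels = np.concatenate(
        [
            np.repeat("independent", n_indep),
            np.repeat("progressive", n_prog),
            np.repeat("intermittent", n_inter),
        ]
    )
    dep[:n_age] = rng.permutation(dep_labels)

    # ---- planted quantities -------------------------------------------
    amplitude = np.zeros(cfg.n_features)
    amplitude[:n_age] = rng.uniform(*cfg.amplitude_log10, size=n_age)
    baseline = np.zeros(cfg.n_features)
    baseline[:n_age] = np.clip(
        rng.normal(*cfg.baseline_log10, size=n_age), *cfg.baseline_bounds
    )
    flat_sl = slice(n_age + cfg.n_damage, cfg.n_features)
    baseline[flat_sl] = np.clip(
        rng.normal(*cfg.flat_baseline_log10, size=n_flat), *cfg.flat_baseline_bounds
    )

    plateau_short = float(cfg.plateau_age[short_diet])
    plateau_long = float(cfg.plateau_age[long_diet])
    dmg = slice(n_age, n_age + cfg.n_damage)
    onset_short = np.full(cfg.n_features, np.nan)
    onset_long = np.full(cfg.n_features, np.nan)
    onset_short[dmg] = rng.uniform(ages[0], plateau_short, size=cfg.n_damage)
    onset_long[dmg] = np.minimum(onset_short[dmg] / cfg.delay_factor, plateau_long)
    baseline[dmg] = lod_log

    offset = np.zeros(cfg.n_features)
    offset_age_idx = np.full(cfg.n_features, -1)
    is_prog = dep == "progressive"
    is_inter = dep == "intermittent"
    signs = rng.choice([-1.0, 1.0], size=cfg.n_features)
    offset[is_prog] = signs[is_prog] * rng.uniform(
        *cfg.progressive_offset_log10, size=int(is_prog.sum())
    )
    offset[is_inter] = signs[is_inter] * rng.uniform(
        *cfg.intermittent_offset_log10, size=int(is_inter.sum())
    )
    offset_age_idx[is_inter] = rng.choice(
        cfg.intermittent_offset_age_index, size=int(is_inter.sum())
    )

    # ---- noiseless mean log10 matrices per diet -----------------------
    means: dict[str, np.ndarray] = {}
    for diet in cfg.diets:
        warp = 1.0 if diet == short_diet else cfg.delay_factor
        plateau = plateau_short if diet == short_diet else plateau_long
        m = np.empty((cfg.n_features, n_ages))
        for i in range(cfg.n_features):
            cls = traj_classes[i]
            if cls == "damage_onset":
                tau = onset_short[i] if diet == short_diet else onset_long[i]
                tpl = trajectory_template(
                    cls,
                    ages,
                    plateau,
                    1.0,
                    onset_age=tau,
                    onset_slope=cfg.onset_slope_log10,
                    onset_cap=cfg.onset_cap_log10,
                    late_decline=cfg.late_decline_log10,
                )
            else:
                tpl = trajectory_template(cls, ages, plateau_short, warp, amplitude[i])
            m[i] = baseline[i] + tpl
        if diet == long_diet:
            m[is_prog] += offset[is_prog, None]
            rows = np.where(is_inter)[0]
            m[rows, offset_age_idx[rows]] += offset[rows]
        means[diet] = m

    # planted inter-diet ratio of lifespan-averaged intensities (noiseless)
    lin_means = {d: np.power(10.0, means[d]).mean(axis=1) for d in cfg.diets}
    ratio = lin_means[long_diet] / lin_means[short_diet]
    planted_ratio = np.maximum(ratio, 1.0 / ratio)

    # ---- intensities ---------------------------------------------------
    biomass = 1.0 - cfg.biomass_slope * ages
    if np.any(biomass <= 0):
        raise ValueError("biomass_slope drives biomass non-positive in the age range")
    std_ids = [f"IS{i + 1}" for i in range(cfg.n_internal_standards)]
    feature_ids = [f"F{i + 1:05d}" for i in range(cfg.n_features)] + std_ids

    tables: dict[str, FeatureTable] = {}
    for diet in cfg.diets:
        noise = rng.normal(0.0, cfg.noise_sd_log10, size=(cfg.n_features, n_ages, n_reps))
        vals = np.power(10.0, means[diet][:, :, None] + noise) * biomass[None, :, None]
        vals = np.where(vals < cfg.lod, 0.0, vals)
        std_noise = rng.normal(
            0.0, cfg.noise_sd_log10, size=(cfg.n_internal_standards, n_ages, n_reps)
        )
        std_vals = np.power(10.0, cfg.standard_log10 + std_noise)
        if not vals.any():
            raise ValueError("detection limit censors the entire table; rescale config")
        full = np.concatenate([vals, std_vals]).reshape(len(feature_ids), -1)
        cols, meta_rows = [], []
        for a in ages:
            for r in range(1, n_reps + 1):
                name = f"{diet}_a{a:g}_r{r}"
                cols.append(name)
                meta_rows.append(
                    {"sample": name, "diet": diet, "age_days": a, "replicate": r}
                )
        meta = pd.DataFrame(meta_rows).set_index("sample")
        tables[diet] = FeatureTable(
            pd.DataFrame(full, index=feature_ids, columns=cols), meta
        )

    # ---- truth ---------------------------------------------------------
    truth = pd.DataFrame(
        {
            "trajectory_class": np.concatenate(
                [traj_classes, np.repeat("flat", cfg.n_internal_standards)]
            ),
            "diet_dependence": np.concatenate(
                [dep, np.array([None] * cfg.n_internal_standards, dtype=object)]
            ),
            "age_associated": [c not in ("flat", "damage_onset") for c in traj_classes]
            + [False] * cfg.n_internal_standards,
            "amplitude_log10": np.concatenate(
                [amplitude, np.zeros(cfg.n_internal_standards)]
            ),
            "onset_age_standard": np.concatenate(
                [onset_short, np.full(cfg.n_internal_standards, np.nan)]
            ),
            "onset_age_defined": np.concatenate(
                [onset_long, np.full(cfg.n_internal_standards, np.nan)]
            ),
            "interdiet_offset_log10": np.concatenate(
                [offset, np.zeros(cfg.n_internal_standards)]
            ),
            "offset_age_days": np.concatenate(
                [
                    np.where(offset_age_idx >= 0, ages[offset_age_idx], np.nan),
                    np.full(cfg.n_internal_standards, np.nan),
                ]
            ),
            "planted_interdiet_ratio": np.concatenate(
                [planted_ratio, np.ones(cfg.n_internal_standards)]
            ),
            "is_standard": [False] * cfg.n_features + [True] * cfg.n_internal_standards,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    # ---- lifespans -----------------------------------------------------
    curves: dict[str, LifespanCurve] = {}
    deaths: dict[str, np.ndarray] = {}
    for diet in cfg.diets:
        params = calibrate_gompertz(cfg.mean_lifespans[diet], cfg.gompertz_b)
        d, curve = simulate_lifespan(params, cfg.n_flies, rng)
        deaths[diet] = d
        curves[diet] = LifespanCurve(
            curve.days, curve.fraction_alive, cfg.n_flies, diet
        )

    return SyntheticStudy(tables, SyntheticTruth(truth), curves, deaths, cfg)
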