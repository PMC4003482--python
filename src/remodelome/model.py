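"""End-to-end metabolome-remodeling analysis as a model/results pair.

``RemodelingModel`` wraps the inputs (per-diet feature tables and
survivorship curves, or a synthetic-study configuration) together with
all stage parameters; ``fit()`` executes the stages in dependency
order — normalization, detection-diversity trends, the per-feature
age-association screen, cross-diet trajectory concordance, clustering
with diet-dependence classification, and the remodeling-delay curves —
and returns a ``RemodelingResults`` bundle with a ``summary()`` table
and TSV export.  A fixed seed makes the whole run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clusters as cl
from . import diversity as dv
from . import screen as sc
from . import trajectories as tj
from .io import (
    FeatureTable,
    LifespanCurve,
    NormalizationSpec,
    normalize_intensities,
    read_feature_table,
    read_survivorship,
    write_feature_table,
    write_survivorship,
)
from .synthetic import GeneratorConfig, SyntheticStudy, generate_study

logger = logging.getLogger("remodelome")

__all__ = ["RunConfig", "RemodelingModel", "RemodelingResults", "run_full_analysis",
           "remodeling_delay_curves"]


@dataclass
class RunConfig:
    """All stage parameters of one analysis run."""

    generator: GeneratorConfig | None = None
    feature_table: str | None = None
    sample_metadata: str | None = None
    survivorship: str | None = None
    normalize: bool = True
    internal_standard_ids: tuple[str, ...] = ()
    kind: str = "metabolite"  # or "transcript" (alpha 0.0013)
    alpha: float | None = None  # overrides the kind default
    auto_calibrate: bool = False
    n_clusters: int = 12
    cluster_method: str = "hierarchical"
    n_perm: int = 1999
    dependence_alpha: float = 0.05
    min_fold: float = 2.0
    strong_r: float = 0.75
    seed: int = 0

    def screen_alpha(self) -> float:
        if self.alpha is not None:
            return self.alpha
        return sc.AgeAssocConfig().alpha(self.kind)

    # -- (de)serialization ------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = dataclasses.asdict(self.generator)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig(**gen)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(generator=gen, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _plain(obj: Any) -> Any:
    """YAML-safe plain types (tuples -> lists, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# delay curves


def _half_change_age(coeffs: np.ndarray, grid: np.ndarray, increasing: bool) -> float:
    v = np.polyval(coeffs, grid)
    if not increasing:
        v = -v
    peak = int(np.argmax(v))
    if peak == 0:
        return float("nan")
    seg = v[: peak + 1]
    level = seg.min() + 0.5 * (v[peak] - seg.min())
    return float(grid[np.argmax(seg >= level)])


def remodeling_delay_curves(
    table: FeatureTable,
    assignments: pd.Series,
    cluster_net_change: pd.Series,
    short_diet: str,
    long_diet: str,
) -> dict:
    """Average up/down trajectories per diet with quadratic fits and the
    remodeling-delay metric.

    Member features of increasing (net change > 0) and decreasing
    clusters are z-scored per feature within each diet at replicate
    level, averaged, and summarized by a quadratic polynomial fit
    through all replicate points.  The delay metric is the difference
    between the diets' half-change ages — the age at which each diet's
    fitted curve attains half of its own total change (an
    affine-invariant reading, unaffected by the per-diet z-scoring) —
    and the ratio short/long of those ages.
    """
    directions = {
        "increasing": cluster_net_change.index[cluster_net_change > 0],
        "decreasing": cluster_net_change.index[cluster_net_change < 0],
    }
    out: dict[str, Any] = {"curves": {}, "fits": {}, "skipped": {}}
    ages = table.ages
    grid = np.linspace(ages.min(), ages.max(), 2001)
    idx = pd.Index(table.feature_ids)
    for direction, cluster_ids in directions.items():
        members = assignments.index[assignments.isin(cluster_ids)]
        if len(members) == 0:
            out["skipped"][direction] = "no clusters with this net-change sign"
            logger.info("delay curves: %s direction absent", direction)
            continue
        pos = idx.get_indexer(members)
        per_diet = {}
        for diet in (short_diet, long_diet):
            arr = np.log10(table.design_array(diet)[pos])  # (m, ages, reps)
            flat = arr.reshape(len(pos), -1)
            z = (arr - flat.mean(axis=1)[:, None, None]) / flat.std(axis=1, ddof=1)[
                :, None, None
            ]
            curve = z.mean(axis=0)  # (n_ages, n_reps)
            x = np.repeat(ages, curve.shape[1])
            coeffs, _ = dv.fit_polynomial_trend(x, curve.ravel(), degree=2)
            per_diet[diet] = {
                "replicate_points": curve,
                "coeffs": coeffs,
                "half_change_age": _half_change_age(coeffs, grid, direction == "increasing"),
            }
        out["curves"][direction] = per_diet
        h_s = per_diet[short_diet]["half_change_age"]
        h_l = per_diet[long_diet]["half_change_age"]
        out["fits"][direction] = {
            "half_age_short": h_s,
            "half_age_long": h_l,
            "delay_days": h_l - h_s,
            "half_age_ratio": h_s / h_l if h_l else float("nan"),
        }
    if not out["fits"]:
        raise ValueError("no increasing or decreasing clusters to summarize")
    ratios = [f["half_age_ratio"] for f in out["fits"].values() if np.isfinite(f["half_age_ratio"])]
    out["mean_half_age_ratio"] = float(np.mean(ratios)) if ratios else float("nan")
    return out


# ---------------------------------------------------------------------------
# results bundle


@dataclass
class RemodelingResults:
    """Everything one analysis run computed.  Tables are pandas frames;
    ``skipped`` records stages that could not run and why."""

    config: RunConfig
    config_hash: str
    diets: tuple[str, str]
    diversity: pd.DataFrame
    diversity_trends: dict
    diversity_anova: dict
    lifespan: dict
    screens: dict[str, pd.DataFrame]
    calibration: dict
    fdr: dict
    overlap: sc.OverlapResult | None
    correlations: pd.DataFrame | None
    concordance: dict | None
    lifespan_corr: pd.DataFrame | None
    fold_changes: pd.DataFrame | None
    cluster_set: cl.ClusterSet | None
    cluster_trajectories: dict | None
    dependence: cl.DependenceSummary | None
    delay: dict | None
    pca: dict | None
    truth: pd.DataFrame | None = None
    skipped: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Metabolome remodeling analysis",
            "=" * 46,
            f"config {self.config_hash}  seed {cfg.seed}  kind {cfg.kind}",
            f"diets: {self.diets[0]} (short-lived) vs {self.diets[1]} (long-lived)",
            "",
            "Lifespan",
        ]
        for d, v in self.lifespan["mean_days"].items():
            lines.append(f"  mean lifespan {d:>9}: {v:6.1f} d")
        lr = self.lifespan.get("log_rank")
        if lr:
            lines.append(f"  log-rank chi2 {lr[0]:.2f}, p = {lr[1]:.3g}")
        lines += ["", "Metabolite diversity (detected features per sample)"]
        for d in self.diets:
            an = self.diversity_anova[d]
            pl = self.diversity_trends[d]["plateau_age"]
            pl_s = f"{pl:.1f} d" if pl is not None else "none"
            lines.append(
                f"  {d:>9}: RM-ANOVA F = {an[0]:.1f}, p = {an[1]:.2g}; plateau ~ {pl_s}; "
                f"total-signal slope {self.diversity_trends[d]['total_signal_slope']:+.3g}/d"
            )
        lines += ["", f"Age-association screen (alpha = {self.calibration['alpha_used']:g})"]
        for d in self.diets:
            scr = self.screens[d]
            n_el = int(scr["eligible"].sum())
            n_sig = int(scr["significant"].sum())
            fdr = self.fdr.get(d)
            fdr_s = f", plug-in FDR {fdr:.3f}" if fdr is not None and np.isfinite(fdr) else ""
            lines.append(
                f"  {d:>9}: {n_sig}/{len(scr)} significant "
                f"({100 * n_sig / len(scr):.1f}% of all, {n_el} eligible){fdr_s}"
            )
        if self.overlap is not None:
            ov = self.overlap
            lines.append(
                f"  overlap: {ov.both} in both diets ({ov.a_only} / {ov.b_only} diet-specific)"
            )
        if self.concordance is not None:
            c = self.concordance
            lines += [
                "",
                "Cross-diet trajectory concordance",
                f"  median matched-pair r = {c['observed_median_r']:.3f}; "
                f"re-pairing permutation p = {c['p']:.2g} ({c['n_perm']} permutations)",
            ]
        if self.fold_changes is not None:
            frac = float(self.fold_changes["below_twofold"].mean())
            lines.append(f"  inter-diet fold change below twofold: {100 * frac:.1f}% of overlap features")
        if self.dependence is not None:
            f = self.dependence.fractions
            lines += [
                "",
                f"Trajectory clusters (k = {self.cluster_set.k}, {cfg.cluster_method}, complete linkage)",
                f"  diet-independent {100 * f['independent']:.1f}%  "
                f"progressive {100 * f['progressive']:.1f}%  "
                f"intermittent {100 * f['intermittent']:.1f}%",
            ]
        if self.delay is not None:
            for direction, fit in self.delay["fits"].items():
                lines.append(
                    f"  {direction} signals: half-change at {fit['half_age_short']:.1f} d "
                    f"({self.diets[0]}) vs {fit['half_age_long']:.1f} d ({self.diets[1]}), "
                    f"delay {fit['delay_days']:+.1f} d, ratio {fit['half_age_ratio']:.3f}"
                )
        for stage, reason in self.skipped.items():
            lines.append(f"  [skipped] {stage}: {reason}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = f"# config_hash={self.config_hash} seed={self.config.seed}\n"

        def _write(df: pd.DataFrame, name: str, index_label: str | None = None) -> None:
            path = outdir / name
            with open(path, "w") as fh:
                fh.write(stamp)
                df.to_csv(fh, sep="\t", index_label=index_label)

        self.config.to_yaml(outdir / "config.yaml")
        _write(self.diversity, "diversity.tsv")
        for d in self.diets:
            _write(self.screens[d], f"screen_{d}.tsv", "feature_id")
        if self.overlap is not None:
            _write(self.overlap.labels.to_frame(), "overlap.tsv", "feature_id")
        if self.correlations is not None:
            _write(self.correlations, "trajectory_correlations.tsv", "feature_id")
        if self.fold_changes is not None:
            _write(self.fold_changes, "fold_changes.tsv", "feature_id")
        if self.cluster_set is not None:
            _write(self.cluster_set.assignments.to_frame(), "clusters.tsv", "feature_id")
            if self.cluster_set.classification is not None:
                _write(self.cluster_set.classification, "cluster_classification.tsv", "cluster")
            for d, m in self.cluster_trajectories.items():
                _write(m, f"cluster_mean_trajectory_{d}.tsv", "cluster")
        if self.delay is not None:
            _write(pd.DataFrame(self.delay["fits"]).T, "remodeling_delay.tsv", "direction")
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")


# ---------------------------------------------------------------------------
# the model


class RemodelingModel:
    """Analysis model over per-diet feature tables and lifespans.

    Construct from files (``from_files``), from an in-memory study, or
    from a synthetic-generator configuration (``from_config`` /
    ``from_synthetic``); ``fit()`` returns a ``RemodelingResults``.
    """

    def __init__(
        self,
        tables: dict[str, FeatureTable],
        curves: dict[str, LifespanCurve],
        config: RunConfig | None = None,
        death_times: dict[str, np.ndarray] | None = None,
        truth: pd.DataFrame | None = None,
    ) -> None:
        if len(tables) != 2:
            raise ValueError("exactly two diets are required")
        self.tables = tables
        self.curves = curves
        self.config = config or RunConfig()
        self.death_times = death_times
        self.truth = truth

    # -- constructors -----------------------------------------------
    @classmethod
    def from_synthetic(cls, config: RunConfig) -> "RemodelingModel":
        gen = config.generator or GeneratorConfig()
        gen = dataclasses.replace(gen, seed=config.seed)
        config = dataclasses.replace(config, generator=gen)
        study = generate_study(gen)
        config = dataclasses.replace(
            config, internal_standard_ids=study.internal_standard_ids
        )
        return cls(
            study.tables,
            study.curves,
            config,
            study.death_times,
            study.truth.table,
        )

    from_config = from_synthetic

    @classmethod
    def from_files(cls, config: RunConfig) -> "RemodelingModel":
        if not (config.feature_table and config.sample_metadata):
            raise ValueError("feature_table and sample_metadata paths are required")
        table = read_feature_table(config.feature_table, config.sample_metadata)
        tables = {d: table.subset(d) for d in table.diets}
        curves = read_survivorship(config.survivorship) if config.survivorship else {}
        return cls(tables, curves, config)

    @classmethod
    def from_study(cls, study: SyntheticStudy, config: RunConfig | None = None) -> "RemodelingModel":
        config = config or RunConfig(generator=study.config, seed=study.config.seed)
        config = dataclasses.replace(
            config, internal_standard_ids=study.internal_standard_ids
        )
        return cls(study.tables, study.curves, config, study.death_times, study.truth.table)

    # -- fitting ------------------------------------------------------
    def fit(self) -> RemodelingResults:
        cfg = self.config
        skipped: dict[str, str] = {}
        diets = self._diet_order()
        short_diet, long_diet = diets
        logger.info("diets: short-lived %s, long-lived %s", short_diet, long_diet)

        # normalization ------------------------------------------------
        tables = {}
        for d in diets:
            t = self.tables[d]
            if cfg.normalize and not t.normalized:
                spec = NormalizationSpec(
                    tuple(i for i in cfg.internal_standard_ids if i in t.feature_ids),
                    total_signal=True,
                )
                t = normalize_intensities(t, spec)
            tables[d] = t
        analysis_ids = [
            f for f in tables[short_diet].feature_ids if f not in cfg.internal_standard_ids
        ]
        tables = {
            d: FeatureTable(
                t.intensities.loc[analysis_ids], t.metadata.copy(), t.normalized
            )
            for d, t in tables.items()
        }

        # diversity ----------------------------------------------------
        div = pd.concat([dv.diversity_series(tables[d]) for d in diets], ignore_index=True)
        trends, anovas = {}, {}
        for d in diets:
            sub = div[div["diet"] == d]
            coeffs, fitted = dv.fit_polynomial_trend(
                sub["age_days"], sub["detected_count"], degree=3
            )
            slope = np.polyfit(sub["age_days"], sub["total_signal"], 1)[0]
            trends[d] = {
                "cubic_coeffs": coeffs,
                "plateau_age": dv.plateau_age(
                    coeffs, (sub["age_days"].min(), sub["age_days"].max())
                ),
                "total_signal_slope": float(slope),
            }
            anovas[d] = dv.diversity_age_anova(sub)
            logger.info(
                "diversity %s: ANOVA p=%.3g plateau=%s", d, anovas[d][1], trends[d]["plateau_age"]
            )

        # lifespan -----------------------------------------------------
        lifespan: dict[str, Any] = {"mean_days": {}}
        deaths = self.death_times or {
            d: _deaths_from_curve(self.curves[d]) for d in diets if d in self.curves
        }
        for d in diets:
            if d in deaths and len(deaths[d]):
                lifespan["mean_days"][d] = dv.mean_lifespan(deaths[d])
        if all(d in deaths and len(deaths[d]) for d in diets):
            lifespan["log_rank"] = dv.log_rank_test(deaths[short_diet], deaths[long_diet])

        # screen -------------------------------------------------------
        alpha = cfg.screen_alpha()
        screens = {d: sc.rm_anova_table(tables[d], d, alpha) for d in diets}
        calibration: dict[str, Any] = {"alpha_used": alpha, "auto": {}}
        if cfg.auto_calibrate:
            for d in diets:
                pv = screens[d].loc[screens[d]["eligible"], "p"].to_numpy()
                calib = sc.calibrate_threshold(pv)
                calibration["auto"][d] = calib
            alpha = min(c.alpha_star for c in calibration["auto"].values())
            calibration["alpha_used"] = alpha
            screens = {d: sc.rm_anova_table(tables[d], d, alpha) for d in diets}
        fdr = {
            d: sc.plug_in_fdr(
                screens[d].loc[screens[d]["eligible"], "p"].to_numpy(), alpha
            )
            for d in diets
        }
        for d in diets:
            logger.info(
                "screen %s: %d eligible, %d significant at alpha=%g",
                d,
                int(screens[d]["eligible"].sum()),
                int(screens[d]["significant"].sum()),
                alpha,
            )
        overlap = sc.diet_overlap(screens[short_diet], screens[long_diet])
        both = list(overlap.both_ids)
        logger.info("overlap: %d both, %d/%d diet-only", overlap.both, overlap.a_only, overlap.b_only)

        # trajectories -------------------------------------------------
        correlations = concordance = lifespan_corr = folds = None
        cluster_set = cluster_traj = dependence = delay = pca = None
        merged = _merge_tables(tables, diets)
        if not both:
            skipped["trajectories"] = "no overlapping age-associated features"
            logger.info("trajectories skipped: empty overlap")
        else:
            traj_log = tj.average_replicates(merged, both, log10=True)
            traj_lin = tj.average_replicates(merged, both, log10=False)
            correlations = tj.diet_pair_correlations(traj_log)
            folds = tj.fold_changes(traj_lin)
            if self.curves:
                lifespan_corr = tj.lifespan_correlation(traj_log, self.curves, cfg.strong_r)
            if len(both) >= 10:
                rng = np.random.default_rng((cfg.seed, 0x7261))
                concordance = tj.permutation_concordance(traj_log, cfg.n_perm, rng)
                logger.info(
                    "concordance: median r=%.3f p=%.3g",
                    concordance["observed_median_r"],
                    concordance["p"],
                )
            else:
                skipped["concordance"] = f"only {len(both)} overlap features (<10)"
                logger.info("concordance skipped: %s", skipped["concordance"])

            # clustering ------------------------------------------------
            scaled_across = tj.scale(traj_log, "across_diets")
            scaled_within = tj.scale(traj_log, "within_diet")
            n_clusterable = len(scaled_across.feature_ids)
            if n_clusterable < cfg.n_clusters:
                skipped["clusters"] = (
                    f"{n_clusterable} scalable overlap features < k={cfg.n_clusters}"
                )
                logger.info("clustering skipped: %s", skipped["clusters"])
            else:
                cluster_set = cl.hierarchical_clusters(
                    scaled_across, cfg.n_clusters, cfg.cluster_method
                )
                cluster_traj = cl.cluster_mean_trajectory(cluster_set, scaled_across)
                cl.classify_diet_dependence(
                    cluster_set, merged, cfg.dependence_alpha, cfg.min_fold
                )
                dependence = cl.dependence_frequencies(cluster_set)
                logger.info("dependence fractions: %s", dependence.fractions)

                within_means = cl.cluster_mean_trajectory(cluster_set, scaled_within)
                net = sum(
                    m.iloc[:, -1] - m.iloc[:, 0] for m in within_means.values()
                ) / len(within_means)
                try:
                    delay = remodeling_delay_curves(
                        merged, cluster_set.assignments, net, short_diet, long_diet
                    )
                except ValueError as err:
                    skipped["delay"] = str(err)

            # dual-scaling PCA ------------------------------------------
            pca = _dual_pca(merged, both, diets)

        return RemodelingResults(
            config=cfg,
            config_hash=cfg.config_hash(),
            diets=diets,
            diversity=div,
            diversity_trends=trends,
            diversity_anova=anovas,
            lifespan=lifespan,
            screens=screens,
            calibration=calibration,
            fdr=fdr,
            overlap=overlap,
            correlations=correlations,
            concordance=concordance,
            lifespan_corr=lifespan_corr,
            fold_changes=folds,
            cluster_set=cluster_set,
            cluster_trajectories=cluster_traj,
            dependence=dependence,
            delay=delay,
            pca=pca,
            truth=self.truth,
            skipped=skipped,
        )

    # -- helpers ------------------------------------------------------
    def _diet_order(self) -> tuple[str, str]:
        """(short-lived, long-lived), by mean lifespan when known."""
        diets = sorted(self.tables)
        means = {}
        for d in diets:
            if self.death_times and d in self.death_times:
                means[d] = float(np.mean(self.death_times[d]))
            elif d in self.curves:
                means[d] = float(np.trapezoid(self.curves[d].fraction_alive, self.curves[d].days))
        if len(means) == 2:
            diets = sorted(diets, key=lambda d: means[d])
        return tuple(diets)  # type: ignore[return-value]


def _deaths_from_curve(curve: LifespanCurve) -> np.ndarray:
    if curve.cohort_size is None:
        return np.array([])
    counts = np.round(dv.deaths_per_interval(curve)).astype(int)
    return np.repeat(curve.days[1:], counts)


def _merge_tables(tables: dict[str, FeatureTable], diets) -> FeatureTable:
    mats = [tables[d].intensities for d in diets]
    metas = [tables[d].metadata for d in diets]
    return FeatureTable(
        pd.concat(mats, axis=1), pd.concat(metas), tables[diets[0]].normalized
    )


def _dual_pca(merged: FeatureTable, feature_ids, diets) -> dict:
    """PCA of samples under across-diet and within-diet feature scaling."""
    log = np.log10(merged.intensities.loc[feature_ids].to_numpy(float))
    meta = merged.metadata
    out = {}
    for mode in ("across_diets", "within_diet"):
        z = np.empty_like(log)
        if mode == "across_diets":
            z = (log - log.mean(axis=1, keepdims=True)) / log.std(axis=1, ddof=1, keepdims=True)
        else:
            for d in diets:
                cols = np.asarray(meta["diet"] == d)
                sub = log[:, cols]
                z[:, cols] = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(
                    axis=1, ddof=1, keepdims=True
                )
        ok = np.isfinite(z).all(axis=1)
        frame = pd.DataFrame(z[ok].T, index=merged.intensities.columns)
        scores, evr = cl.pca_project(frame)
        scores = scores.join(meta[["diet", "age_days", "replicate"]])
        out[mode] = {"scores": scores, "explained_variance_ratio": evr}
    return out


def run_full_analysis(config: RunConfig) -> RemodelingResults:
    """Execute the full pipeline described by ``config``.

    Uses the synthetic generator when ``config.generator`` is set (or
    no input paths are given), otherwise reads the input files.
    """
    if config.generator is not None or config.feature_table is None:
        model = RemodelingModel.from_synthetic(config)
    else:
        model = RemodelingModel.from_files(config)
    return model.fit()
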