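"""Trajectory averaging, scaling, concordance, and fold changes."""

import numpy as np
import pandas as pd
import pytest

import remodelome as rm
from remodelome.trajectories import TrajectoryMatrix
from conftest import make_table


def matrix_from(data_by_diet, ages=(3, 10, 25, 40)):
    ages = np.asarray(ages, float)
    data = {
        d: pd.DataFrame(
            np.asarray(v, float),
            index=[f"F{i}" for i in range(len(v))],
            columns=ages,
        )
        for d, v in data_by_diet.items()
    }
    return TrajectoryMatrix(ages, data)


class TestAveraging:
    def test_mean_across_replicates(self):
        table = make_table([[1.0, 2.0, 3.0]], ages=(3,), n_reps=3)
        m = rm.average_replicates(table)
        assert m.data["standard"].iloc[0, 0] == 2.0

    def test_identical_replicates_unchanged(self):
        table = make_table([[5.0, 5.0, 7.0, 7.0]], ages=(3, 10), n_reps=2)
        m = rm.average_replicates(table)
        np.testing.assert_allclose(m.data["standard"].iloc[0], [5.0, 7.0])

    def test_averaging_commutes_with_direct_computation(self, small_study):
        table = small_study.tables["standard"]
        ids = table.feature_ids[:20]
        m = rm.average_replicates(table, ids)
        arr = table.design_array("standard")[:20].mean(axis=2)
        np.testing.assert_allclose(m.data["standard"].to_numpy(), arr)


class TestScaling:
    def test_row_zscore(self):
        m = matrix_from({"a": [[1, 2, 3]], "b": [[1, 2, 3]]}, ages=(3, 10, 25))
        z = rm.scale(m, "within_diet")
        np.testing.assert_allclose(z.data["a"].iloc[0], [-1, 0, 1])

    def test_within_diet_removes_offset_across_diets_keeps_it(self):
        m = matrix_from({"a": [[1, 2, 3]], "b": [[11, 12, 13]]}, ages=(3, 10, 25))
        zw = rm.scale(m, "within_diet")
        np.testing.assert_allclose(zw.data["a"].iloc[0], zw.data["b"].iloc[0])
        za = rm.scale(m, "across_diets")
        assert za.data["a"].iloc[0].mean() == pytest.approx(-za.data["b"].iloc[0].mean())
        assert za.data["b"].iloc[0].mean() > 0

    def test_idempotence(self, small_study):
        table = small_study.tables
        merged_ids = table["standard"].feature_ids[:50]
        from remodelome.model import _merge_tables

        merged = _merge_tables(table, list(table))
        m = rm.average_replicates(merged, merged_ids, log10=False)
        for mode in ("within_diet", "across_diets"):
            z1 = rm.scale(m, mode)
            z2 = rm.scale(z1, mode)
            for d in z1.diets:
                np.testing.assert_allclose(
                    z1.data[d].to_numpy(), z2.data[d].to_numpy(), atol=1e-12
                )

    def test_constant_rows_dropped_with_flag(self):
        m = matrix_from({"a": [[1, 2, 3], [4, 4, 4]], "b": [[1, 2, 3], [4, 4, 4]]},
                        ages=(3, 10, 25))
        z = rm.scale(m, "within_diet")
        assert list(z.feature_ids) == ["F0"]
        assert z.data["a"].attrs["dropped_constant"] == ["F1"]

    def test_unknown_mode_rejected(self):
        m = matrix_from({"a": [[1, 2, 3]]}, ages=(3, 10, 25))
        with pytest.raises(ValueError):
            rm.scale(m, "sideways")


class TestPairCorrelations:
    def test_identity_and_negation(self):
        m = matrix_from(
            {"a": [[1, 2, 4], [1, 2, 4]], "b": [[1, 2, 4], [4, 3, 1]]},
            ages=(3, 10, 25),
        )
        out = rm.diet_pair_correlations(m)
        np.testing.assert_allclose(out["r"], [1.0, -1.0], atol=1e-12)

    def test_hand_computed_r(self):
        m = matrix_from({"a": [[1, 2, 3, 4]], "b": [[1, 2, 4, 3]]})
        out = rm.diet_pair_correlations(m)
        assert out["r"].iloc[0] == pytest.approx(0.8, abs=1e-12)

    def test_scaling_invariance(self, small_study):
        # Pearson r is location/scale free, so within-diet scaling is a no-op
        from remodelome.model import _merge_tables

        merged = _merge_tables(small_study.tables, list(small_study.tables))
        truth = small_study.truth.table
        detected = (merged.intensities > 0).all(axis=1)
        ids = truth.index[truth["age_associated"] & detected][:50]
        m = rm.average_replicates(merged, ids, log10=True)
        raw = rm.diet_pair_correlations(m)["r"]
        z = rm.scale(m, "within_diet")
        again = rm.diet_pair_correlations(z)["r"]
        np.testing.assert_allclose(raw.to_numpy(), again.to_numpy(), atol=1e-9)

    def test_constant_trajectory_flagged(self):
        m = matrix_from({"a": [[1, 1, 1]], "b": [[1, 2, 3]]}, ages=(3, 10, 25))
        out = rm.diet_pair_correlations(m)
        assert not out["defined"].iloc[0]


class TestPermutationConcordance:
    def test_matched_identical_sets_attain_minimum_p(self):
        rng = np.random.default_rng(8)
        arr = rng.normal(size=(50, 7))
        m = matrix_from({"a": arr, "b": arr}, ages=(3, 10, 25, 40, 50, 60, 63))
        res = rm.permutation_concordance(m, n_perm=999, seed=1)
        assert res["observed_median_r"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1 / 1000)

    def test_row_shuffled_null_is_calibrated(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            arr = rng.normal(size=(30, 7))
            m = matrix_from(
                {"a": arr, "b": arr[rng.permutation(30)]},
                ages=(3, 10, 25, 40, 50, 60, 63),
            )
            ps.append(rm.permutation_concordance(m, n_perm=99, seed=seed)["p"])
        ps = np.asarray(ps)
        # super-uniform: empirical CDF never far above the diagonal
        for x in (0.05, 0.1, 0.25, 0.5):
            assert (ps <= x).mean() <= x + 3 * np.sqrt(x * (1 - x) / len(ps))

    def test_exhaustive_enumeration_matches_sampled(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(3, 5))
        m = matrix_from({"a": a, "b": a + rng.normal(0, 0.4, a.shape)},
                        ages=(3, 10, 25, 40, 50))
        exact = rm.permutation_concordance(m, exhaustive=True, n_perm=1)
        assert exact["n_perm"] == 6  # 3! pairings
        # large-sample re-pairing estimate converges to the enumeration value
        with pytest.raises(ValueError):
            rm.permutation_concordance(m, n_perm=999, seed=0)  # n < 10 needs exhaustive
        null = exact["null_medians"]
        assert exact["p"] == pytest.approx(
            (1 + (null >= exact["observed_median_r"] - 1e-12).sum()) / (len(null) + 1)
        )

    def test_input_contracts(self):
        m = matrix_from({"a": [[1, 2, 3]], "b": [[1, 2, 3]]}, ages=(3, 10, 25))
        with pytest.raises(ValueError, match="too few"):
            rm.permutation_concordance(m, n_perm=9)


class TestLifespanCorrelation:
    def test_trivial_correlations(self):
        curve = rm.io.LifespanCurve(
            np.arange(0.0, 30.0), np.linspace(1, 0, 30), cohort_size=10, diet="a"
        )
        ages = (3, 10, 25)
        surv = curve.interpolate(np.asarray(ages, float))
        m = matrix_from({"a": [surv, 1 - surv]}, ages=ages)
        out = rm.lifespan_correlation(m, {"a": curve})
        np.testing.assert_allclose(out["r"], [1.0, -1.0], atol=1e-12)
        assert out["strong"].all()

    def test_rising_features_track_falling_survivorship(self, recovery_runs):
        rates = []
        for res in recovery_runs:
            truth = res.truth
            up = truth.index[
                (truth["trajectory_class"] == "monotone_up")
                & truth["age_associated"]
            ]
            sub = res.lifespan_corr.loc[res.lifespan_corr.index.isin(up)]
            rates.append((sub["strong"] & (sub["r"] < 0)).mean())
        assert np.mean(rates) >= 0.80


class TestFoldChanges:
    def test_intradiet_max_over_min(self):
        m = matrix_from({"a": [[2, 4, 8]], "b": [[2, 4, 8]]}, ages=(3, 10, 25))
        out = rm.fold_changes(m)
        assert out["intradiet_a"].iloc[0] == 4.0

    def test_identical_diets_below_twofold(self):
        m = matrix_from({"a": [[2, 4, 8]], "b": [[2, 4, 8]]}, ages=(3, 10, 25))
        out = rm.fold_changes(m)
        assert out["interdiet"].iloc[0] == 1.0
        assert bool(out["below_twofold"].iloc[0])

    def test_interdiet_ratio_orientation_free(self):
        m = matrix_from({"a": [[3, 3, 3]], "b": [[7, 7, 7]]}, ages=(3, 10, 25))
        out = rm.fold_changes(m)
        assert out["interdiet"].iloc[0] == pytest.approx(7 / 3)
        assert not bool(out["below_twofold"].iloc[0])
        flipped = rm.fold_changes(
            matrix_from({"a": [[7, 7, 7]], "b": [[3, 3, 3]]}, ages=(3, 10, 25))
        )
        assert flipped["interdiet"].iloc[0] == pytest.approx(7 / 3)

    def test_nonpositive_values_rejected(self):
        m = matrix_from({"a": [[0, 1, 2]], "b": [[1, 1, 1]]}, ages=(3, 10, 25))
        with pytest.raises(ValueError, match="exclude censored"):
            rm.fold_changes(m)

    def test_scaled_input_rejected(self):
        m = matrix_from({"a": [[1, 2, 3]], "b": [[1, 2, 3]]}, ages=(3, 10, 25))
        z = rm.scale(m, "within_diet")
        with pytest.raises(ValueError, match="unscaled"):
            rm.fold_changes(z)
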