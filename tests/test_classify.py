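"""Feature selection and LOSO classification: filter, RFE+CBR, evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from thermostress.classify import (
    FeatureTable,
    evaluate_confusion,
    filter_select,
    loso_accuracy_curve,
    svm_rfe_cbr_rank,
)
from thermostress.errors import TableAssemblyError
from thermostress.rois import all_feature_names, thermal_feature_names


def make_table(n_subjects=20, n_noise=8, informative=None, seed=0):
    """Synthetic observation table; ``informative`` maps name -> class shift."""
    rng = np.random.default_rng(seed)
    informative = informative or {}
    rows = []
    for i in range(n_subjects):
        for sess, lab in (("Rest", 2), ("Stroop", 1)):
            row = {"subject": f"S{i:02d}", "session": sess, "label": lab}
            for name, shift in informative.items():
                row[name] = (shift if lab == 1 else 0.0) + rng.normal()
            for j in range(n_noise):
                row[f"noise{j}"] = rng.normal()
            rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


class TestFeatureTable:
    def test_duplicate_rows_rejected(self):
        t = make_table(4)
        dup = pd.concat([t.data, t.data.iloc[[0]]])
        with pytest.raises(TableAssemblyError):
            FeatureTable(dup)

    def test_subject_without_both_sessions_rejected(self):
        t = make_table(4)
        with pytest.raises(TableAssemblyError):
            FeatureTable(t.data.iloc[1:])

    def test_views_partition_features(self, rng):
        rows = []
        for i in range(4):
            for sess, lab in (("Rest", 2), ("Stroop", 1)):
                row = {"subject": f"S{i}", "session": sess, "label": lab}
                row.update({f: rng.normal() for f in all_feature_names()})
                rows.append(row)
        table = FeatureTable(pd.DataFrame(rows))
        full = table.view("full")
        thermo = table.view("thermo")
        nothermo = table.view("nothermo")
        assert len(full.feature_columns) == 75
        assert thermo.feature_columns == thermal_feature_names()
        assert len(nothermo.feature_columns) == 19
        assert set(thermo.feature_columns) | set(nothermo.feature_columns) == set(
            full.feature_columns
        )
        assert not set(thermo.feature_columns) & set(nothermo.feature_columns)


class TestFilter:
    def test_label_copy_retained(self):
        t = make_table(10)
        t.data["oracle"] = t.data["label"].astype(float)
        kept = filter_select(FeatureTable(t.data)).feature_columns
        assert "oracle" in kept

    def test_constant_feature_excluded_with_warning(self):
        t = make_table(10)
        t.data["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            kept = filter_select(FeatureTable(t.data)).feature_columns
        assert "flat" not in kept

    def test_column_order_preserved(self):
        t = make_table(12, informative={"infA": 3.0, "infB": -3.0})
        kept = filter_select(t).feature_columns
        order = {c: i for i, c in enumerate(t.feature_columns)}
        assert kept == sorted(kept, key=order.get)

    def test_type_one_error_calibrated(self):
        """Pure-noise features survive the p<=0.05 filter at ~5%."""
        retained = []
        for seed in range(200):
            t = make_table(n_subjects=19, n_noise=10, seed=seed)
            retained.append(len(filter_select(t).feature_columns))
        assert np.mean(retained) == pytest.approx(0.5, abs=0.15)


class TestRFE:
    def test_single_feature_is_rank_one(self):
        t = make_table(8, n_noise=0, informative={"only": 1.0})
        result = svm_rfe_cbr_rank(t)
        assert result.ranking == ["only"]

    def test_planted_informative_in_top_two(self):
        t = make_table(20, n_noise=8, informative={"infA": 2.0, "infB": -2.0}, seed=1)
        result = svm_rfe_cbr_rank(t)
        assert set(result.ranking[:2]) == {"infA", "infB"}

    def test_ranking_is_deterministic_permutation(self):
        t = make_table(12, informative={"inf": 2.0})
        r1 = svm_rfe_cbr_rank(t)
        r2 = svm_rfe_cbr_rank(t)
        assert r1.ranking == r2.ranking
        assert sorted(r1.ranking) == sorted(t.feature_columns)

    def test_median_rank_improves_with_effect_size(self):
        """The planted feature's median rank never worsens as its class
        separation grows."""
        median_ranks = []
        for shift in (0.5, 1.0, 2.0):
            ranks = []
            for seed in range(10):
                t = make_table(16, n_noise=6, informative={"inf": shift}, seed=seed)
                ranks.append(svm_rfe_cbr_rank(t).ranking.index("inf") + 1)
            median_ranks.append(np.median(ranks))
        assert median_ranks[0] >= median_ranks[1] >= median_ranks[2]

    def test_cbr_counteracts_correlation_bias(self):
        """Duplicated informative feature: without CBR one copy is often
        under-ranked below noise; with CBR both copies stay on top."""
        both_top_on = both_top_off = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rows = []
            for i in range(20):
                for sess, lab in (("Rest", 2), ("Stroop", 1)):
                    row = {"subject": f"S{i:02d}", "session": sess, "label": lab}
                    base = (2.0 if lab == 1 else 0.0) + rng.normal()
                    row["infA"] = base
                    row["infB"] = base  # exact duplicate, r = 1
                    for j in range(8):
                        row[f"noise{j}"] = rng.normal()
                    rows.append(row)
            t = FeatureTable(pd.DataFrame(rows))
            both_top_on += set(svm_rfe_cbr_rank(t, use_cbr=True).ranking[:2]) == {
                "infA", "infB",
            }
            both_top_off += set(svm_rfe_cbr_rank(t, use_cbr=False).ranking[:2]) == {
                "infA", "infB",
            }
        # the bias: without CBR a copy drops below noise in >= 30% of runs
        assert n_seeds - both_top_off >= 0.3 * n_seeds
        # the correction: with CBR both copies usually stay on top
        assert both_top_on >= 0.6 * n_seeds
        assert both_top_on > both_top_off

    def test_correlated_cluster_recorded(self):
        t = make_table(12, informative={"infA": 2.0})
        t.data["infB"] = t.data["infA"]
        result = svm_rfe_cbr_rank(FeatureTable(t.data))
        first_step = result.clusters_per_step[0]
        assert any({"infA", "infB"} <= set(cl) for cl in first_step)


class TestLOSO:
    def test_perfect_feature_reaches_full_accuracy(self):
        t = make_table(8, n_noise=3)
        t.data["oracle"] = t.data["label"].astype(float)
        res = loso_accuracy_curve(FeatureTable(t.data))
        assert res.accuracies[0] == 1.0
        assert res.ranking[0] == "oracle"

    def test_subject_never_in_own_training_fold(self):
        t = make_table(8, informative={"inf": 2.0})
        res = loso_accuracy_curve(t)
        # each subject appears as test exactly once per k
        per_k = res.predictions.groupby("k")["subject"].value_counts()
        assert (per_k == 2).all()  # both sessions, once each

    def test_confusion_rows_sum_to_100(self):
        t = make_table(8, informative={"inf": 2.0})
        res = loso_accuracy_curve(t)
        for conf in res.confusion.values():
            assert np.allclose(conf.sum(axis=1), 100.0)

    def test_strict_mode_runs_leakage_free(self):
        t = make_table(10, informative={"inf": 3.0})
        res = loso_accuracy_curve(t, mode="strict")
        assert res.ranking is None  # no global ranking exists in strict mode
        assert res.accuracies.max() <= 1.0

    def test_null_labels_near_chance(self):
        """Label-shuffled tables: LOSO accuracy (averaged over rank depths)
        stays inside the 95% binomial band around 0.5."""
        accs = []
        for seed in range(20):
            t = make_table(n_subjects=19, n_noise=10, seed=seed + 100)
            res = loso_accuracy_curve(t, filter_alpha=1.0)
            accs.append(res.accuracies.mean())
        n_obs = 38
        half_width = 1.96 * np.sqrt(0.25 / n_obs)
        assert abs(np.mean(accs) - 0.5) < half_width

    def test_unbalanced_subject_rejected(self):
        t = make_table(6, informative={"inf": 2.0})
        bad = t.data.copy()
        bad.loc[bad.index[-1], "label"] = 2  # subject with two Rest labels
        with pytest.raises(TableAssemblyError):
            FeatureTable(bad)


class TestEvaluateConfusion:
    def test_identity_matrix(self):
        out = evaluate_confusion([[100.0, 0.0], [0.0, 100.0]], (19, 19))
        assert out["accuracy_pct"] == 100.0
        assert out["type2_error_pct"] == 0.0
        assert out["type1_error_pct"] == 0.0

    def test_counts_mode(self):
        out = evaluate_confusion([[18, 1], [0, 19]], (19, 19), as_percent=False)
        assert out["accuracy_pct"] == pytest.approx(100 * 37 / 38)

    def test_bad_row_sum_rejected(self):
        with pytest.raises(ValueError):
            evaluate_confusion([[90.0, 5.0], [0.0, 100.0]], (19, 19))
        with pytest.raises(ValueError):
            evaluate_confusion([[18, 2], [0, 19]], (19, 19), as_percent=False)
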