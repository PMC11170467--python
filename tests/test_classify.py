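"""Classification: scheme assembly, score definitions, determinism,
attribution additivity and the progressive feature curve."""

import numpy as np
import pytest

import eegconn as e
from eegconn.classify import _binary_scores, explain

from conftest import make_feature_bench


class TestAssembleFeatures:
    def test_complementary_scheme_keeps_all_variants_of_family(
            self, planted_tensor, planted_selection, coherence_features):
        fm = coherence_features
        assert set(fm.provenance.family) == {"Coh"}
        assert set(fm.provenance.variant) <= {"instantaneous", "lagged",
                                              "total"}
        assert fm.n_features > 0

    def test_single_metric_scheme_is_one_variant(self, planted_tensor,
                                                 planted_selection):
        survivors = [r for r in planted_selection if r.passes_fdr]
        fm = e.assemble_features(planted_tensor, survivors, "single_metric",
                                 family="Coh", variant="lagged")
        assert set(fm.provenance.variant) == {"lagged"}
        assert len(set(fm.provenance.band)) > 1

    def test_time_domain_scheme_families(self, planted_tensor,
                                         planted_selection):
        survivors = [r for r in planted_selection if r.passes_fdr]
        fm = e.assemble_features(planted_tensor, survivors, "time_domain")
        assert set(fm.provenance.family) <= {"rho", "MI", "CMI", "WMI",
                                             "O_info"}
        assert set(fm.provenance.band) == {"broadband"}

    def test_empty_survivors_rejected(self, planted_tensor):
        with pytest.raises(ValueError, match="nothing to classify"):
            e.assemble_features(planted_tensor, [], "time_domain")

    def test_unknown_scheme_rejected(self, planted_tensor):
        with pytest.raises(ValueError, match="unknown scheme"):
            e.assemble_features(planted_tensor, [], "everything")


class TestScores:
    def test_f1_matches_hand_confusion_matrix(self):
        y_true = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        y_pred = np.array([1, 0, 1, 0, 0, 1, 0, 1])
        s = _binary_scores(y_true, y_pred)
        # tp=3 fp=1 fn=1 tn=3
        assert s["precision"] == pytest.approx(3 / 4)
        assert s["recall"] == pytest.approx(3 / 4)
        assert s["f1"] == pytest.approx(2 * 0.75 * 0.75 / 1.5)
        assert s["specificity"] == pytest.approx(3 / 4)
        assert s["accuracy"] == pytest.approx(6 / 8)


class TestTrainAndEvaluate:
    def test_separable_cohort_classified_perfectly(self, coherence_features):
        report, _ = e.train_and_evaluate(coherence_features, seed=0,
                                         n_boot=200)
        assert report.scores["f1"][0] >= 0.95
        assert report.auc >= 0.95

    def test_deterministic_given_seed(self, coherence_features):
        r1, _ = e.train_and_evaluate(coherence_features, seed=5, n_boot=100)
        r2, _ = e.train_and_evaluate(coherence_features, seed=5, n_boot=100)
        assert r1.scores == r2.scores
        assert r1.test_scores == r2.test_scores

    def test_label_equal_single_column_is_trivially_learned(self):
        import pandas as pd
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        fm = e.FeatureMatrix(y[:, None].astype(float), y, ["label_copy"],
                             pd.DataFrame({"family": ["x"], "variant": ["v"],
                                           "band": ["b"], "region_a": [0],
                                           "region_b": [1],
                                           "direction": ["hyper"]}))
        report, _ = e.train_and_evaluate(fm, seed=1, n_boot=100,
                                         search_budget=5)
        assert report.scores["f1"][0] == 1.0

    def test_shuffled_labels_score_at_chance(self, coherence_features):
        fm = coherence_features
        rng = np.random.default_rng(0)
        f1s = []
        for s in range(10):
            fmsh = e.FeatureMatrix(fm.X, rng.permutation(fm.y),
                                   fm.feature_names, fm.provenance,
                                   fm.subjects)
            rep, _ = e.train_and_evaluate(fmsh, seed=s, n_boot=100,
                                          search_budget=8)
            f1s.append(rep.scores["f1"][0])
        assert 0.35 < np.mean(f1s) < 0.65

    def test_roc_band_is_monotone(self, coherence_features):
        report, _ = e.train_and_evaluate(coherence_features, seed=2,
                                         n_boot=300)
        assert np.all(np.diff(report.roc_mean_tpr) >= 0)
        assert 0.45 <= report.auc <= 1.0

    def test_too_few_subjects_rejected(self):
        import pandas as pd
        y = np.array([0, 0, 1, 1])
        fm = e.FeatureMatrix(np.random.default_rng(0).random((4, 2)), y,
                             ["a", "b"],
                             pd.DataFrame({"family": ["x", "x"],
                                           "variant": ["v", "v"],
                                           "band": ["b", "b"],
                                           "region_a": [0, 0],
                                           "region_b": [1, 2],
                                           "direction": ["hyper", "hypo"]}))
        with pytest.raises(ValueError, match="at least 10"):
            e.train_and_evaluate(fm)


class TestExplain:
    def test_attributions_sum_to_margin_output(self, coherence_features):
        report, model = e.train_and_evaluate(coherence_features, seed=1,
                                             n_boot=100)
        fm = coherence_features
        attr = explain(model, fm)
        contribs = attr.attrs["contribs"]
        import xgboost as xgb
        margins = model.get_booster().predict(
            xgb.DMatrix(fm.X), output_margin=True)
        assert np.allclose(contribs.sum(axis=1), margins, atol=1e-5)

    def test_unused_feature_has_zero_attribution(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        X = np.column_stack([y + 0.01 * rng.standard_normal(40),
                             np.zeros(40)])
        fm = e.FeatureMatrix(X, y, ["signal", "constant"],
                             pd.DataFrame({"family": ["x"] * 2,
                                           "variant": ["v"] * 2,
                                           "band": ["b"] * 2,
                                           "region_a": [0, 0],
                                           "region_b": [1, 2],
                                           "direction": ["hyper"] * 2}))
        _, model = e.train_and_evaluate(fm, seed=0, n_boot=100,
                                        search_budget=5)
        attr = explain(model, fm).set_index("feature")
        assert attr.loc["constant", "attribution"] == 0.0
        assert attr.loc["signal", "attribution"] > 0.0


class TestProgressiveCurve:
    def test_rise_plateau_decline_with_noise_features(self):
        fm, ranking = make_feature_bench(seed=1)
        curve, optimal, test_scores = e.progressive_feature_curve(
            fm, ranking=ranking, seed=1)
        f1 = np.array([v for _, v in curve])
        assert len(curve) == fm.n_features
        assert f1.max() >= f1[0] + 0.05  # rises beyond the first feature
        assert f1[-5:].mean() <= f1.max() - 0.01  # declines under noise
        assert 1 <= optimal.n_features <= fm.n_features
        assert 0 <= test_scores["f1"] <= 1

    def test_optimum_is_smallest_count_at_max(self):
        fm, ranking = make_feature_bench(seed=2, n_noise=6)
        curve, optimal, _ = e.progressive_feature_curve(fm, ranking=ranking,
                                                        seed=2)
        best = max(v for _, v in curve)
        ks_at_best = [k for k, v in curve if v >= best - 1e-12]
        assert optimal.n_features == min(ks_at_best)

    def test_single_feature_gives_length_one_curve(self):
        fm, _ = make_feature_bench(seed=3, n_sig=1, n_noise=0)
        curve, optimal, _ = e.progressive_feature_curve(
            fm, ranking=["sig0"], seed=3)
        assert len(curve) == 1
        assert optimal.n_features == 1

    def test_incomplete_ranking_rejected(self):
        fm, ranking = make_feature_bench(seed=4, n_noise=2)
        with pytest.raises(ValueError, match="ranking"):
            e.progressive_feature_curve(fm, ranking=ranking[:-1], seed=4)
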