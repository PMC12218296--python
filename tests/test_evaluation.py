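"""Metrics, table inversion, curves, cross-validation and t-SNE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgattgr.evaluation import (
    ConfusionMatrix,
    confusion,
    metrics_from_cm,
    minority_class,
    recover_cm_from_rates,
    roc_pr_curves,
    run_cv,
    score_report,
    tsne_plot,
)
from bgattgr.pipeline import BGATTGRPipeline


class TestConfusion:
    def test_perfect_predictions(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 0, 0], positive_class=1)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 0, 2, 0)

    def test_all_negative_predictions(self):
        cm = confusion([1, 1, 0], [0, 0, 0], positive_class=1)
        assert cm.tp == 0 and cm.fp == 0 and cm.fn == 2 and cm.tn == 1

    def test_flipping_positive_class_swaps_cells(self):
        y = [1, 1, 0, 0, 0]
        p = [1, 0, 0, 1, 0]
        a = confusion(y, p, positive_class=1)
        b = confusion(y, p, positive_class=0)
        assert (a.tp, a.tn) == (b.tn, b.tp)
        assert (a.fn, a.fp) == (b.fp, b.fn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1], positive_class=1)


class TestMetrics:
    def test_headline_independent_row(self):
        """SN .964 / SP .951 on a 55/263 test set: the recovered confusion
        matrix (53,2,250,13) must give BACC .957, MCC .853, F1 .876."""
        rep = metrics_from_cm(ConfusionMatrix(tp=53, fn=2, tn=250, fp=13))
        assert round(rep.sn, 3) == 0.964
        assert round(rep.sp, 3) == 0.951
        assert round(rep.bacc, 3) == 0.957
        assert round(rep.mcc, 3) == 0.853
        assert round(rep.f1, 3) == 0.876

    def test_undersampling_only_independent_row(self):
        rep = metrics_from_cm(ConfusionMatrix(tp=53, fn=2, tn=205, fp=58))
        assert round(rep.f1, 3) == 0.639
        assert round(rep.mcc, 3) == 0.590

    def test_degenerate_cells_use_zero_convention(self):
        rep = metrics_from_cm(ConfusionMatrix(tp=0, fn=0, tn=5, fp=0))
        assert rep.mcc == 0.0 and rep.sn == 0.0 and rep.f1 == 0.0

    @given(
        st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    )
    @settings(max_examples=100, deadline=None)
    def test_bacc_identity_holds_exactly(self, tp, fn, tn, fp):
        rep = metrics_from_cm(ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp))
        assert rep.bacc == (rep.sn + rep.sp) / 2

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_mcc_invariant_under_class_swap(self, tp, fn, tn, fp):
        a = metrics_from_cm(ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp))
        b = metrics_from_cm(ConfusionMatrix(tp=tn, fn=fp, tn=tp, fp=fn))
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)
        assert (a.sn, a.sp) == (b.sp, b.sn)


class TestRecoverCm:
    def test_headline_row_is_unique(self):
        cm = recover_cm_from_rates(0.964, 0.951, 55, 263)
        assert isinstance(cm, ConfusionMatrix)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (53, 2, 250, 13)

    def test_perfect_sensitivity_row(self):
        cm = recover_cm_from_rates(1.000, 0.905, 55, 263)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (55, 0, 238, 25)

    def test_trivial_perfect_case(self):
        cm = recover_cm_from_rates(1.0, 1.0, 10, 10)
        assert cm.tp == 10 and cm.tn == 10

    def test_impossible_rates_flag_inconsistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            recover_cm_from_rates(0.1234, 0.5, 10, 10)

    def test_ambiguous_rates_return_all_matches(self):
        # at 1 decimal, several tp values round to 0.5 on 55 positives
        matches = recover_cm_from_rates(0.5, 1.0, 55, 10, decimals=1)
        assert isinstance(matches, list) and len(matches) > 1


class TestCurves:
    def test_perfect_separation(self):
        auc, aupr, roc, pr = roc_pr_curves([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1)
        assert auc == 1.0 and aupr == 1.0

    def test_random_scores_near_chance(self, rng):
        n = 2000
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        scores = rng.uniform(size=n)
        auc, aupr, _, _ = roc_pr_curves(scores, y, 1)
        assert auc == pytest.approx(0.5, abs=0.05)
        assert aupr == pytest.approx(0.5, abs=0.05)  # prevalence of balanced data

    def test_four_point_toy_matches_mann_whitney_oracle(self):
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        labels = np.array([1, 0, 1, 0])
        auc, _, _, _ = roc_pr_curves(scores, labels, 1)
        # Mann-Whitney: fraction of (pos, neg) pairs ranked correctly
        pos, neg = scores[labels == 1], scores[labels == 0]
        pairs = [(p > q) + 0.5 * (p == q) for p in pos for q in neg]
        assert auc == pytest.approx(np.mean(pairs), abs=1e-12)
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves([0.5, 0.6], [1, 1], 1)


class TestScoreReport:
    def test_report_fields_consistent(self, rng):
        y = np.array(["a"] * 30 + ["b"] * 10)
        scores = np.where(y == "b", 0.9, 0.1) + rng.normal(0, 0.05, size=40)
        rep = score_report(y, np.clip(scores, 0, 1), positive_class="b")
        assert rep.bacc == (rep.sn + rep.sp) / 2
        assert rep.cm.n_pos == 10 and rep.cm.n_neg == 30
        assert rep.auc > 0.9 and rep.aupr > 0.8

    def test_minority_class_helper(self):
        assert minority_class(["x"] * 5 + ["y"] * 2) == "y"


def tiny_pipeline():
    return BGATTGRPipeline(
        use_bgatt=False, use_pca=False, p=0.5, k=3,
        classifier="ET", classifier_params={"n_estimators": 30}, random_state=0,
    )


class TestRunCv:
    def make_data(self, rng, n_maj=80, n_min=20, width=10):
        X = rng.normal(size=(n_maj + n_min, width))
        y = np.array(["maj"] * n_maj + ["min"] * n_min)
        X[y == "min", 0] += 3.0
        return X, y

    def test_deterministic_under_seed(self, rng):
        X, y = self.make_data(rng)
        pipe = tiny_pipeline()
        a, _ = run_cv(pipe, X, y, folds=3, seed=4)
        b, _ = run_cv(pipe, X, y, folds=3, seed=4)
        assert a.to_dict() == b.to_dict()

    def test_two_folds_report_per_fold(self, rng):
        X, y = self.make_data(rng, 20, 20)
        mean_rep, fold_reps = run_cv(tiny_pipeline(), X, y, folds=2, seed=0)
        assert len(fold_reps) == 2
        assert mean_rep.mode == "cv_mean_safe"
        assert mean_rep.bacc == pytest.approx(np.mean([r.bacc for r in fold_reps]))

    def test_paper_mode_balances_before_folding(self, rng):
        X, y = self.make_data(rng)
        rep, folds = run_cv(tiny_pipeline(), X, y, folds=3, seed=1, mode="paper")
        assert rep.mode == "cv_mean_paper"
        # balanced once at p=0.5: per-class 50, so folds see ~33 rows each
        assert sum(r.cm.n_pos + r.cm.n_neg for r in folds) == 100

    def test_invalid_mode_rejected(self, rng):
        X, y = self.make_data(rng)
        with pytest.raises(ValueError):
            run_cv(tiny_pipeline(), X, y, folds=2, seed=0, mode="bogus")


class TestTsne:
    def test_separated_blobs_stay_separated(self, rng):
        X = np.vstack([rng.normal(0, 1, (60, 10)), rng.normal(8, 1, (60, 10))])
        y = np.array([0] * 60 + [1] * 60)
        coords = tsne_plot(X, y, perplexity=10, seed=0)
        assert coords.shape == (120, 2)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(coords, y) > 0.5

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(80, 5))
        y = np.array([0, 1] * 40)
        a = tsne_plot(X, y, perplexity=10, seed=3)
        b = tsne_plot(X, y, perplexity=10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_plot(rng.normal(size=(20, 4)), np.zeros(20), perplexity=10)

    def test_plot_file_written(self, rng, tmp_path):
        X = rng.normal(size=(70, 4))
        y = np.array(["active"] * 50 + ["inactive"] * 20)
        out = tmp_path / "tsne.png"
        tsne_plot(X, y, perplexity=5, seed=0, path=out)
        assert out.exists() and out.stat().st_size > 0
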