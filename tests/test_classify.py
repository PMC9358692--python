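"""Median binarization, the logistic-unit network, and ROC evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netprop import (
    SynthConfig,
    binarize_by_median,
    evaluate_roc,
    fit_nn_classifier,
    synth_expression,
    synth_network,
)
from netprop.classify import delong_auc_ci, BinaryPatternClassifier

from conftest import make_study


def panel_frame(genes, directions):
    return pd.DataFrame({"symbol": genes, "direction": directions,
                         "origin": "validated"})


class TestBinarizeByMedian:
    def _study(self):
        values = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],   # median 2.5
                [1.0, 2.0, 3.0, 4.0],
                [7.0, 7.0, 7.0, 7.0],   # constant
            ]
        )
        return make_study(values, n_case=2, genes=["up_g", "down_g", "const_g"])

    def test_up_rule_is_at_or_above_median(self):
        study = self._study()
        bm = binarize_by_median(study, panel_frame(["up_g"], ["up"]))
        assert bm.values.loc["up_g"].tolist() == [0, 0, 1, 1]

    def test_up_gene_exactly_at_median_scores_one(self):
        values = np.array([[1.0, 2.0, 2.0, 5.0]])
        study = make_study(values, n_case=2, genes=["g"])
        bm = binarize_by_median(study, panel_frame(["g"], ["up"]))
        # median is 2; the two samples at the median score 1
        assert bm.values.loc["g"].tolist() == [0, 1, 1, 1]

    def test_down_rule_reverses_comparison(self):
        study = self._study()
        bm = binarize_by_median(study, panel_frame(["down_g"], ["down"]))
        assert bm.values.loc["down_g"].tolist() == [1, 1, 0, 0]

    def test_constant_gene_is_all_ones_under_either_rule(self):
        study = self._study()
        for direction in ("up", "down"):
            bm = binarize_by_median(study, panel_frame(["const_g"], [direction]))
            assert (bm.values.loc["const_g"] == 1).all()

    def test_missing_gene_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            binarize_by_median(self._study(), panel_frame(["absent"], ["up"]))


class TestFitNnClassifier:
    def test_separable_feature_reaches_perfect_training_accuracy(self):
        values = np.array([[9.0] * 10 + [1.0] * 10])
        study = make_study(values, n_case=10, genes=["g"])
        bm = binarize_by_median(study, panel_frame(["g"], ["up"]))
        model = fit_nn_classifier(bm, study.labels, hidden=5, rng_seed=0)
        X = bm.values.to_numpy().T
        y = (study.labels == "case").astype(int).to_numpy()
        assert (model.predict(X) == y).all()

    def test_hidden_layer_width_recorded(self):
        values = np.array([[9.0] * 10 + [1.0] * 10, [1.0] * 10 + [9.0] * 10])
        study = make_study(values, n_case=10, genes=["a", "b"])
        bm = binarize_by_median(study, panel_frame(["a", "b"], ["up", "down"]))
        model = fit_nn_classifier(bm, study.labels, hidden=5, rng_seed=0)
        assert model.hidden == 5
        assert model.mlp_.coefs_[0].shape == (2, 5)
        assert model.mlp_.activation == "logistic"

    def test_label_independent_features_give_chance_auc(self):
        # a net trained on noise must score fresh noise at chance level;
        # the flexible net overfits its own training noise, so the null
        # check is on an independent draw
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            train = make_study(rng.normal(8, 1, size=(4, 60)), n_case=30)
            fresh = make_study(rng.normal(8, 1, size=(4, 60)), n_case=30)
            directions = ["up"] * 4
            bm_train = binarize_by_median(train, panel_frame(train.gene_ids,
                                                             directions))
            model = fit_nn_classifier(bm_train, train.labels, hidden=5,
                                      rng_seed=seed)
            bm_fresh = binarize_by_median(fresh, panel_frame(fresh.gene_ids,
                                                             directions))
            aucs.append(evaluate_roc(model, bm_fresh, fresh.labels).auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_single_class_rejected(self):
        study = make_study(np.ones((1, 6)), n_case=3, genes=["g"])
        study.labels[:] = "control"
        bm = binarize_by_median(study, panel_frame(["g"], ["up"]))
        with pytest.raises(ValueError):
            fit_nn_classifier(bm, study.labels)


class TestDelongAuc:
    def test_perfect_separation(self):
        auc, lo, hi = delong_auc_ci(np.array([0.9, 0.8, 0.2, 0.1]),
                                    np.array([1, 1, 0, 0]))
        assert auc == 1.0 and hi == 1.0

    def test_perfectly_reversed_scores(self):
        auc, _, _ = delong_auc_ci(np.array([0.1, 0.2, 0.8, 0.9]),
                                  np.array([1, 1, 0, 0]))
        assert auc == 0.0

    def test_matches_exhaustive_pair_counting(self):
        scores = np.array([0.9, 0.6, 0.6, 0.2, 0.8, 0.6, 0.3, 0.1])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        pos, neg = scores[y == 1], scores[y == 0]
        concordant = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        auc, _, _ = delong_auc_ci(scores, y)
        assert auc == pytest.approx(concordant / 16)

    def test_agrees_with_rank_based_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.random(40).round(1)  # rounding forces ties
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 1, 0
        auc, lo, hi = delong_auc_ci(scores, y)
        assert auc == pytest.approx(roc_auc_score(y, scores))
        assert 0.0 <= lo <= auc <= hi <= 1.0

    @given(
        shift=st.floats(min_value=0.1, max_value=5.0),
        scale=st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_strictly_monotone_transforms(self, shift, scale):
        rng = np.random.default_rng(9)
        scores = rng.random(30)
        y = np.array([1, 0] * 15)
        base, _, _ = delong_auc_ci(scores, y)
        transformed, _, _ = delong_auc_ci(np.exp(scale * scores) + shift, y)
        assert transformed == pytest.approx(base)


class TestEvaluateRoc:
    def test_identical_scores_fall_back_to_half(self, caplog):
        study = make_study(np.full((1, 8), 3.0), n_case=4, genes=["g"])
        bm = binarize_by_median(study, panel_frame(["g"], ["up"]))
        model = fit_nn_classifier(bm, study.labels, rng_seed=0)
        with caplog.at_level("WARNING", logger="netprop.classify"):
            roc = evaluate_roc(model, bm, study.labels)
        assert (roc.auc, roc.ci_low, roc.ci_high) == (0.5, 0.5, 0.5)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(2)
        values = rng.normal(8, 1, size=(2, 40))
        values[0, :20] += 2.0
        study = make_study(values, n_case=20, genes=["a", "b"])
        bm = binarize_by_median(study, panel_frame(["a", "b"], ["up", "up"]))
        model = fit_nn_classifier(bm, study.labels, rng_seed=0)
        roc = evaluate_roc(model, bm, study.labels)
        assert roc.ci_low <= roc.auc <= roc.ci_high
        assert roc.n_case == 20 and roc.n_control == 20


class TestTransferProtocol:
    def test_model_transfers_to_cohort_binarized_with_its_own_medians(self):
        """Train on one synthetic cohort, evaluate on the held-out cohort
        binarized against its own medians; the shared planted signal keeps
        transfer AUC high."""
        aucs = []
        for seed in range(1, 6):
            cfg = SynthConfig(rng_seed=seed, n_nodes=300, module_size=20,
                              n_seed_genes=5)
            _, _, truth = synth_network(cfg)
            studies, truth = synth_expression(cfg, truth)
            pair = list(truth.informative_pair)
            panel = panel_frame(pair, [truth.de_directions[g] for g in pair])
            train, test = studies[0], studies[2]
            bm_train = binarize_by_median(train, panel)
            model = fit_nn_classifier(bm_train, train.labels, rng_seed=0)
            bm_test = binarize_by_median(test, panel)  # test's own medians
            aucs.append(evaluate_roc(model, bm_test, test.labels).auc)
        assert np.mean(aucs) >= 0.85
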