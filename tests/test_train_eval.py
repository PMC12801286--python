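"""Training protocol and evaluation statistics, each against an independent
oracle on small instances."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from tlsview.train_eval import (
    FoldSplit,
    ModelSpec,
    auroc,
    bootstrap_auroc_ci,
    delong_compare,
    eer_threshold,
    ensemble_predict,
    km_curve,
    logrank,
    run_cv,
    stratify,
    train_fold,
    weighted_ce_loss,
)


class TestWeightedCE:
    def test_perfect_predictions_zero_loss(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert weighted_ce_loss(probs, [0, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_single_relapse_at_half_probability(self):
        # one relapse sample with p=0.5 -> 1.2 * ln 2
        assert weighted_ce_loss(np.array([0.5]), [1]) == pytest.approx(
            1.2 * np.log(2))

    def test_relapse_weight_recovered_at_one_over_e(self):
        # p(relapse)=1/e makes -log p = 1, so the loss equals the class weight
        loss = weighted_ce_loss(np.array([np.exp(-1.0)]), [1])
        assert loss == pytest.approx(1.2, abs=1e-12)

    def test_unit_weights_reduce_to_plain_cross_entropy(self, rng):
        p = rng.uniform(0.05, 0.95, size=20)
        y = rng.integers(0, 2, size=20)
        got = weighted_ce_loss(p, y, w0=1.0, w1=1.0)
        expected = -np.mean(np.where(y == 1, np.log(p), np.log(1 - p)))
        assert got == pytest.approx(expected)

    def test_zero_probability_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            loss = weighted_ce_loss(np.array([0.0]), [1])
        assert np.isfinite(loss)


def tiny_cohort(n=30, seed=0, d_spatial=12):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 3 == 0).astype(int)
    spatial = rng.normal(size=(n, d_spatial)) + 1.5 * y[:, None]
    centers = rng.normal(size=(n, 7, 4))
    clinical = rng.normal(size=(n, 14))
    ids = [f"c{i:03d}" for i in range(n)]
    return ids, y, spatial, centers, clinical


FAST_SPEC = ModelSpec("spb", d_spatial=12, epochs=30, pretrain_epochs=0)


class TestRunCV:
    def test_every_case_predicted_exactly_once(self):
        ids, y, s, c, cl = tiny_cohort()
        cv = run_cv(ids, y, s, c, cl, FAST_SPEC, seed=1)
        assert not np.isnan(cv.oof_probs).any()
        assert sorted(x for f in cv.split.folds for x in f) == sorted(ids)
        assert (cv.oof_fold >= 0).all()

    def test_reproducible_under_fixed_seed(self):
        ids, y, s, c, cl = tiny_cohort()
        cv1 = run_cv(ids, y, s, c, cl, FAST_SPEC, seed=3)
        cv2 = run_cv(ids, y, s, c, cl, FAST_SPEC, seed=3)
        assert np.array_equal(cv1.oof_probs, cv2.oof_probs)
        assert cv1.split.folds == cv2.split.folds

    def test_fold_sizes_balanced(self):
        ids, y, s, c, cl = tiny_cohort(33)
        split = FoldSplit.stratified(ids, y, seed=0)
        sizes = sorted(len(f) for f in split.folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_too_small_cohort_rejected(self):
        ids, y, s, c, cl = tiny_cohort(9)
        with pytest.raises(ValueError):
            run_cv(ids, y, s, c, cl, FAST_SPEC, seed=0)

    def test_no_leakage_from_held_out_labels(self):
        # permuting held-out-fold labels must leave trained weights identical
        ids, y, s, c, cl = tiny_cohort(25)
        split = FoldSplit.stratified(ids, y, seed=0)
        test_ids = set(split.folds[0])
        y2 = y.copy()
        test_idx = [i for i, cid in enumerate(ids) if cid in test_ids]
        y2[test_idx] = 1 - y2[test_idx]
        train_mask = np.array([cid not in test_ids for cid in ids])
        m1 = train_fold(FAST_SPEC, s[train_mask], c[train_mask], cl[train_mask],
                        y[train_mask], seed=5)
        m2 = train_fold(FAST_SPEC, s[train_mask], c[train_mask], cl[train_mask],
                        y2[train_mask], seed=5)
        for k, v in m1.net.state_dict().items():
            assert np.array_equal(v, m2.net.state_dict()[k])

    def test_lr_trace_follows_inverse_time_decay(self):
        ids, y, s, c, cl = tiny_cohort()
        tm = train_fold(FAST_SPEC, s, c, cl, y, seed=0)
        epochs = np.arange(FAST_SPEC.epochs)
        expected = FAST_SPEC.lr0 / (1 + FAST_SPEC.decay * epochs)
        assert np.allclose(tm.lr_trace, expected)


class TestEnsemble:
    def test_mean_of_probabilities(self, rng):
        ids, y, s, c, cl = tiny_cohort()
        cv = run_cv(ids, y, s, c, cl, FAST_SPEC, seed=1)
        ens = ensemble_predict(cv.models, s, c, cl)
        per_model = np.stack([m.predict_proba(s, c, cl) for m in cv.models])
        assert np.allclose(ens, per_model.mean(axis=0))
        ens2 = ensemble_predict(cv.models[::-1], s, c, cl)
        assert np.allclose(ens, ens2)

    def test_five_models_required(self):
        with pytest.raises(ValueError):
            ensemble_predict([], np.zeros((1, 12)))

    def test_known_mean(self):
        class Fake:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, *a):
                return np.array([self.p])

        models = [Fake(p) for p in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert ensemble_predict(models, np.zeros((1, 2)))[0] == pytest.approx(0.6)


def eer_sweep_oracle(probs, labels):
    cands = np.append(np.unique(probs), np.inf)
    best_t, best_gap = None, np.inf
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    for t in cands:
        pred = probs >= t
        fpr = (pred & (labels == 0)).sum() / n0
        fnr = (~pred & (labels == 1)).sum() / n1
        if abs(fpr - fnr) < best_gap - 1e-15:
            best_gap, best_t = abs(fpr - fnr), t
    return best_t


class TestEER:
    def test_perfectly_separated_scores(self):
        probs = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1])
        t = eer_threshold(probs, labels)
        assert t == eer_sweep_oracle(probs, labels)
        pred = probs >= t
        assert ((pred == 1) == labels.astype(bool)).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_sweep(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random(40)
        labels = rng.integers(0, 2, 40)
        if len(set(labels.tolist())) < 2:
            labels[0] = 1 - labels[0]
        assert eer_threshold(probs, labels) == eer_sweep_oracle(probs, labels)
        flipped = 1 - labels
        assert eer_threshold(probs, flipped) == eer_sweep_oracle(probs, flipped)

    def test_degenerate_equal_probabilities(self):
        with pytest.warns(UserWarning):
            t = eer_threshold(np.full(6, 0.4), np.array([0, 1, 0, 1, 0, 1]))
        assert t == 0.4

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            eer_threshold(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_stratify_consistency(self):
        preds = stratify(["a", "b"], np.array([0.2, 0.8]), 0.5)
        assert [p.risk_class for p in preds] == [0, 1]


class TestAUROC:
    def test_perfect_ranking(self):
        assert auroc(np.array([0.1, 0.9, 0.8, 0.2]), np.array([0, 1, 1, 0])) == 1.0

    def test_all_ties_give_half(self):
        assert auroc(np.full(8, 0.3), np.array([0, 1] * 4)) == 0.5

    def test_matches_all_pairs_oracle_and_sklearn(self, rng):
        probs = rng.choice([0.1, 0.3, 0.5, 0.7], size=30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        pos = probs[labels == 1]
        neg = probs[labels == 0]
        pairs = sum((1.0 if p > q else 0.5 if p == q else 0.0)
                    for p in pos for q in neg)
        expected = pairs / (len(pos) * len(neg))
        assert auroc(probs, labels) == pytest.approx(expected)
        assert auroc(probs, labels) == pytest.approx(roc_auc_score(labels, probs))

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        probs = rng.random(60)
        labels = (probs + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        a, lo, hi = bootstrap_auroc_ci(probs, labels, n_boot=200, seed=0)
        assert lo <= a <= hi


class TestDeLong:
    def test_identical_classifiers(self, rng):
        probs = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        res = delong_compare(probs, probs, labels)
        assert res["z"] == 0.0
        assert res["p"] == 1.0

    def test_antisymmetry(self, rng):
        a = rng.random(40)
        b = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        r1 = delong_compare(a, b, labels)
        r2 = delong_compare(b, a, labels)
        assert r1["z"] == pytest.approx(-r2["z"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_variance_close_to_jackknife(self):
        rng = np.random.default_rng(7)
        n = 200
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        probs = np.clip(0.5 * labels + rng.normal(0, 0.35, n), 0, 1)
        res = delong_compare(probs, rng.random(n), labels)
        # jackknife variance oracle for the AUROC of model A
        theta = auroc(probs, labels)
        loo = np.array([
            auroc(np.delete(probs, i), np.delete(labels, i)) for i in range(n)
        ])
        jack = (n - 1) / n * ((loo - loo.mean()) ** 2).sum()
        assert res["var_a"] == pytest.approx(jack, rel=0.10)


class TestSurvival:
    def test_no_events_survival_stays_one(self):
        t, s = km_curve(np.array([5.0, 10.0, 15.0]), np.array([0, 0, 0]))
        assert np.allclose(s, 1.0)

    def test_identical_groups_logrank_null(self):
        times = np.array([3.0, 5.0, 8.0, 3.0, 5.0, 8.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        group = np.array([0, 0, 0, 1, 1, 1])
        chi2, p = logrank(times, events, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        # group 0: events at 1, 2; censored 4.  group 1: events at 3, 5; censored 6.
        times = np.array([1.0, 2.0, 4.0, 3.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        group = np.array([0, 0, 0, 1, 1, 1])
        # hand tabulation of observed - expected for group 1 and its variance
        # t=1: at risk 3/3, d=1 (g0): e1 = 3/6,   v = (1*3*3*5)/(36*5) = 0.25
        # t=2: at risk 2/3, d=1 (g0): e1 = 3/5,   v = (1*2*3*4)/(25*4) = 0.24
        # t=3: at risk 1/3, d=1 (g1): e1 = 3/4,   v = (1*1*3*3)/(16*3) = 0.1875
        # t=5: at risk 0/2, d=1 (g1): e1 = 1,     v = 0
        o_minus_e = (0 - 0.5) + (0 - 0.6) + (1 - 0.75) + (1 - 1.0)
        var = 0.25 + 0.24 + 0.1875 + 0.0
        expected_chi2 = o_minus_e**2 / var
        chi2, p = logrank(times, events, group)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-6)

    def test_km_matches_hand_product_limit(self):
        times = np.array([2.0, 4.0, 4.0, 6.0])
        events = np.array([1, 1, 0, 1])
        t, s = km_curve(times, events)
        # S(2)=3/4; S(4)=3/4*(2/3)=1/2; S(6)=1/2*0=0
        lookup = dict(zip(t, s))
        assert lookup[2.0] == pytest.approx(0.75)
        assert lookup[4.0] == pytest.approx(0.5)
        assert lookup[6.0] == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank(np.array([1.0, 2.0]), np.array([1, 1]), np.array([0, 0]))
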