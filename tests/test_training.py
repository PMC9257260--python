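"""Cross-validation schemes, metrics, training loop contracts, leakage."""

import numpy as np
import pytest

from emoconn.model import DomainAdaptiveRCNN, default_block_channels
from emoconn.preprocessing import LabeledWindows
from emoconn.training import (Metrics, audit_no_leakage, cross_validate,
                              evaluate, make_loso_folds,
                              make_subject_dependent_folds, run_variant,
                              train_fold)

SMALL = dict(n_blocks=1, kernel_size=3, stem_filters=4, block_channels=(4,),
             dense_sizes=(16, 8), dense_activation="relu", disc_hidden=16,
             learning_rate=5e-3, batch_size=32, epochs=15)


def toy_windows(n_subjects=2, n_trials=4, per_trial=6, side=8, shift=2.0, seed=0):
    """Linearly separable matrix dataset with full provenance."""
    rng = np.random.default_rng(seed)
    rows = []
    X, yv, subj, trial, starts = [], [], [], [], []
    for s in range(n_subjects):
        for t in range(n_trials):
            cls = t % 2
            for w in range(per_trial):
                m = rng.standard_normal((side, side)).astype(np.float32)
                m[:4, :4] += shift * (1 if cls else -1)
                X.append(m)
                yv.append(cls)
                subj.append(s)
                trial.append(t)
                starts.append(w * 10)
    X = np.stack(X)
    yv = np.array(yv, dtype=np.int8)
    return X, LabeledWindows(windows=np.zeros((len(X), 1, 2)), y_valence=yv,
                             y_arousal=yv, subject_ids=np.array(subj),
                             trial_ids=np.array(trial), starts=np.array(starts))


class TestMetrics:
    def test_perfect_predictions(self):
        m = evaluate(np.array([0, 1, 1, 0]), np.array([0, 1, 1, 0]))
        assert m.acc == m.sn == m.sp == 1.0

    def test_worked_confusion_example(self):
        # TP=9 FN=1 TN=8 FP=2 -> Sn=0.9 Sp=0.8 Acc=0.85
        y_true = np.r_[np.ones(10), np.zeros(10)]
        y_pred = np.r_[np.ones(9), [0], np.zeros(8), [1, 1]]
        m = evaluate(y_true, y_pred)
        assert (m.sn, m.sp, m.acc) == (0.9, 0.8, 0.85)

    def test_all_positive_predictor_on_balanced_set(self):
        y_true = np.r_[np.ones(5), np.zeros(5)]
        m = evaluate(y_true, np.ones(10))
        assert m.sn == 1.0 and m.sp == 0.0 and m.acc == 0.5

    def test_matches_per_sample_loop_oracle(self, rng):
        for _ in range(200):
            y_true = rng.integers(0, 2, 30)
            y_pred = rng.integers(0, 2, 30)
            m = evaluate(y_true, y_pred)
            tp = sum(1 for a, b in zip(y_true, y_pred) if a == 1 and b == 1)
            tn = sum(1 for a, b in zip(y_true, y_pred) if a == 0 and b == 0)
            assert (m.tp, m.tn) == (tp, tn)
            assert m.acc == pytest.approx((tp + tn) / 30)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([]), np.array([]))


class TestFolds:
    def test_forty_trials_make_ten_folds_of_four(self):
        scheme = make_subject_dependent_folds(np.arange(40), seed=3)
        assert len(scheme.folds) == 10
        assert all(len(f) == 4 for f in scheme.folds)
        union = np.sort(np.concatenate(scheme.folds))
        assert np.array_equal(union, np.arange(40))

    def test_seed_determinism_and_sensitivity(self):
        a = make_subject_dependent_folds(np.arange(40), seed=5)
        b = make_subject_dependent_folds(np.arange(40), seed=5)
        c = make_subject_dependent_folds(np.arange(40), seed=6)
        assert all(np.array_equal(x, y) for x, y in zip(a.folds, b.folds))
        assert any(not np.array_equal(x, y) for x, y in zip(a.folds, c.folds))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            make_subject_dependent_folds(np.arange(8), n_folds=10)

    def test_loso_one_fold_per_subject(self):
        scheme = make_loso_folds(np.repeat(np.arange(32), 3))
        assert len(scheme.folds) == 32

    def test_loso_two_subjects_complementary(self):
        scheme = make_loso_folds(np.array([0, 0, 1, 1]))
        assert [f.tolist() for f in scheme.folds] == [[0], [1]]

    def test_loso_single_subject_rejected(self):
        with pytest.raises(ValueError):
            make_loso_folds(np.zeros(5))


class TestLeakageAudit:
    def test_overlap_detected(self):
        X, lw = toy_windows()
        with pytest.raises(AssertionError):
            audit_no_leakage(lw, np.arange(10), np.arange(5, 15))

    def test_duplicate_provenance_detected(self):
        X, lw = toy_windows()
        lw2 = lw.select(np.r_[np.arange(len(X)), 0])  # window 0 duplicated
        with pytest.raises(AssertionError, match="leakage"):
            audit_no_leakage(lw2, np.array([0]), np.array([len(X)]))

    def test_clean_split_passes(self):
        X, lw = toy_windows()
        train = np.flatnonzero(lw.subject_ids == 0)
        test = np.flatnonzero(lw.subject_ids == 1)
        audit_no_leakage(lw, train, test)

    def test_every_cv_scheme_is_leak_free(self):
        X, lw = toy_windows(n_subjects=3, n_trials=10)
        dep = make_subject_dependent_folds(np.unique(lw.trial_ids), n_folds=5, seed=0)
        loso = make_loso_folds(lw.subject_ids)
        from emoconn.training import _fold_indices
        for scheme, subject in [(dep, 0), (dep, 1), (loso, None)]:
            for fold in scheme.folds:
                tr, te = _fold_indices(lw, scheme, fold, subject=subject)
                audit_no_leakage(lw, tr, te)


class TestTargetLabelsUnread:
    def test_fit_api_has_no_target_label_slot(self):
        """The transductive API accepts target inputs only; corrupting the
        target labels cannot change the fitted model."""
        X, lw = toy_windows()
        tr = np.flatnonzero(lw.subject_ids == 0)
        te = np.flatnonzero(lw.subject_ids == 1)
        m1, _ = train_fold(X, lw, tr, te, domain_adapt=True, model_params=SMALL, seed=0)
        lw_corrupt = lw.select(np.arange(len(X)))
        lw_corrupt.y_valence = lw_corrupt.y_valence.copy()
        lw_corrupt.y_valence[te] = 1 - lw_corrupt.y_valence[te]
        m2, _ = train_fold(X, lw_corrupt, tr, te, domain_adapt=True,
                           model_params=SMALL, seed=0)
        # identical predictions: metrics flip exactly with the flipped truth
        assert m1.tp == m2.fp and m1.tn == m2.fn


class TestTrainingLoop:
    def test_da_off_reduces_to_plain_cross_entropy(self):
        X, lw = toy_windows()
        tr = np.flatnonzero(lw.subject_ids == 0)
        te = np.flatnonzero(lw.subject_ids == 1)
        _, hist = train_fold(X, lw, tr, te, domain_adapt=False, model_params=SMALL, seed=0)
        assert all(h["L_d"] == 0.0 for h in hist)
        assert all(h["L"] == h["L_y"] for h in hist)

    def test_total_objective_identity(self):
        """Every logged step satisfies L = L_y - L_d."""
        X, lw = toy_windows()
        tr = np.flatnonzero(lw.subject_ids == 0)
        te = np.flatnonzero(lw.subject_ids == 1)
        _, hist = train_fold(X, lw, tr, te, domain_adapt=True, model_params=SMALL, seed=0)
        for h in hist:
            assert h["L"] == pytest.approx(h["L_y"] - h["L_d"], abs=1e-6)

    def test_converges_on_separable_data(self):
        """200 linearly separable training matrices reach 100% training
        accuracy well within 200 epochs."""
        X, lw = toy_windows(n_trials=8, per_trial=25, shift=4.0)
        tr = np.flatnonzero(lw.subject_ids == 0)
        assert len(tr) == 200
        clf = DomainAdaptiveRCNN(**{**SMALL, "epochs": 25}, random_state=0)
        clf.fit(X[tr], lw.y_valence[tr])
        assert np.mean(clf.predict(X[tr]) == lw.y_valence[tr]) == 1.0
        assert clf.history_[-1]["L_y"] < 0.1

    def test_identical_seed_identical_history(self):
        X, lw = toy_windows()
        tr = np.flatnonzero(lw.subject_ids == 0)
        te = np.flatnonzero(lw.subject_ids == 1)
        _, h1 = train_fold(X, lw, tr, te, domain_adapt=True, model_params=SMALL, seed=4)
        _, h2 = train_fold(X, lw, tr, te, domain_adapt=True, model_params=SMALL, seed=4)
        assert h1 == h2

    def test_empty_source_rejected(self):
        X, lw = toy_windows()
        with pytest.raises(ValueError):
            train_fold(X, lw, np.array([], dtype=int),
                       np.arange(4), model_params=SMALL)

    def test_domain_adapt_requires_target(self):
        clf = DomainAdaptiveRCNN(domain_adapt=True, **{k: v for k, v in SMALL.items()})
        X, lw = toy_windows()
        with pytest.raises(ValueError, match="X_target"):
            clf.fit(X[:10], lw.y_valence[:10])


class TestEstimatorContract:
    def test_get_set_params_roundtrip(self):
        clf = DomainAdaptiveRCNN(**SMALL)
        params = clf.get_params()
        clone = DomainAdaptiveRCNN().set_params(**params)
        assert clone.get_params() == params

    def test_predict_proba_rows_sum_to_one(self):
        X, lw = toy_windows()
        clf = DomainAdaptiveRCNN(**SMALL, epochs=2) if "epochs" not in SMALL else \
            DomainAdaptiveRCNN(**{**SMALL, "epochs": 2})
        clf.fit(X[:20], lw.y_valence[:20])
        p = clf.predict_proba(X[:5])
        assert np.allclose(p.sum(axis=1), 1.0)
        assert set(clf.predict(X[:5])) <= set(clf.classes_)

    def test_default_block_channels(self):
        assert default_block_channels(3) == (32, 64, 128)
        assert default_block_channels(5) == (32, 64, 128, 128, 128)
        assert default_block_channels(2, stem_filters=8) == (8, 8)

    def test_mismatched_block_channels_rejected(self):
        X, lw = toy_windows()
        clf = DomainAdaptiveRCNN(**{**SMALL, "n_blocks": 2})
        with pytest.raises(ValueError, match="blocks"):
            clf.fit(X[:8], lw.y_valence[:8])


class TestRunVariant:
    def test_variant_feature_mapping(self, tiny_dataset):
        _, _, _, lw = tiny_dataset
        sub = lw.select(np.arange(0, len(lw), 4))
        scheme = make_loso_folds(sub.subject_ids)
        cache = {}
        out = run_variant("RCNN", sub, scheme,
                          model_params={**SMALL, "epochs": 2}, feature_cache=cache)
        assert out["feature"] == "psd" and not out["domain_adapt"]
        out2 = run_variant("BC-RCNN", sub, scheme,
                           model_params={**SMALL, "epochs": 2}, feature_cache=cache)
        assert out2["feature"] == "plv" and not out2["domain_adapt"]
        assert ("psd", "plv") in cache and ("connectivity", "plv") in cache
        assert len(out["folds"]) == len(scheme.folds)

    def test_unknown_variant_rejected(self, tiny_dataset):
        _, _, _, lw = tiny_dataset
        with pytest.raises(ValueError, match="variant"):
            run_variant("MLP", lw, make_loso_folds(lw.subject_ids))
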