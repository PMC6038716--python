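"""Cross-validated time-resolved decoding against brute-force oracles."""

import numpy as np
import pytest

from decodem import (
    AnalysisConfig,
    ClassSpec,
    TemporalDecoder,
    decode_first_level,
    kfold_splits,
    load_first_level,
    save_first_level,
    simulate_epochs,
)
from decodem.metrics import score_auc

from conftest import planted_design


class TestKFold:
    def test_four_folds_train_75_percent(self):
        y = np.repeat([0, 1], 50)
        folds = kfold_splits(y, 4, seed=0)
        assert len(folds) == 4
        for tr, te in folds:
            assert len(tr) == 75 and len(te) == 25

    def test_excess_nfolds_degrades_to_leave_one_out(self):
        y = np.repeat([0, 1], 20)
        folds = kfold_splits(y, 1000, seed=0)
        assert len(folds) == 40
        assert all(len(te) == 1 for _, te in folds)

    def test_stratification_exact_on_balanced_labels(self):
        y = np.repeat([0, 1], 50)
        for tr, te in kfold_splits(y, 5, seed=1):
            assert np.sum(y[te] == 0) == 10 and np.sum(y[te] == 1) == 10

    def test_each_trial_tested_exactly_once(self):
        y = np.repeat([0, 1], 30)
        folds = kfold_splits(y, 5, seed=2)
        tested = np.concatenate([te for _, te in folds])
        assert sorted(tested) == list(range(60))
        for tr, te in folds:
            assert set(tr).isdisjoint(te)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError, match="overfit"):
            kfold_splits(np.repeat([0, 1], 10), 1)


def brute_force_cv_decision_values(X, y, folds):
    """Independent closed-form LDA cross-validation oracle (<=3 features).

    Pooled covariance with ddof n-2, w = pinv(S) @ (mu0 - mu1),
    b = -w @ (mu0+mu1)/2, decision value w@x + b.
    """
    dv = np.zeros(len(y))
    for tr, te in folds:
        mu0 = X[tr][y[tr] == 0].mean(axis=0)
        mu1 = X[tr][y[tr] == 1].mean(axis=0)
        cen = np.vstack(
            [X[tr][y[tr] == 0] - mu0, X[tr][y[tr] == 1] - mu1]
        )
        S = cen.T @ cen / (len(tr) - 2)
        w = np.linalg.pinv(S) @ (mu0 - mu1)
        b = -w @ (mu0 + mu1) / 2
        dv[te] = X[te] @ w + b
    return dv


class TestOracleEquivalence:
    def test_cv_decision_values_match_brute_force(self, rng):
        # <= 20 trials, <= 3 features; no shrinkage, no oversampling
        X3 = rng.standard_normal((20, 3, 1))
        X3[:10, :, 0] += 0.5
        y = np.repeat([0, 1], 10)
        folds = kfold_splits(y, 4, seed=9)
        oracle_dv = brute_force_cv_decision_values(X3[:, :, 0], y, folds)
        # recompute with the package's estimator per fold
        from decodem import ShrinkageLDA

        dv = np.zeros(len(y))
        for tr, te in folds:
            m = ShrinkageLDA(shrinkage=0.0).fit(X3[tr, :, 0], y[tr])
            dv[te] = m.decision_function(X3[te, :, 0])
        np.testing.assert_allclose(dv, oracle_dv, atol=1e-10)

    def test_fold_averaged_auc_matches_oracle(self, rng):
        X = rng.standard_normal((20, 2, 1))
        X[:10, 0, 0] += 1.0
        y = np.repeat([0, 1], 10)
        dec = TemporalDecoder(
            nfolds=4, balance_classes=False, shrinkage=0.0, random_state=21,
            compute_patterns=False,
        ).fit(X, y)
        folds = kfold_splits(y, 4, seed=np.random.SeedSequence(21).spawn(2)[0])
        oracle = np.mean(
            [
                score_auc(
                    brute_force_cv_decision_values(X[:, :, 0], y, [f])[f[1]],
                    y[f[1]],
                )
                for f in folds
            ]
        )
        assert dec.scores_[0] == pytest.approx(oracle, abs=1e-12)


class TestTemporalDecoder:
    def test_planted_effect_auc_inside_vs_outside_window(self):
        # essentially noiseless: the effect window is perfectly separable
        design = planted_design(amp=5.0, noise_sd=1e-6, seed=3)
        ep = simulate_epochs(design)
        spec = ClassSpec.from_strings(["1", "2"])
        res = decode_first_level(ep, spec, AnalysisConfig(nfolds=5, seed=4))
        in_window = (ep.times > 100) & (ep.times < 200)
        assert np.all(res.performance[in_window] == 1.0)
        # at realistic noise the Gaussian tail of the component drowns long
        # before the baseline, so pre-stimulus samples sit at chance
        noisy = simulate_epochs(planted_design(amp=5.0, noise_sd=1.0, seed=3))
        res_n = decode_first_level(noisy, spec, AnalysisConfig(nfolds=5, seed=4))
        out_window = noisy.times < -50
        assert np.all(np.abs(res_n.performance[out_window] - 0.5) < 0.35)
        assert np.max(res_n.performance) > 0.9

    def test_shuffled_labels_give_chance(self, rng):
        design = planted_design(amp=2.0, seed=5)
        ep = simulate_epochs(design)
        ep = ep.copy(event_code=rng.permutation(ep.event_code))
        spec = ClassSpec.from_strings(["1", "2"])
        res = decode_first_level(ep, spec, AnalysisConfig(nfolds=5, seed=4))
        assert abs(res.performance.mean() - 0.5) < 0.05

    def test_crossclass_diagonal_equals_diagonal_run(self, planted_epochs):
        spec = ClassSpec.from_strings(["1", "2"])
        diag = decode_first_level(
            planted_epochs, spec, AnalysisConfig(nfolds=4, seed=7)
        )
        tgm = decode_first_level(
            planted_epochs,
            spec,
            AnalysisConfig(nfolds=4, crossclass=True, seed=7),
        )
        np.testing.assert_allclose(
            np.diagonal(tgm.performance), diag.performance, atol=1e-12
        )

    def test_fold_averaging_contract(self, planted_epochs):
        spec = ClassSpec.from_strings(["1", "2"])
        cfg = AnalysisConfig(nfolds=4, seed=7)
        res = decode_first_level(planted_epochs, spec, cfg)
        dec = TemporalDecoder(nfolds=4, random_state=None)
        # documented contract: reported metric is the unweighted mean of
        # per-fold metrics
        X = np.concatenate(
            [
                planted_epochs.data[planted_epochs.event_code == 1],
                planted_epochs.data[planted_epochs.event_code == 2],
            ]
        )
        y = np.repeat([0, 1], 30)
        dec = TemporalDecoder(nfolds=4, random_state=13, compute_patterns=False)
        dec.fit(X, y)
        np.testing.assert_allclose(
            dec.scores_, dec.fold_scores_.mean(axis=0), atol=1e-14
        )

    def test_metric_bounds_and_no_nans(self, planted_epochs):
        spec = ClassSpec.from_strings(["1", "2"])
        for metric in ("auc", "balanced_accuracy", "dprime"):
            res = decode_first_level(
                planted_epochs,
                spec,
                AnalysisConfig(nfolds=4, metric=metric, seed=7),
            )
            assert np.all(np.isfinite(res.performance))
            if metric in ("auc", "balanced_accuracy"):
                assert np.all(res.performance >= 0.0)
                assert np.all(res.performance <= 1.0)

    def test_null_time_points_centered_at_chance(self, rng):
        # pure-noise two-class data: mean AUC over many time points ~ 0.5
        X = rng.standard_normal((60, 4, 200))
        y = np.repeat([0, 1], 30)
        dec = TemporalDecoder(
            nfolds=5, balance_classes=False, random_state=3, compute_patterns=False
        ).fit(X, y)
        se = dec.scores_.std(ddof=1) / np.sqrt(len(dec.scores_))
        assert abs(dec.scores_.mean() - 0.5) < 3 * se + 1e-3

    def test_independent_train_test_mode(self, rng):
        design = planted_design(amp=4.0, seed=6)
        ep_train = simulate_epochs(design, subject_id="train")
        design2 = planted_design(amp=4.0, seed=60)
        ep_test = simulate_epochs(design2, subject_id="test")
        spec = ClassSpec.from_strings(["1", "2"])
        res = decode_first_level(
            ep_train, spec, AnalysisConfig(nfolds=5, seed=1), test_epochs=ep_test
        )
        assert res.settings["n_folds_used"] == 1  # nfolds disregarded
        in_window = (ep_train.times > 100) & (ep_train.times < 200)
        assert res.performance[in_window].mean() > 0.9


class TestFirstLevelIO:
    def test_flr_roundtrip(self, planted_epochs, tmp_path):
        spec = ClassSpec.from_strings(["1", "2"], names=["on", "off"])
        res = decode_first_level(
            planted_epochs, spec, AnalysisConfig(nfolds=4, seed=7)
        )
        path = save_first_level(res, tmp_path / "s01.flr")
        back = load_first_level(path)
        np.testing.assert_allclose(back.performance, res.performance)
        np.testing.assert_allclose(back.class_erps, res.class_erps)
        np.testing.assert_allclose(back.weights, res.weights)
        np.testing.assert_allclose(back.patterns, res.patterns)
        assert back.channels == res.channels
        assert back.settings["class_names"] == ["on", "off"]
        assert back.metric_name == "auc"

    def test_erps_are_balanced_class_means(self, rng):
        # class ERPs must equal per-class means of the undersampled trials
        design = planted_design(amp=3.0, seed=8)
        design.event_counts = {1: 40, 2: 40}
        ep = simulate_epochs(design)
        spec = ClassSpec.from_strings(["1", "2"])
        res = decode_first_level(ep, spec, AnalysisConfig(nfolds=4, seed=7))
        # balanced counts: no undersampling, ERP = plain class means
        np.testing.assert_allclose(
            res.class_erps[0],
            ep.data[ep.event_code == 1].mean(axis=0),
            atol=1e-10,
        )
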