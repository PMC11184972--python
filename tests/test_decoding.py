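"""Vectorization, z-scoring, calibrated SVM, CV schemes, chance statistics."""

import numpy as np
import pytest

from phosdec.decoding import (
    DecoderSettings,
    FeatureMatrix,
    FoldAccuracies,
    compare_to_chance,
    crossval_decode,
    fit_calibrated_decoder,
    random_decoder,
    task_features,
    task_labels,
    vectorize,
    zscore_apply,
    zscore_fit,
)
from phosdec.preprocessing import EpochSet


def _epochs(data, ids=None):
    n = data.shape[0]
    ids = ids if ids is not None else np.array([f"s{i}" for i in range(n)])
    return EpochSet(data=data, fs=100.0,
                    ch_names=[f"c{i}" for i in range(data.shape[1])],
                    stimulus_ids=np.asarray(ids))


def _toy_features(rng, n=120, n_channels=4, n_samples=25, effect=1.5):
    data = rng.standard_normal((n, n_channels, n_samples))
    labels = np.array(["a", "b"])[np.arange(n) % 2]
    data[labels == "b", 1, 5:15] += effect
    return vectorize(_epochs(data), labels)


class TestVectorize:
    def test_channel_major_order(self):
        data = np.arange(6.0).reshape(1, 2, 3)
        fm = vectorize(_epochs(data))
        np.testing.assert_array_equal(fm.X[0], [0, 1, 2, 3, 4, 5])
        assert fm.feature_index(4) == (1, 1)
        assert fm.flat_index(1, 1) == 4

    def test_round_trip(self, rng):
        data = rng.standard_normal((5, 3, 7))
        fm = vectorize(_epochs(data))
        np.testing.assert_array_equal(fm.as_epochs_array(), data)

    def test_feature_count_full_scale(self):
        fm = FeatureMatrix(np.zeros((1, 128 * 1050)), 128, 1050, np.array(["x"]))
        assert fm.X.shape[1] == 134400


class TestZscore:
    def test_train_moments_after_apply(self, rng):
        fm = _toy_features(rng)
        params = zscore_fit(fm)
        z = zscore_apply(params, fm).as_epochs_array()
        for j in range(z.shape[1]):
            pooled = z[:, j, :].ravel()
            assert pooled.mean() == pytest.approx(0.0, abs=1e-10)
            assert pooled.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_offsets_removed(self):
        data = np.random.default_rng(0).standard_normal((10, 2, 5))
        data[:, 0] += 10.0
        data[:, 1] -= 10.0
        fm = vectorize(_epochs(data))
        z = zscore_apply(zscore_fit(fm), fm).as_epochs_array()
        assert abs(z[:, 0].mean()) < 1e-10
        assert abs(z[:, 1].mean()) < 1e-10

    def test_matches_nested_loop_oracle(self, rng):
        data = rng.standard_normal((6, 3, 8))
        fm = vectorize(_epochs(data))
        params = zscore_fit(fm)
        for j in range(3):
            vals = [data[n, j, t] for n in range(6) for t in range(8)]
            mu = sum(vals) / len(vals)
            sd = np.sqrt(sum((v - mu) ** 2 for v in vals) / (len(vals) - 1))
            assert params.mu[j] == pytest.approx(mu, abs=1e-12)
            assert params.sigma[j] == pytest.approx(sd, abs=1e-12)

    def test_zero_variance_channel_named(self):
        data = np.random.default_rng(0).standard_normal((5, 2, 4))
        data[:, 1] = 3.0
        fm = vectorize(_epochs(data))
        with pytest.raises(ValueError, match="c1"):
            zscore_fit(fm)

    def test_params_fit_on_train_only(self, rng):
        fm = _toy_features(rng)
        train, test = fm.select(np.arange(60)), fm.select(np.arange(60, 120))
        params = zscore_fit(train)
        z_test = zscore_apply(params, test).as_epochs_array()
        # test set is not exactly standardized -> proves params came from train
        pooled = z_test[:, 1, :].ravel()
        assert abs(pooled.mean()) > 1e-3


class TestCalibratedDecoder:
    def test_separable_training_accuracy(self, rng):
        fm = _toy_features(rng, effect=8.0)
        decoder = fit_calibrated_decoder(fm)
        assert np.mean(decoder.predict(fm.X) == fm.labels) == 1.0

    def test_probabilities_on_simplex(self, rng):
        fm = _toy_features(rng)
        decoder = fit_calibrated_decoder(fm)
        proba = decoder.predict_proba(fm.X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(proba >= 0)

    def test_single_class_raises(self, rng):
        fm = _toy_features(rng)
        only_a = fm.select(np.flatnonzero(fm.labels == "a"))
        with pytest.raises(ValueError, match="single class"):
            fit_calibrated_decoder(only_a)

    def test_reliability_of_calibration(self, rng):
        """Binned predicted probability tracks empirical accuracy."""
        fm = _toy_features(rng, n=1000, effect=1.2)
        train, test = fm.select(np.arange(500)), fm.select(np.arange(500, 1000))
        params = zscore_fit(train)
        decoder = fit_calibrated_decoder(zscore_apply(params, train))
        proba = decoder.predict_proba(zscore_apply(params, test).X)
        pred_idx = np.argmax(proba, axis=1)
        conf = proba[np.arange(len(proba)), pred_idx]
        correct = decoder.classes[pred_idx] == test.labels
        for lo in (0.5, 0.65, 0.8):
            sel = (conf >= lo) & (conf < lo + 0.15)
            if sel.sum() >= 30:
                assert abs(correct[sel].mean() - conf[sel].mean()) < 0.15


class TestCrossValidation:
    def test_reproducible_under_seed(self, rng):
        fm = _toy_features(rng)
        a = crossval_decode(fm, seed=5).accuracies.accuracies
        b = crossval_decode(fm, seed=5).accuracies.accuracies
        np.testing.assert_array_equal(a, b)

    def test_null_data_near_chance(self):
        g = np.random.default_rng(77)
        fm = _toy_features(g, n=200, effect=0.0)
        run = crossval_decode(fm, seed=1)
        # binomial 95% band around 0.5 for 200 pooled test trials
        assert abs(run.accuracies.mean - 0.5) < 2 * 0.5 / np.sqrt(200)
        rand = random_decoder(run.fold_true_labels, run.classes, seed=2)
        cmp = compare_to_chance(run.accuracies, rand)
        assert cmp.p_value > 0.05

    def test_unbalanced_scheme_selected_and_balances(self, rng):
        data = rng.standard_normal((130, 3, 10))
        labels = np.array(["a"] * 100 + ["b"] * 30)
        data[labels == "b", 0, :] += 2.0
        fm = vectorize(_epochs(data), labels)
        run = crossval_decode(fm, scheme="auto", seed=0)
        assert run.accuracies.scheme == "monte-carlo-resample"
        assert len(run.accuracies.accuracies) == 10
        # each resample tests 10% of 2 * 30 balanced trials
        assert all(s == 6 for s in run.accuracies.fold_test_sizes)

    def test_small_class_raises(self, rng):
        data = rng.standard_normal((14, 2, 5))
        labels = np.array(["a"] * 9 + ["b"] * 5)
        with pytest.raises(ValueError, match="fewer than"):
            crossval_decode(vectorize(_epochs(data), labels))

    def test_no_leakage_from_test_labels(self, rng):
        """Permuting test labels never changes fitted state."""
        from phosdec.decoding import zscore_fit, zscore_apply

        fm = _toy_features(rng)
        train, test = fm.select(np.arange(60)), fm.select(np.arange(60, 120))
        params = zscore_fit(train)
        decoder = fit_calibrated_decoder(zscore_apply(params, train))
        h1 = decoder.state_hash()
        shuffled = FeatureMatrix(test.X, test.n_channels, test.n_samples,
                                 np.random.default_rng(0).permutation(test.labels))
        decoder.predict(zscore_apply(params, shuffled).X)
        assert decoder.state_hash() == h1


class TestTaskLabels:
    def test_excluded_trials_dropped(self, tasks, registry):
        ids = np.array(["block1_r0c0", "vbar5_c2", "block1_r0c4"])
        labels = task_labels(tasks["left_vs_right"], ids)
        assert labels[0] == "left" and labels[1] == "" and labels[2] == "right"

    def test_task_features_filters(self, tasks, rng):
        data = rng.standard_normal((3, 2, 4))
        ep = _epochs(data, ["block1_r0c0", "vbar5_c2", "block1_r0c4"])
        fm = task_features(ep, tasks["left_vs_right"])
        assert fm.X.shape[0] == 2
        assert set(fm.labels) == {"left", "right"}


class TestRandomDecoder:
    def test_binary_expectation(self):
        trues = [np.array(["a", "b"] * 50) for _ in range(10)]
        accs = random_decoder(trues, np.array(["a", "b"]), seed=0).accuracies
        assert abs(accs.mean() - 0.5) < 3 * 0.5 / np.sqrt(100 * 10)

    def test_five_class_expectation(self):
        classes = np.array(list("abcde"))
        trues = [np.tile(classes, 40) for _ in range(10)]
        accs = random_decoder(trues, classes, seed=1).accuracies
        assert abs(accs.mean() - 0.2) < 0.05

    def test_matches_binomial_distribution(self):
        """#correct per fold follows Binomial(n, 1/M)."""
        from scipy import stats as sps

        n, m, reps = 20, 2, 3000
        trues = [np.array(["a", "b"] * (n // 2))] * reps
        accs = random_decoder(trues, np.array(["a", "b"]), seed=3).accuracies
        counts = np.bincount((accs * n).round().astype(int), minlength=n + 1)
        expected = sps.binom.pmf(np.arange(n + 1), n, 1.0 / m) * reps
        keep = expected > 5
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = sps.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.001


class TestChanceComparison:
    def _fa(self, values):
        return FoldAccuracies("t", "s", np.asarray(values, float), "tenfold", 0)

    def test_identical_not_significant(self):
        f = self._fa([0.5] * 10)
        cmp = compare_to_chance(f, f)
        assert cmp.degenerate
        assert cmp.p_value >= 0.5

    def test_clear_separation_exact_p(self):
        cmp = compare_to_chance(self._fa([0.9] * 10), self._fa([0.5] * 10))
        assert cmp.p_value == pytest.approx(1 / 2**10)
        assert cmp.p_value < 0.005

    def test_bonferroni(self):
        cmp = compare_to_chance(self._fa([0.9] * 10), self._fa([0.5] * 10),
                                n_subjects=10)
        assert cmp.p_corrected == pytest.approx(10 / 2**10)
        cmp2 = compare_to_chance(self._fa([0.5] * 10), self._fa([0.9] * 10),
                                 n_subjects=10)
        assert cmp2.p_corrected == 1.0

    def test_mismatched_folds_raise(self):
        with pytest.raises(ValueError):
            compare_to_chance(self._fa([0.5] * 10),
                              FoldAccuracies("t", "s", np.full(9, 0.5), "random", 0))
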