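"""LN and CNN encoding models, windowing, evaluation, hyperparameter search."""

from dataclasses import replace

import numpy as np
import pytest

from retdecode.stimuli import StimulusMovie, generate_white_noise
from retdecode.synthetic_retina import GroundTruthCell, SpikeTrain, simulate_cell
from retdecode.encoding_models import (CNNConfig, DEFAULT_SEARCH_SPACE, LNModel,
                                       TrainTestSplit, build_and_train_cnn,
                                       downsample_to_frames, evaluate, fit_ln,
                                       five_fold_cv, random_search,
                                       sample_config, window_pairs)
from retdecode.encoding_models import _ln_fold_r


@pytest.fixture(scope="module")
def ln_data():
    """Small movie + noiseless LN cell, shared by the model tests."""
    mv = generate_white_noise((12_000, 6, 6), seed=5)
    cell = GroundTruthCell(cell_id="c0", center_um=(180.0, 180.0))
    train = simulate_cell(cell, mv, seed=6)
    return mv, cell, train


class TestSplit:
    def test_default_is_twenty_twenty_sixty(self):
        sp = TrainTestSplit()
        assert sp.discard_fraction == pytest.approx(0.6)
        tr, te = sp.segments(1000)
        assert (tr.start, tr.stop, te.start, te.stop) == (0, 200, 200, 400)

    def test_five_folds_are_equal_fifths(self):
        for fold in range(5):
            tr, te = TrainTestSplit(fold=fold).segments(1000)
            assert tr.stop - tr.start == 200
            assert te.stop - te.start == 200
            assert tr.start == fold * 200

    def test_overfull_split_rejected(self):
        with pytest.raises(ValueError):
            TrainTestSplit(train_fraction=0.7, test_fraction=0.4)


class TestLN:
    def test_filter_recovery_and_monotone_nonlinearity(self, ln_data):
        mv, cell, train = ln_data
        model = fit_ln(mv, train, TrainTestSplit(train_fraction=0.8, test_fraction=0.2))
        w = cell.kernel(mv)
        r = np.corrcoef(model.kernel.ravel(), w.ravel())[0, 1]
        assert r > 0.85
        upper = model.bin_rates[len(model.bin_rates) // 2 :]
        assert np.all(np.diff(upper) >= -1e-9)

    def test_too_few_spikes_refused(self, ln_data):
        mv, _, train = ln_data
        sparse = SpikeTrain(train.times[:50], train.duration)
        with pytest.raises(ValueError, match="spikes"):
            fit_ln(mv, sparse)

    def test_prediction_tracks_true_rate(self, ln_data):
        mv, cell, train = ln_data
        from retdecode.synthetic_retina import filter_drive

        model = fit_ln(mv, train, TrainTestSplit(train_fraction=0.8, test_fraction=0.2))
        pred = model.predict(mv)
        w = cell.kernel(mv)
        true_rate = cell.gain * np.maximum(
            filter_drive(mv.frames - 0.5, w), 0.0) + cell.baseline_rate
        d = 23
        assert np.corrcoef(pred[d:], true_rate[d:])[0, 1] > 0.95
        assert np.all(pred >= 0)

    def test_constant_nonlinearity_gives_constant_trace(self, ln_data):
        mv, cell, _ = ln_data
        model = LNModel(cell.kernel(mv), np.array([0.0, 1.0]),
                        np.array([4.0, 4.0]), 30.0, 0.5)
        pred = model.predict(mv)
        assert np.allclose(pred[23:], 4.0)

    def test_off_twin_on_inverted_movie_predicts_identically(self, ln_data):
        mv, cell, train = ln_data
        model = fit_ln(mv, train, TrainTestSplit(train_fraction=0.8, test_fraction=0.2))
        inverted = StimulusMovie(1.0 - mv.frames, mv.frame_rate, mv.pixel_pitch)
        # the inverted movie's mean is 1 - mean, so the OFF twin centres there
        twin = LNModel(-model.kernel, model.bin_drives, model.bin_rates,
                       model.frame_rate, 1.0 - model.stimulus_mean)
        assert np.allclose(model.predict(mv), twin.predict(inverted), atol=1e-9)

    def test_five_fold_cv_returns_one_row_per_fold(self, ln_data):
        mv, _, train = ln_data
        df = five_fold_cv(mv, train)
        assert list(df["fold"]) == [0, 1, 2, 3, 4]
        assert df["r"].notna().all()


class TestEvaluate:
    def test_identical_traces_give_unity(self):
        x = np.random.default_rng(0).poisson(2.0, 500).astype(float)
        assert evaluate(x, x) == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(1)
        rs = [evaluate(rng.poisson(2.0, 2000).astype(float),
                       rng.poisson(2.0, 2000).astype(float)) for _ in range(5)]
        assert abs(np.mean(rs)) < 0.05

    def test_affine_invariance_of_prediction(self):
        rng = np.random.default_rng(2)
        pred = rng.random(400)
        obs = rng.poisson(3.0, 400).astype(float)
        assert evaluate(pred, obs) == pytest.approx(evaluate(5 * pred + 1, obs))

    def test_zero_variance_trace_is_nan(self):
        assert np.isnan(evaluate(np.ones(100), np.zeros(100)))

    def test_evaluation_r_decreases_with_gaussian_sigma_mismatch(self):
        # sanity on the broadening path: sigma=0 equals plain correlation
        rng = np.random.default_rng(3)
        a, b = rng.random(300), rng.random(300)
        assert evaluate(a, b, sigma_frames=1e-9) == pytest.approx(
            np.corrcoef(a, b)[0, 1], abs=1e-6)


class TestWindowPairs:
    def test_visual_windows_span_600_ms(self, ln_data):
        mv, _, train = ln_data
        X, Y, times = window_pairs(mv, train, "visual")
        assert X.shape[1] == 20  # frames per window, ~0.65 s at 30 Hz
        assert X.shape[1] / mv.frame_rate == pytest.approx(20 / 30)
        assert X.shape[0] == mv.n_frames - 20
        assert Y.shape == (X.shape[0], 1)
        # target is the spike count in the frame after the window
        assert Y.sum() <= train.n_spikes

    def test_electrical_upsampling_factor(self):
        mv = generate_white_noise((200, 4, 4), frame_rate=20.0, seed=0,
                                  pixel_pitch=70.0, modality="electrical")
        train = SpikeTrain(np.array([5.0]), mv.duration)
        X, Y, times = window_pairs(mv, train, "electrical")
        # 250 Hz / 20 Hz = 12.5 samples per movie frame
        assert np.diff(times)[0] == pytest.approx(1 / 250)
        assert X.shape[1] == round(5 * 12.5)  # 5 frames -> 62 or 63 samples

    def test_downsampling_back_to_frames(self):
        times = np.arange(0.0, 1.0, 1 / 250)
        values = np.ones_like(times)
        out = downsample_to_frames(values, times, 1 / 20)
        assert len(out) == 20
        assert np.allclose(out, 1.0)


@pytest.fixture(scope="module")
def tiny_config():
    return CNNConfig(n_filters1=8, filter_size1=3, n_filters2=8, filter_size2=3,
                     learning_rate=3e-3, l2=1e-5, l1=0.0, batch_size=128,
                     dropout=0.2, epochs=15)


class TestCNN:
    def test_table_default_architectures(self):
        v = CNNConfig.visual_default()
        assert (v.n_filters1, v.filter_size1, v.n_filters2, v.filter_size2) == (8, 13, 16, 9)
        e = CNNConfig.electrical_default()
        assert (e.n_filters1, e.filter_size1, e.n_filters2, e.filter_size2) == (16, 5, 32, 5)

    def test_training_reduces_loss_and_beats_ln(self, ln_data, tiny_config):
        """On LN-generated data the CNN matches or exceeds the LN model."""
        mv, cell, train = ln_data
        X, Y, _ = window_pairs(mv, train, "visual")
        sp = TrainTestSplit()
        tr, te = sp.segments(len(X))
        net = build_and_train_cnn(X[tr], Y[tr], tiny_config, seed=7)
        assert net.loss_history[-1] < net.loss_history[0]
        pred = net.predict(X[te])[:, 0]
        r_cnn = evaluate(pred, Y[te][:, 0])
        r_ln = _ln_fold_r(mv, train, sp, 24)
        assert r_cnn >= r_ln - 0.05
        assert np.all(pred >= 0)

    def test_filter_too_large_for_input_rejected(self, tiny_config):
        X = np.zeros((8, 4, 5, 5))
        Y = np.zeros((8, 1))
        cfg = replace(tiny_config, filter_size1=9, epochs=1)
        with pytest.raises(ValueError):
            build_and_train_cnn(X, Y, cfg, seed=0)


class TestRandomSearch:
    def _data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 4, 8, 8))
        Y = rng.poisson(1.0, size=(120, 1)).astype(float)
        return X[:90], Y[:90], X[90:], Y[90:]

    def test_single_trial_returns_that_config(self):
        Xtr, Ytr, Xte, Yte = self._data()
        cfg, table = random_search(Xtr, Ytr, Xte, Yte, n_trials=1, seed=3, epochs=1)
        assert len(table) == 1
        assert cfg is not None

    def test_thirteen_searchable_hyperparameters_within_bounds(self):
        assert len(CNNConfig.SEARCHABLE) == 13
        rng = np.random.default_rng(1)
        for _ in range(50):
            cfg = sample_config(DEFAULT_SEARCH_SPACE, rng)
            for name, (lo, hi) in DEFAULT_SEARCH_SPACE.items():
                assert lo - 1e-12 <= getattr(cfg, name) <= hi + 1e-12
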