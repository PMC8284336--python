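"""Single-cell encoding models: linear–nonlinear (LN) and CNN.

The LN model is R(s) = N(w . s): the filter ``w`` is the (mean-subtracted)
STA on the training segment, and the static nonlinearity ``N`` maps the
filter drive to a firing rate via quantile-binned empirical averages with
linear interpolation. The CNN stacks two convolution blocks
(conv -> parametric ReLU -> batch norm -> dropout), flattens, and ends in a
dense layer; a softplus keeps rates positive. It is trained with Adam on
the Poisson negative log-likelihood plus L2 on the conv/dense weights and
L1 on the output:

    L = (1/N) sum_i (Rhat_i - R_i log Rhat_i)
        + (alpha/2) sum_j ||W_j||_F^2 + (beta/N) sum_i |Rhat_i|

Recordings use a 20/20/60 train/test/discard split taken as contiguous
blocks from the start (with a five-fold cross-validated variant). Because
the white noise is never repeated, model and data are compared after
broadening both spike trains with a Gaussian of sigma = 2 frames, then
taking the Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._nn import (Adam, BatchNorm, Conv2D, Dense, Dropout, Flatten, PReLU,
                  Sequential, Softplus)
from .stimuli import StimulusMovie
from .synthetic_retina import SpikeTrain, filter_drive
from .receptive_fields import compute_sta

__all__ = [
    "TrainTestSplit",
    "LNModel",
    "CNNConfig",
    "TrainedCNN",
    "fit_ln",
    "window_pairs",
    "build_and_train_cnn",
    "evaluate",
    "five_fold_cv",
    "random_search",
    "DEFAULT_SEARCH_SPACE",
]

VISUAL_WINDOW_FRAMES = 20  # 600 ms at 30 Hz
ELECTRICAL_WINDOW_FRAMES = 5  # 250 ms at 20 Hz
ELECTRICAL_UPSAMPLE_HZ = 250.0


@dataclass
class TrainTestSplit:
    """Contiguous 20/20/60 train/test/discard split of a recording."""

    train_fraction: float = 0.20
    test_fraction: float = 0.20
    fold: int | None = None  # 0..4 selects a five-fold CV fold instead

    def __post_init__(self) -> None:
        if self.train_fraction + self.test_fraction > 1.0 + 1e-9:
            raise ValueError("train + test fractions exceed 1")

    @property
    def discard_fraction(self) -> float:
        return 1.0 - self.train_fraction - self.test_fraction

    def segments(self, n_frames: int) -> tuple[slice, slice]:
        """(train, test) frame slices."""
        if self.fold is None:
            a = int(round(self.train_fraction * n_frames))
            b = int(round((self.train_fraction + self.test_fraction) * n_frames))
            return slice(0, a), slice(a, b)
        edges = np.linspace(0, n_frames, 6).astype(int)
        k = self.fold % 5
        j = (k + 1) % 5
        return slice(edges[k], edges[k + 1]), slice(edges[j], edges[j + 1])


def _frame_counts(train: SpikeTrain, frame_rate: float, n_frames: int) -> np.ndarray:
    idx = np.floor(train.times * frame_rate + 1e-9).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_frames)]
    return np.bincount(idx, minlength=n_frames).astype(np.float64)


def _subtrain(train: SpikeTrain, sl: slice, frame_rate: float) -> SpikeTrain:
    t0, t1 = sl.start / frame_rate, sl.stop / frame_rate
    times = train.times[(train.times >= t0) & (train.times < t1)] - t0
    return SpikeTrain(times, t1 - t0, cell_id=train.cell_id)


@dataclass
class LNModel:
    """Linear filter plus monotone-lookup static nonlinearity."""

    kernel: np.ndarray  # (depth, H, W), mean-subtracted
    bin_drives: np.ndarray  # lookup domain (quantile bin centres)
    bin_rates: np.ndarray  # Hz at each bin centre
    frame_rate: float
    stimulus_mean: float

    @property
    def depth_frames(self) -> int:
        return self.kernel.shape[0]

    def drive(self, stimulus: StimulusMovie) -> np.ndarray:
        return filter_drive(stimulus.frames - self.stimulus_mean, self.kernel)

    def predict(self, stimulus: StimulusMovie) -> np.ndarray:
        """Nonnegative predicted rate (Hz) per frame."""
        if stimulus.n_frames <= self.depth_frames:
            raise ValueError("stimulus shorter than the filter depth")
        rate = np.interp(self.drive(stimulus), self.bin_drives, self.bin_rates)
        return np.maximum(rate, 0.0)


def fit_ln(
    stimulus: StimulusMovie,
    train: SpikeTrain,
    split: TrainTestSplit | None = None,
    depth_frames: int = 24,
    n_bins: int = 25,
    min_spikes: int = 100,
    separable: bool = True,
) -> LNModel:
    """Fit the LN model on the split's training segment.

    The filter is the training-segment STA (stimulus mean subtracted, unit
    L2 norm); with ``separable=True`` (default) it is denoised to its best
    rank-1 space-time separable approximation (top SVD component), the
    standard cleanup for white-noise STAs. The nonlinearity averages
    observed per-frame spike counts in 25 quantile bins of the filter
    drive, linearly interpolated with constant extrapolation beyond the
    outer bins.
    """
    split = split or TrainTestSplit()
    tr, _ = split.segments(stimulus.n_frames)
    sub = _subtrain(train, tr, stimulus.frame_rate)
    if sub.n_spikes < min_spikes:
        raise ValueError(
            f"training segment has {sub.n_spikes} spikes; need >= {min_spikes}"
        )
    sub_movie = StimulusMovie(stimulus.frames[tr], stimulus.frame_rate,
                              stimulus.pixel_pitch, stimulus.modality)
    sta = compute_sta(sub, sub_movie, depth_frames)
    kernel = sta.kernel - sta.stimulus_mean
    if separable:
        M = kernel.reshape(depth_frames, -1)
        U, S, Vt = np.linalg.svd(M, full_matrices=False)
        kernel = (S[0] * np.outer(U[:, 0], Vt[0])).reshape(kernel.shape)
    norm = np.linalg.norm(kernel)
    if norm > 0:
        kernel = kernel / norm
    model = LNModel(kernel, np.array([0.0, 1.0]), np.array([0.0, 0.0]),
                    stimulus.frame_rate, sta.stimulus_mean)
    g = model.drive(sub_movie)[depth_frames - 1 :]
    counts = _frame_counts(sub, stimulus.frame_rate, sub_movie.n_frames)[depth_frames - 1 :]
    edges = np.quantile(g, np.linspace(0, 1, n_bins + 1))
    which = np.clip(np.searchsorted(edges, g, side="right") - 1, 0, n_bins - 1)
    centres, rates = [], []
    for b in range(n_bins):
        sel = which == b
        if np.any(sel):
            centres.append(g[sel].mean())
            rates.append(counts[sel].mean() * stimulus.frame_rate)
    model.bin_drives = np.asarray(centres)
    model.bin_rates = np.asarray(rates)
    return model


def evaluate(
    predicted: np.ndarray,
    observed: np.ndarray | SpikeTrain,
    sigma_frames: float = 2.0,
    frame_rate: float | None = None,
) -> float:
    """Pearson r between Gaussian-broadened prediction and spike counts.

    Both the predicted rate trace and the observed per-frame counts are
    convolved with a Gaussian (sigma in frames, truncated at 4 sigma).
    Returns NaN when either trace has zero variance.
    """
    if isinstance(observed, SpikeTrain):
        if frame_rate is None:
            raise ValueError("frame_rate needed to bin a SpikeTrain")
        observed = _frame_counts(observed, frame_rate, len(predicted))
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("traces must be aligned on the same frame grid")
    a = gaussian_filter1d(predicted, sigma_frames, truncate=4.0)
    b = gaussian_filter1d(observed, sigma_frames, truncate=4.0)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _ln_fold_r(stimulus, train, split, depth_frames, sigma_frames=2.0):
    model = fit_ln(stimulus, train, split, depth_frames)
    _, te = split.segments(stimulus.n_frames)
    test_movie = StimulusMovie(stimulus.frames[te], stimulus.frame_rate,
                               stimulus.pixel_pitch, stimulus.modality)
    pred = model.predict(test_movie)
    obs = _frame_counts(_subtrain(train, te, stimulus.frame_rate),
                        stimulus.frame_rate, test_movie.n_frames)
    d = depth_frames - 1  # drop frames without a full filter window
    return evaluate(pred[d:], obs[d:], sigma_frames)


def five_fold_cv(
    stimulus: StimulusMovie,
    train: SpikeTrain,
    depth_frames: int = 24,
    sigma_frames: float = 2.0,
) -> pd.DataFrame:
    """LN test correlation per fold; the recording is cut into equal fifths."""
    rows = []
    for fold in range(5):
        r = _ln_fold_r(stimulus, train, TrainTestSplit(fold=fold), depth_frames,
                       sigma_frames)
        rows.append({"fold": fold, "model": "ln", "r": r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CNN


@dataclass
class CNNConfig:
    """CNN architecture and training hyperparameters (13 searchable)."""

    n_filters1: int = 8
    filter_size1: int = 13
    stride1: int = 1
    prelu_init1: float = 0.25
    n_filters2: int = 16
    filter_size2: int = 9
    stride2: int = 1
    prelu_init2: float = 0.25
    learning_rate: float = 1e-3
    l2: float = 1e-4  # alpha
    l1: float = 0.0  # beta
    batch_size: int = 128
    dropout: float = 0.5
    epochs: int = 50  # not part of the random search
    bn_momentum: float = 0.5  # not part of the random search

    SEARCHABLE = (
        "n_filters1", "filter_size1", "stride1", "prelu_init1",
        "n_filters2", "filter_size2", "stride2", "prelu_init2",
        "learning_rate", "l2", "l1", "batch_size", "dropout",
    )

    @classmethod
    def visual_default(cls) -> "CNNConfig":
        return cls(n_filters1=8, filter_size1=13, n_filters2=16, filter_size2=9)

    @classmethod
    def electrical_default(cls) -> "CNNConfig":
        return cls(n_filters1=16, filter_size1=5, n_filters2=32, filter_size2=5)


def window_pairs(
    stimulus: StimulusMovie,
    train: SpikeTrain | list[SpikeTrain],
    modality: str | None = None,
    window_frames: int | None = None,
):
    """Sliding stimulus windows and target spike rates for CNN training.

    Visual: windows of 20 consecutive frames (600 ms at 30 Hz); the target
    is the spike count in the single frame (33 ms) following the window.
    Electrical: the movie is up-sampled to 250 Hz by linear interpolation,
    windows span 5 original frames (250 ms) and targets are 4 ms bins at
    250 Hz; validation predictions should be down-sampled back with
    :func:`downsample_to_frames` before scoring.

    Returns ``(X, Y, times)``: ``X`` is (n, window, H, W) float32 centred at
    the stimulus mean, ``Y`` is (n, n_cells) counts, and ``times`` are the
    target bin start times in seconds.
    """
    trains = train if isinstance(train, list) else [train]
    modality = modality or stimulus.modality
    mean = float(stimulus.frames.mean())
    if modality == "visual":
        L = window_frames or VISUAL_WINDOW_FRAMES
        frames = stimulus.frames.astype(np.float32) - mean
        dt = stimulus.dt
        T = stimulus.n_frames
        n = T - L  # window ends at t, target is frame t+1
        from numpy.lib.stride_tricks import sliding_window_view

        X = sliding_window_view(frames, L, axis=0)[:n].transpose(0, 3, 1, 2)
        Y = np.column_stack(
            [_frame_counts(tr, stimulus.frame_rate, T)[L:] for tr in trains]
        )
        times = np.arange(L, T) * dt
        return X, Y, times
    if modality == "electrical":
        L = window_frames or ELECTRICAL_WINDOW_FRAMES
        up_dt = 1.0 / ELECTRICAL_UPSAMPLE_HZ
        t_frames = np.arange(stimulus.n_frames) * stimulus.dt
        t_up = np.arange(0.0, stimulus.duration - stimulus.dt, up_dt)
        ff = stimulus.frames.reshape(stimulus.n_frames, -1)
        up = np.empty((t_up.size, ff.shape[1]), dtype=np.float32)
        for j in range(ff.shape[1]):
            up[:, j] = np.interp(t_up, t_frames, ff[:, j])
        up = up.reshape((t_up.size,) + stimulus.spatial_shape) - mean
        Lw = int(round(L * stimulus.dt * ELECTRICAL_UPSAMPLE_HZ))  # samples/window
        n = t_up.size - Lw
        from numpy.lib.stride_tricks import sliding_window_view

        X = sliding_window_view(up, Lw, axis=0)[:n].transpose(0, 3, 1, 2)
        edges = t_up[Lw:]
        Y = np.column_stack(
            [
                np.histogram(tr.times, bins=np.append(edges, edges[-1] + up_dt))[0]
                for tr in trains
            ]
        ).astype(np.float64)
        return X, Y, edges
    raise ValueError(f"unknown modality: {modality!r}")


def downsample_to_frames(values: np.ndarray, times: np.ndarray, frame_dt: float) -> np.ndarray:
    """Average an up-sampled trace into original-frame bins (electrical path)."""
    frames = np.floor(times / frame_dt + 1e-9).astype(int)
    out = np.bincount(frames, weights=values)
    cnt = np.bincount(frames)
    return out[cnt > 0] / cnt[cnt > 0]


@dataclass
class TrainedCNN:
    model: Sequential
    config: CNNConfig
    loss_history: list
    seed: int | None
    input_shape: tuple

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Predicted rates (counts per target bin), (n, n_cells)."""
        out = [self.model.forward(X[i : i + batch_size], train=False)
               for i in range(0, len(X), batch_size)]
        return np.concatenate(out, axis=0)


def build_and_train_cnn(
    X: np.ndarray,
    Y: np.ndarray,
    config: CNNConfig | None = None,
    seed: int | None = None,
    verbose: bool = False,
) -> TrainedCNN:
    """Train the two-block CNN with Adam on the Poisson loss.

    ``X`` is (n, channels, H, W); ``Y`` is (n, n_cells) spike counts per
    target bin. Raises on NaN loss.
    """
    config = config or CNNConfig()
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, C, H, W = X.shape
    layers = [
        Conv2D(C, config.n_filters1, config.filter_size1, config.stride1, rng),
        PReLU(config.prelu_init1),
        BatchNorm(config.n_filters1, momentum=config.bn_momentum),
        Dropout(config.dropout, rng),
        Conv2D(config.n_filters1, config.n_filters2, config.filter_size2,
               config.stride2, rng),
        PReLU(config.prelu_init2),
        BatchNorm(config.n_filters2, momentum=config.bn_momentum),
        Dropout(config.dropout, rng),
        Flatten(),
    ]
    probe = Sequential(layers).forward(X[:1], train=False)
    layers.append(Dense(probe.shape[1], Y.shape[1], rng))
    layers.append(Softplus())
    model = Sequential(layers)
    opt = Adam(model.params(), lr=config.learning_rate)
    eps = 1e-8
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb = X[sel], Y[sel]
            pred = model.forward(xb, train=True)
            nb = pred.size
            data_loss = np.mean(pred - yb * np.log(pred + eps))
            l1_loss = config.l1 * np.mean(np.abs(pred))
            l2_loss = 0.5 * config.l2 * sum(
                float(np.sum(w * w)) for w in model.weight_matrices()
            )
            loss = data_loss + l1_loss + l2_loss
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}"
                )
            g = (1.0 - yb / (pred + eps)) / nb + config.l1 * np.sign(pred) / nb
            model.backward(g)
            if config.l2 > 0:
                for layer in model.layers:
                    if isinstance(layer, (Conv2D, Dense)):
                        layer.gW += config.l2 * layer.W
            opt.step()
            losses.append(float(loss))
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}  loss {history[-1]:.4f}")
    return TrainedCNN(model, config, history, seed, (C, H, W))


#: bounds for the 13 searchable hyperparameters
DEFAULT_SEARCH_SPACE = {
    "n_filters1": (4, 16),
    "filter_size1": (3, 7),
    "stride1": (1, 2),
    "prelu_init1": (0.05, 0.5),
    "n_filters2": (4, 32),
    "filter_size2": (3, 7),
    "stride2": (1, 2),
    "prelu_init2": (0.05, 0.5),
    "learning_rate": (1e-4, 1e-2),
    "l2": (1e-6, 1e-2),
    "l1": (0.0, 1e-3),
    "batch_size": (32, 256),
    "dropout": (0.0, 0.6),
}

_INT_PARAMS = {"n_filters1", "filter_size1", "stride1", "n_filters2",
               "filter_size2", "stride2", "batch_size"}
_LOG_PARAMS = {"learning_rate", "l2"}


def sample_config(space: dict, rng, epochs: int = 10) -> CNNConfig:
    kwargs = {}
    for name, bounds in space.items():
        lo, hi = bounds
        if name in _LOG_PARAMS and lo > 0:
            val = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            val = float(rng.uniform(lo, hi))
        if name in _INT_PARAMS:
            val = int(round(val))
        kwargs[name] = val
    return CNNConfig(epochs=epochs, **kwargs)


def random_search(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    space: dict | None = None,
    n_trials: int = 10,
    seed: int | None = None,
    epochs: int = 10,
    sigma_frames: float = 2.0,
) -> tuple[CNNConfig, pd.DataFrame]:
    """Random hyperparameter search; best config by test-segment correlation.

    A desk-scale replacement for a 100-trial managed search: each trial
    samples all 13 hyperparameters uniformly (log-uniform for the rates)
    within ``space`` and never leaves the declared bounds.
    """
    space = space or DEFAULT_SEARCH_SPACE
    rng = np.random.default_rng(seed)
    rows = []
    best_cfg, best_r = None, -np.inf
    for trial in range(n_trials):
        cfg = sample_config(space, rng, epochs=epochs)
        try:
            net = build_and_train_cnn(X_train, Y_train, cfg,
                                      seed=int(rng.integers(2**31)))
            pred = net.predict(X_test)
            rs = [evaluate(pred[:, j], Y_test[:, j], sigma_frames)
                  for j in range(Y_test.shape[1])]
            r = float(np.nanmean(rs))
        except (ValueError, FloatingPointError):
            r = -np.inf
        rows.append({"trial": trial, "r": r, **{k: getattr(cfg, k)
                                                for k in CNNConfig.SEARCHABLE}})
        if best_cfg is None or r > best_r:
            best_cfg, best_r = cfg, r
    return best_cfg, pd.DataFrame(rows)
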