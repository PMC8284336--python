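"""Characteristic correlation curves, AUC and noise-ratio matching.

How much of a cell's firing is stimulus-locked? With ``F(i)`` the cropped
stimulus window preceding spike ``i`` (chronological order) and ``N`` total
spikes, the partial STA over the first ``n`` spikes is

    STA(n/N) = (1/n) * sum_{i<=n} F(i)

and the characteristic correlation curve is

    CCC(n/N) = Corr(STA(1), STA(n/N)),     AUC = integral of CCC over n/N,

where STA(1) is the full-spike STA. A perfectly repeatable responder has
CCC identically 1 and AUC = 1; a purely spontaneous cell follows the
pure-noise curve sqrt(n/N). The noise ratio (NR) of a cell is estimated by
injecting noise into a low-noise reference cell at a grid of ratios,
computing the family of (NR, AUC) pairs, and matching the query cell's AUC
into that family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stimuli import StimulusMovie
from .synthetic_retina import SpikeTrain, inject_noise
from .receptive_fields import DEFAULT_CROP, DEFAULT_DEPTH, compute_sta, spike_frame_indices

__all__ = [
    "CCCCurve",
    "NoiseFamily",
    "compute_ccc",
    "compute_auc",
    "select_reference_cell",
    "build_noise_family",
    "match_noise_ratio",
]


@dataclass
class CCCCurve:
    """(normalized spike fraction, correlation) pairs for one cell."""

    fractions: np.ndarray  # n/N, increasing, last entry exactly 1
    correlations: np.ndarray
    n_spikes: int

    def interp(self, grid: np.ndarray) -> np.ndarray:
        ok = np.isfinite(self.correlations)
        return np.interp(grid, self.fractions[ok], self.correlations[ok])


@dataclass
class NoiseFamily:
    """Noise-injected CCC family of a reference cell."""

    nr_grid: np.ndarray  # increasing
    aucs: np.ndarray  # mean AUC per nr (nonincreasing in expectation)
    curves: np.ndarray  # (len(nr_grid), n_grid) mean curves on `fraction_grid`
    fraction_grid: np.ndarray
    reference_id: str | int | None = None
    n_seeds: int = 1


def _cropped_spike_windows(
    train: SpikeTrain, stimulus: StimulusMovie, depth_frames: int, crop_box
) -> np.ndarray:
    """(N, voxels) matrix of the cropped stimulus window before each spike."""
    (f0, f1), (y0, y1), (x0, x1) = crop_box
    T = stimulus.n_frames
    idx = spike_frame_indices(train, stimulus.frame_rate, depth_frames, T)
    crop_frames = stimulus.frames[:, y0:y1, x0:x1].reshape(T, -1).astype(np.float64)
    lags = np.arange(f0, f1)
    frame_ids = idx[:, None] - (depth_frames - 1) + lags[None, :]  # (N, n_lags)
    return crop_frames[frame_ids].reshape(idx.size, -1)


def compute_ccc(
    train: SpikeTrain,
    stimulus: StimulusMovie,
    depth_frames: int = DEFAULT_DEPTH,
    crop: tuple[int, int, int] = DEFAULT_CROP,
    crop_box=None,
    n_points: int = 200,
) -> CCCCurve:
    """Characteristic correlation curve on the cropped STA.

    The crop box defaults to the (4 frames, 3 px, 3 px) region around the
    full STA's peak voxel. Partial STAs use a running (prefix) sum over
    chronologically ordered spikes, so the cost is O(N * box); ``n`` is
    evaluated on a logarithmic subsample of at most ``n_points`` values
    (always including n = N, where the correlation is 1 by definition).
    """
    if crop_box is None:
        sta = compute_sta(train, stimulus, depth_frames, crop)
        crop_box = sta.crop_box
    M = _cropped_spike_windows(train, stimulus, depth_frames, crop_box)
    N = M.shape[0]
    if N < 2:
        raise ValueError("need at least 2 usable spikes")
    prefix = np.cumsum(M, axis=0)
    ref = prefix[-1] / N
    refc = ref - ref.mean()
    ref_norm = np.linalg.norm(refc)
    ns = np.unique(np.round(np.geomspace(1, N, min(n_points, N))).astype(int))
    V = prefix[ns - 1] / ns[:, None]
    Vc = V - V.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Vc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Vc @ refc) / (norms * ref_norm)
    corr[(norms == 0) | (ref_norm == 0)] = np.nan
    corr[ns == N] = 1.0  # Corr(x, x) is 1 by definition
    return CCCCurve(ns / N, corr, N)


def compute_auc(curve: CCCCurve, extend: str = "first") -> float:
    """Trapezoidal integral of the CCC over n/N in [0, 1].

    The curve's smallest-n point is extended to n/N -> 0 with its own value
    (``extend="first"``) or with 0 (``extend="zero"``); the choice applies
    to every curve consistently, so NR matching is insensitive to it.
    """
    ok = np.isfinite(curve.correlations)
    x = curve.fractions[ok]
    y = curve.correlations[ok]
    if x.size < 2:
        raise ValueError("need at least 2 finite points")
    if x[0] > 0:
        y0 = y[0] if extend == "first" else 0.0
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[y0], y])
    return float(np.trapezoid(y, x))


def select_reference_cell(aucs: dict) -> object:
    """Cell id with the median AUC (lower median on even counts)."""
    if not aucs:
        raise ValueError("no cells with a valid AUC")
    items = sorted(aucs.items(), key=lambda kv: (kv[1], str(kv[0])))
    return items[(len(items) - 1) // 2][0]


def build_noise_family(
    reference: SpikeTrain,
    stimulus: StimulusMovie,
    nr_grid=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    n_seeds: int = 3,
    seed: int | None = None,
    depth_frames: int = DEFAULT_DEPTH,
    crop: tuple[int, int, int] = DEFAULT_CROP,
    n_points: int = 200,
    extend: str = "first",
) -> NoiseFamily:
    """Noise-inject the reference train at each ratio and average the CCCs.

    Each (nr, seed) pair gets its own injection; curves are interpolated
    onto a common fraction grid before averaging, and the family AUC per nr
    is the mean over seeds.
    """
    nr_grid = np.sort(np.asarray(nr_grid, dtype=float))
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(len(nr_grid) * n_seeds))
    fgrid = np.linspace(1.0 / max(reference.n_spikes, 2), 1.0, 200)
    curves = np.empty((len(nr_grid), fgrid.size))
    aucs = np.empty(len(nr_grid))
    # crop box fixed from the clean reference so the whole family is comparable
    ref_sta = compute_sta(reference, stimulus, depth_frames, crop)
    for i, nr in enumerate(nr_grid):
        cs, as_ = [], []
        for _ in range(n_seeds):
            noisy = inject_noise(reference, nr, seed=next(streams))
            c = compute_ccc(noisy, stimulus, depth_frames, crop,
                            crop_box=ref_sta.crop_box, n_points=n_points)
            cs.append(c.interp(fgrid))
            as_.append(compute_auc(c, extend=extend))
        curves[i] = np.mean(cs, axis=0)
        aucs[i] = np.mean(as_)
    return NoiseFamily(nr_grid, aucs, curves, fgrid,
                       reference_id=reference.cell_id, n_seeds=n_seeds)


def match_noise_ratio(query, family: NoiseFamily, mode: str = "interp") -> float:
    """Estimate a cell's noise ratio by AUC matching into the family.

    ``query`` is a :class:`CCCCurve` or a scalar AUC. ``mode="interp"``
    linearly interpolates between the two bracketing grid ratios;
    ``mode="nearest"`` returns the grid ratio with the closest AUC (strict
    replication of the "most similar AUC" rule). AUCs outside the family's
    range clamp to the boundary with a warning.
    """
    if len(family.nr_grid) < 2:
        raise ValueError("family needs at least 2 grid points")
    q = compute_auc(query) if isinstance(query, CCCCurve) else float(query)
    if mode == "nearest":
        return float(family.nr_grid[int(np.argmin(np.abs(family.aucs - q)))])
    # enforce a monotone nonincreasing AUC-vs-nr relation for interpolation
    aucs = np.minimum.accumulate(family.aucs)
    lo, hi = aucs[-1], aucs[0]
    if q > hi or q < lo:
        warnings.warn(
            f"query AUC {q:.3f} outside family range [{lo:.3f}, {hi:.3f}]; clamping",
            stacklevel=2,
        )
        q = min(max(q, lo), hi)
    return float(np.interp(q, aucs[::-1], family.nr_grid[::-1]))
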