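"""Spike-triggered averaging, time courses, SNR, polarity and cell selection.

The STA — the mean stimulus in the ``depth_frames`` frames preceding each
spike — estimates a cell's linear receptive field under white noise. From
it we extract the time course at the spatial peak, a signal-to-noise ratio
(peak over the RMS of the earliest lags), an ON/OFF polarity label (sign of
the lobe nearest the spike, inverted for electrical stimulation of the
healthy retina, where anodic subretinal pulses depolarize photoreceptor
terminals like a visual OFF step), and the selection filters applied to
recorded populations: contamination < 10 % and time-course SNR >= 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stimuli import StimulusMovie
from .synthetic_retina import SpikeTrain

__all__ = [
    "STA",
    "TimeCourse",
    "CellRecord",
    "RFEllipse",
    "compute_sta",
    "extract_time_course",
    "compute_snr",
    "classify_polarity",
    "select_cells",
    "fit_rf_ellipse",
    "spike_frame_indices",
]

DEFAULT_DEPTH = 24
#: (frames, rows, cols) of the crop box used by the noise-ratio analysis
DEFAULT_CROP = (4, 3, 3)


@dataclass
class STA:
    """Spike-triggered average kernel.

    ``kernel[depth-1]`` is the frame nearest the spike. ``crop_box`` is the
    (lag, row, col) slice triple of the (4 frames, 3 px, 3 px) region around
    the peak voxel used by the correlation-curve analysis.
    """

    kernel: np.ndarray  # (depth, H, W)
    spike_count_used: int
    stimulus_mean: float
    peak: tuple[int, int, int]  # (lag, row, col)
    crop_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    @property
    def depth_frames(self) -> int:
        return self.kernel.shape[0]

    def cropped(self) -> np.ndarray:
        (f0, f1), (y0, y1), (x0, x1) = self.crop_box
        return self.kernel[f0:f1, y0:y1, x0:x1]


@dataclass
class TimeCourse:
    """Mean-subtracted temporal profile of the STA at its spatial peak."""

    values: np.ndarray  # length = depth_frames; last entry nearest the spike
    peak_lag: int
    peak_value: float  # signed value at the largest-|.| lag


def spike_frame_indices(
    train: SpikeTrain, frame_rate: float, depth_frames: int, n_frames: int
) -> np.ndarray:
    """Frame index of each spike, keeping only spikes with a full preceding window."""
    idx = np.floor(train.times * frame_rate + 1e-9).astype(np.int64)
    return idx[(idx >= depth_frames - 1) & (idx < n_frames)]


def _peak_and_crop(kernel: np.ndarray, stimulus_mean: float, crop=DEFAULT_CROP):
    depth, H, W = kernel.shape
    flat = np.abs(kernel - stimulus_mean)
    # argmax is lag-major then row-major, which is exactly the tie-break rule
    lag, py, px = np.unravel_index(int(np.argmax(flat)), kernel.shape)
    cf, cy, cx = crop
    f0 = min(max(lag - (cf - 2), 0), max(depth - cf, 0))
    y0 = min(max(py - cy // 2, 0), max(H - cy, 0))
    x0 = min(max(px - cx // 2, 0), max(W - cx, 0))
    box = ((f0, min(f0 + cf, depth)), (y0, min(y0 + cy, H)), (x0, min(x0 + cx, W)))
    return (int(lag), int(py), int(px)), box


def compute_sta(
    train: SpikeTrain,
    stimulus: StimulusMovie,
    depth_frames: int = DEFAULT_DEPTH,
    crop: tuple[int, int, int] = DEFAULT_CROP,
) -> STA:
    """Average the ``depth_frames`` stimulus frames preceding each spike.

    Spikes whose preceding window would run off the start of the movie are
    skipped; ``spike_count_used`` records how many spikes contributed.
    """
    T = stimulus.n_frames
    idx = spike_frame_indices(train, stimulus.frame_rate, depth_frames, T)
    if idx.size == 0:
        raise ValueError("no spikes with a full preceding stimulus window")
    counts = np.bincount(idx, minlength=T).astype(np.float64)
    ff = stimulus.frames.reshape(T, -1).astype(np.float64)
    kernel = np.empty((depth_frames,) + stimulus.spatial_shape)
    n = idx.size
    for lag in range(depth_frames):
        shift = depth_frames - 1 - lag  # kernel[depth-1] = spike frame
        kernel[lag] = ((counts[shift:] @ ff[: T - shift]) / n).reshape(stimulus.spatial_shape)
    mean = float(stimulus.frames.mean())
    peak, box = _peak_and_crop(kernel, mean, crop)
    return STA(kernel, n, mean, peak, box)


def extract_time_course(sta: STA, spatial: str = "peak") -> TimeCourse:
    """Temporal profile at the RF centre, mean-subtracted.

    ``spatial="peak"`` reads the single peak pixel; ``"crop_mean"`` averages
    over the crop box's 3x3 spatial extent.
    """
    _, py, px = sta.peak
    if spatial == "peak":
        values = sta.kernel[:, py, px] - sta.stimulus_mean
    elif spatial == "crop_mean":
        (_, _), (y0, y1), (x0, x1) = sta.crop_box
        values = sta.kernel[:, y0:y1, x0:x1].mean(axis=(1, 2)) - sta.stimulus_mean
    else:
        raise ValueError(f"unknown spatial mode: {spatial!r}")
    lag = int(np.argmax(np.abs(values)))
    return TimeCourse(values, lag, float(values[lag]))


def compute_snr(tc: TimeCourse, n_noise_lags: int = 10) -> float:
    """|peak| over the RMS of the lags farthest from the spike (the earliest ones)."""
    if len(tc.values) < n_noise_lags + 1:
        raise ValueError("time course too short for the SNR convention")
    noise = float(np.sqrt(np.mean(tc.values[:n_noise_lags] ** 2)))
    peak = abs(tc.peak_value)
    return float("inf") if noise == 0 else peak / noise


def classify_polarity(
    tc: TimeCourse,
    modality: str = "visual",
    retina_type: str = "LE",
    eps: float = 0.0,
) -> str:
    """ON/OFF from the sign of the lobe nearest the spike.

    For electrical stimulation of the healthy (LE) retina the label is
    inverted: a visual ON cell appears as an electrical OFF cell. Degenerate
    (RCS) electrical labels are reported as measured. Returns
    ``"unclassified"`` when the time course has no lobe above ``eps``.
    """
    x = tc.values
    m = float(np.max(np.abs(x)))
    if m <= eps:
        return "unclassified"
    above = np.abs(x) >= 0.5 * m
    last = len(x) - 1 - int(np.argmax(above[::-1]))
    start = last
    while start > 0 and above[start - 1]:
        start -= 1
    lobe = x[start : last + 1]
    sign = np.sign(lobe[int(np.argmax(np.abs(lobe)))])
    label = "ON" if sign > 0 else "OFF"
    if modality == "electrical" and retina_type in ("LE", "healthy"):
        label = "OFF" if label == "ON" else "ON"
    return label


@dataclass
class CellRecord:
    """Per-cell summary used by the selection filters."""

    cell_id: str | int
    snr: float
    contamination: float
    polarity: str = "unclassified"
    in_implant_region: bool | None = None
    dual_responsive: bool | None = None


def select_cells(
    records: list[CellRecord],
    max_contamination: float = 0.10,
    min_snr: float = 3.0,
    require_in_implant: bool = False,
    require_dual_responsive: bool = False,
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Apply the cell-selection criteria; return kept cells and an audit log.

    The audit log has one row per (cell, criterion) with the outcome, so the
    removals per criterion can be counted. Axon-direction / EI-based
    exclusions, which need full-array geometry, are represented by a no-op
    slot and never remove cells here.
    """
    rows = []
    kept = []
    for rec in records:
        checks = {
            "contamination<%.2f" % max_contamination: rec.contamination <= max_contamination,
            "snr>=%g" % min_snr: rec.snr >= min_snr,
            "axon_direction": True,  # no-op slot: requires array geometry
        }
        if require_in_implant:
            checks["soma_under_implant"] = bool(rec.in_implant_region)
        if require_dual_responsive:
            checks["dual_responsive"] = bool(rec.dual_responsive)
        ok = all(checks.values())
        for crit, passed in checks.items():
            rows.append({"cell_id": rec.cell_id, "criterion": crit,
                         "kept": bool(passed)})
        if ok:
            kept.append(rec)
    audit = pd.DataFrame(rows, columns=["cell_id", "criterion", "kept"])
    return kept, audit


@dataclass
class RFEllipse:
    center: tuple[float, float]  # (row, col) in pixels
    sigma_y: float
    sigma_x: float
    angle: float  # radians
    amplitude: float
    converged: bool


def _gauss2d(coords, amp, y0, x0, sy, sx, theta, off):
    y, x = coords
    ct, st = np.cos(theta), np.sin(theta)
    yr = (y - y0) * ct + (x - x0) * st
    xr = -(y - y0) * st + (x - x0) * ct
    return (amp * np.exp(-0.5 * ((yr / sy) ** 2 + (xr / sx) ** 2)) + off).ravel()


def fit_rf_ellipse(sta: STA) -> RFEllipse:
    """Fit a 2-D Gaussian to the peak-lag spatial frame of the STA."""
    lag, py, px = sta.peak
    frame = sta.kernel[lag] - sta.stimulus_mean
    if frame[py, px] < 0:
        frame = -frame
    H, W = frame.shape
    yy, xx = np.mgrid[0:H, 0:W] + 0.5
    p0 = [float(frame[py, px]), py + 0.5, px + 0.5, 1.0, 1.0, 0.0, 0.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_gauss2d, (yy, xx), frame.ravel(), p0=p0, maxfev=5000)
        amp, y0, x0, sy, sx, th, _ = popt
        return RFEllipse((float(y0), float(x0)), abs(float(sy)), abs(float(sx)),
                         float(th), float(amp), True)
    except RuntimeError:
        return RFEllipse((py + 0.5, px + 0.5), np.nan, np.nan, 0.0, np.nan, False)
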