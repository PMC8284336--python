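"""Stimulation-artifact removal and spike detection on raw voltage traces.

Subretinal stimulation saturates the MEA amplifiers, so the stretch of
recording right after each pulse is unusable. The pipeline is: (1) blank —
replace the first ``blank_ms`` (default 8.25 ms) after each pulse with
Gaussian noise matched to the electrode's off-pulse noise level; (2)
detrend — fit and subtract a 7th-order polynomial per inter-pulse segment
to remove the lingering capacitive decay; (3) detect — negative deflections
exceeding 3x the RMS noise are spikes. A contamination statistic from
refractory-period violations supports the <10 % selection filter.

Noise levels are estimated robustly (median absolute deviation x 1.4826) so
spikes do not inflate them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .synthetic_retina import SpikeTrain

__all__ = [
    "VoltageTrace",
    "blank_artifact",
    "detrend_decay",
    "detect_spikes",
    "estimate_contamination",
    "save_trace",
    "load_trace",
]

DEFAULT_BLANK_MS = 8.25
DEFAULT_DETREND_ORDER = 7


@dataclass
class VoltageTrace:
    """Single-electrode voltage samples (µV) with stimulation pulse onsets."""

    samples: np.ndarray
    sample_rate: float = 20_000.0
    pulse_times: np.ndarray | None = None  # seconds, sorted

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.pulse_times is None:
            self.pulse_times = np.empty(0)
        self.pulse_times = np.asarray(self.pulse_times, dtype=np.float64)
        if self.pulse_times.size:
            if np.any(np.diff(self.pulse_times) < 0):
                raise ValueError("pulse_times must be sorted")
            if self.pulse_times.min() < 0 or self.pulse_times.max() >= self.duration:
                raise ValueError("pulse_times must lie within the trace")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def _blank_windows(trace: VoltageTrace, blank_ms: float) -> list[tuple[int, int]]:
    """Per-pulse blank windows as sample index ranges, merged if overlapping."""
    n = trace.samples.size
    w = int(round(blank_ms / 1000.0 * trace.sample_rate))
    raw = [(int(round(t * trace.sample_rate)), min(int(round(t * trace.sample_rate)) + w, n))
           for t in trace.pulse_times]
    merged: list[tuple[int, int]] = []
    overlapped = False
    for a, b in raw:
        if merged and a < merged[-1][1]:
            overlapped = True
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    if overlapped:
        warnings.warn("overlapping blank windows merged", stacklevel=3)
    return merged


def _offpulse_mask(trace: VoltageTrace, blank_ms: float) -> np.ndarray:
    mask = np.ones(trace.samples.size, dtype=bool)
    for a, b in _blank_windows(trace, blank_ms):
        mask[a:b] = False
    return mask


def _robust_rms(x: np.ndarray) -> float:
    """MAD-based noise scale, robust to spikes."""
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def blank_artifact(
    trace: VoltageTrace, blank_ms: float = DEFAULT_BLANK_MS, seed: int | None = None
) -> VoltageTrace:
    """Replace the first ``blank_ms`` after each pulse with matched noise.

    The replacement is Gaussian with the off-pulse robust RMS, centred at
    the off-pulse median; samples outside the blank windows are untouched.
    """
    if trace.pulse_times.size == 0:
        return VoltageTrace(trace.samples.copy(), trace.sample_rate, trace.pulse_times.copy())
    rng = np.random.default_rng(seed)
    mask = _offpulse_mask(trace, blank_ms)
    off = trace.samples[mask]
    sigma = _robust_rms(off)
    centre = float(np.median(off))
    out = trace.samples.copy()
    for a, b in _blank_windows(trace, blank_ms):
        out[a:b] = rng.normal(centre, sigma, size=b - a)
    return VoltageTrace(out, trace.sample_rate, trace.pulse_times.copy())


def detrend_decay(
    trace: VoltageTrace,
    order: int = DEFAULT_DETREND_ORDER,
    blank_ms: float = DEFAULT_BLANK_MS,
) -> VoltageTrace:
    """Subtract a least-squares polynomial per inter-pulse segment.

    Segments run between consecutive pulse onsets (plus the leading and
    trailing stretches). The fit excludes the blanked samples at the head
    of each segment and the polynomial is subtracted over the fitted span;
    segments too short to constrain the fit are skipped with a warning.
    """
    n = trace.samples.size
    out = trace.samples.copy()
    pulses = np.round(trace.pulse_times * trace.sample_rate).astype(int)
    edges = np.concatenate([[0], pulses, [n]])
    blank = int(round(blank_ms / 1000.0 * trace.sample_rate)) if trace.pulse_times.size else 0
    for i in range(len(edges) - 1):
        a, b = int(edges[i]), int(edges[i + 1])
        fit_a = a + blank if i >= 1 else a  # segment i>=1 starts at a pulse
        if b - fit_a <= order + 1:
            if b > a:
                warnings.warn(f"segment [{a}, {b}) too short for order-{order} fit; skipped",
                              stacklevel=2)
            continue
        t = np.arange(fit_a, b)
        poly = np.polynomial.Polynomial.fit(t, trace.samples[fit_a:b], order)
        out[fit_a:b] = trace.samples[fit_a:b] - poly(t)
        if fit_a > a:
            # re-centre the blanked head with the fit's boundary value rather
            # than extrapolating the polynomial backwards, so a constant
            # offset on the input cancels there too
            out[a:fit_a] = trace.samples[a:fit_a] - poly(fit_a)
    return VoltageTrace(out, trace.sample_rate, trace.pulse_times.copy())


def detect_spikes(
    trace: VoltageTrace,
    threshold_sigma: float = 3.0,
    refractory_ms: float = 1.0,
) -> SpikeTrain:
    """Threshold detector: local negative minima below -3x RMS noise.

    The noise RMS is the robust (MAD-based) scale about the median, so the
    absolute threshold scales with the noise level. Candidate minima closer
    than ``refractory_ms`` are merged, keeping the deeper one.
    """
    x = trace.samples
    if x.size < 3:
        return SpikeTrain(np.empty(0), max(trace.duration, np.finfo(float).tiny))
    med = float(np.median(x))
    sigma = _robust_rms(x)
    th = med - threshold_sigma * sigma
    below = x < th
    local_min = np.zeros_like(below)
    local_min[1:-1] = (x[1:-1] <= x[:-2]) & (x[1:-1] <= x[2:])
    cand = np.flatnonzero(below & local_min)
    if cand.size == 0:
        return SpikeTrain(np.empty(0), trace.duration)
    merge = int(round(refractory_ms / 1000.0 * trace.sample_rate))
    kept = [cand[0]]
    for c in cand[1:]:
        if c - kept[-1] < merge:
            if x[c] < x[kept[-1]]:
                kept[-1] = c
        else:
            kept.append(c)
    times = np.asarray(kept) / trace.sample_rate
    return SpikeTrain(times, trace.duration)


def estimate_contamination(train: SpikeTrain, refractory_ms: float = 1.5) -> float:
    """Contaminating-spike fraction from refractory-period violations.

    The observed fraction of inter-spike intervals shorter than
    ``refractory_ms`` is divided by the fraction expected from a
    rate-matched Poisson process (1 - exp(-lambda * t_ref)) and clipped to
    [0, 1]. A well-isolated cell with a dead time >= the refractory window
    scores 0; a 50/50 merge of two independent refractory trains scores
    about 0.5.
    """
    if train.n_spikes < 2:
        return 0.0
    t_ref = refractory_ms / 1000.0
    lam = train.n_spikes / train.duration
    expected = 1.0 - np.exp(-lam * t_ref)
    if expected <= 0:
        return 0.0
    observed = float(np.mean(np.diff(train.times) < t_ref))
    return float(np.clip(observed / expected, 0.0, 1.0))


def save_trace(trace: VoltageTrace, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples", data=trace.samples)
        d.attrs["sample_rate"] = trace.sample_rate
        f.create_dataset("pulse_times", data=trace.pulse_times)


def load_trace(path) -> VoltageTrace:
    with h5py.File(path, "r") as f:
        return VoltageTrace(
            f["samples"][...],
            float(f["samples"].attrs["sample_rate"]),
            f["pulse_times"][...],
        )
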