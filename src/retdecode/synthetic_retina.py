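"""Ground-truth RGC population simulator.

Cells are linear–nonlinear Poisson units: a space–time separable filter
(difference-of-Gaussians centre–surround × biphasic temporal kernel) drives
a rectifying nonlinearity, and per-frame spike counts are Poisson. The
simulator also implements the noise-injection process used to calibrate the
noise-ratio estimator: a fraction ``nr`` of a train's spikes is removed and
replaced, in expectation one-for-one, by randomly timed (homogeneous
Poisson) "spontaneous" spikes, so the mean rate is preserved while the
stimulus-locked signal shrinks by ``1 - nr``.

Population presets mirror the two retina types studied: a healthy
("LE-like") retina with dense receptive-field mosaics and low spontaneous
fraction, and a degenerate ("RCS-like") retina with fewer cells confined to
the implant region and a high spontaneous fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .stimuli import StimulusMovie

__all__ = [
    "SpikeTrain",
    "GroundTruthCell",
    "RetinaSpec",
    "LE_CELL_COUNTS",
    "RCS_CELL_COUNTS",
    "simulate_cell",
    "inject_noise",
    "build_population",
    "simulate_population",
]

#: cell counts of the four healthy (Long-Evans) retinas
LE_CELL_COUNTS = (49, 49, 21, 20)
#: cell counts of the four degenerate (RCS) retinas
RCS_CELL_COUNTS = (19, 14, 13, 9)


@dataclass
class SpikeTrain:
    """Sorted spike times of one cell, in seconds from recording start."""

    times: np.ndarray
    duration: float
    cell_id: str | int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times.size:
            if self.times.min() < 0 or self.times.max() >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")
            if np.any(np.diff(self.times) < 0):
                raise ValueError("spike times must be sorted")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return self.n_spikes / self.duration


@dataclass
class GroundTruthCell:
    """Parametric LN ground-truth cell.

    The spatial filter is a difference of Gaussians centred at
    ``center_um`` (µm); the temporal filter is biphasic with a lobe peaking
    ``peak_frames`` before the spike and an opposing trough at
    ``trough_frames``. ``polarity`` flips the sign of the whole kernel
    (an OFF cell's filter is the negated ON filter). The nonlinearity is a
    rectifier: rate = gain * max(drive - threshold, 0) + baseline_rate.
    ``noise_ratio`` is the fraction of stimulus-driven spikes to replace by
    spontaneous ones when simulating the population.
    """

    cell_id: str | int
    polarity: str = "ON"  # "ON" | "OFF"
    center_um: tuple[float, float] = (0.0, 0.0)  # (y, x) on the retina
    sigma_center_um: float = 55.0
    sigma_surround_um: float = 110.0
    surround_weight: float = 0.25
    peak_frames: float = 2.5
    trough_frames: float = 5.5
    trough_weight: float = 0.6
    threshold: float = 0.0
    gain: float = 120.0  # Hz per unit filter drive
    baseline_rate: float = 2.0  # Hz
    noise_ratio: float = 0.0
    refractory_ms: float = 0.0  # optional absolute dead time

    def __post_init__(self) -> None:
        if self.polarity not in ("ON", "OFF"):
            raise ValueError("polarity must be 'ON' or 'OFF'")
        if not 0.0 <= self.noise_ratio <= 1.0:
            raise ValueError("noise_ratio must lie in [0, 1]")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")

    def spatial_kernel(self, shape: tuple[int, int], pixel_pitch: float) -> np.ndarray:
        """Difference-of-Gaussians RF sampled at the stimulus pixel centres."""
        H, W = shape
        y = (np.arange(H) + 0.5) * pixel_pitch - self.center_um[0]
        x = (np.arange(W) + 0.5) * pixel_pitch - self.center_um[1]
        r2 = y[:, None] ** 2 + x[None, :] ** 2
        centre = np.exp(-r2 / (2 * self.sigma_center_um**2))
        surround = np.exp(-r2 / (2 * self.sigma_surround_um**2))
        return centre - self.surround_weight * surround

    def temporal_kernel(self, depth_frames: int = 24) -> np.ndarray:
        """Biphasic kernel; index ``depth-1`` is the frame nearest the spike."""
        tau = np.arange(depth_frames - 1, -1, -1, dtype=np.float64)  # lag before spike

        def lobe(t_peak: float, q: float = 3.0) -> np.ndarray:
            z = tau / t_peak
            return z**q * np.exp(q * (1.0 - z))

        return lobe(self.peak_frames) - self.trough_weight * lobe(self.trough_frames)

    def kernel(self, stimulus: StimulusMovie, depth_frames: int = 24) -> np.ndarray:
        """Unit-L2 spatiotemporal filter on the stimulus grid, signed by polarity."""
        k = (
            self.temporal_kernel(depth_frames)[:, None, None]
            * self.spatial_kernel(stimulus.spatial_shape, stimulus.pixel_pitch)[None]
        )
        k /= np.linalg.norm(k)
        return k if self.polarity == "ON" else -k


def filter_drive(frames: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Sliding inner product of a spatiotemporal kernel with a frame stack.

    Returns a length-``T`` array; entry ``t`` is the kernel dotted with the
    ``depth`` frames ending at (and including) frame ``t``. The first
    ``depth - 1`` entries, which lack a full window, are zero.
    """
    depth = kernel.shape[0]
    T = frames.shape[0]
    if T < depth:
        raise ValueError("stimulus shorter than the filter depth")
    ff = frames.reshape(T, -1)
    kf = kernel.reshape(depth, -1)
    acc = np.zeros(T - depth + 1)
    for lag in range(depth):
        acc += ff[lag : T - depth + 1 + lag] @ kf[lag]
    out = np.zeros(T)
    out[depth - 1 :] = acc
    return out


def simulate_cell(
    cell: GroundTruthCell,
    stimulus: StimulusMovie,
    seed: int | None = None,
    depth_frames: int = 24,
    stimulus_mean: float = 0.5,
) -> SpikeTrain:
    """Simulate one cell's spike train in response to a stimulus movie.

    Per frame, rate = gain * relu(w . (s - mean) - threshold) + baseline;
    counts are Poisson(rate * dt) and spike times are jittered uniformly
    within the frame. The cell's ``noise_ratio`` is *not* applied here; see
    :func:`inject_noise` / :func:`simulate_population`.
    """
    if stimulus.n_frames == 0:
        raise ValueError("empty stimulus")
    if stimulus.n_frames <= depth_frames:
        raise ValueError("stimulus must be longer than the filter depth")
    rng = np.random.default_rng(seed)
    if cell.gain != 0.0:
        w = cell.kernel(stimulus, depth_frames)
        drive = filter_drive(stimulus.frames - stimulus_mean, w)
        rate = cell.gain * np.maximum(drive - cell.threshold, 0.0)
    else:
        rate = np.zeros(stimulus.n_frames)
    rate = rate + cell.baseline_rate
    dt = stimulus.dt
    counts = rng.poisson(rate * dt)
    idx = np.repeat(np.arange(stimulus.n_frames), counts)
    times = np.sort((idx + rng.random(idx.size)) * dt)
    if cell.refractory_ms > 0 and times.size:
        dead = cell.refractory_ms / 1000.0
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= dead:
                kept.append(t)
        times = np.asarray(kept)
    return SpikeTrain(times, stimulus.duration, cell_id=cell.cell_id)


def inject_noise(train: SpikeTrain, nr: float, seed: int | None = None) -> SpikeTrain:
    """Replace a fraction ``nr`` of spikes with randomly timed spikes.

    Exactly ``round(nr * N)`` spikes are removed uniformly at random;
    replacements are drawn from a homogeneous Poisson process over the full
    recording (count ~ Poisson(removed count)), preserving the mean rate in
    expectation.
    """
    if not 0.0 <= nr <= 1.0:
        raise ValueError("noise ratio must lie in [0, 1]")
    if nr == 0.0 or train.n_spikes == 0:
        return SpikeTrain(train.times.copy(), train.duration, cell_id=train.cell_id)
    rng = np.random.default_rng(seed)
    n = train.n_spikes
    m = int(round(nr * n))
    keep = np.ones(n, dtype=bool)
    keep[rng.choice(n, size=m, replace=False)] = False
    k = rng.poisson(m)
    new = rng.uniform(0.0, train.duration, size=k)
    times = np.sort(np.concatenate([train.times[keep], new]))
    return SpikeTrain(times, train.duration, cell_id=train.cell_id)


@dataclass
class RetinaSpec:
    """Configuration of a synthetic retina.

    ``preset`` selects the retina archetype: ``"LE"`` (healthy, dense
    mosaic, low spontaneous fraction, visual stimulation by default) or
    ``"RCS"`` (degenerate, sparse, cells restricted to the implant disc,
    high spontaneous fraction, electrical stimulation). Fields left at
    ``None`` take preset defaults; ``n_cells=None`` draws one of the
    preset's recorded retina sizes.
    """

    preset: str = "LE"
    n_cells: int | None = None
    field_shape: tuple[int, int] = (16, 16)  # stimulus pixels covered by the mosaic
    pixel_pitch: float | None = None
    modality: str | None = None
    noise_ratio: float | tuple[float, float] | None = None
    implant_radius_um: float | None = None
    gain: float | None = None
    baseline_rate: float | None = None
    on_fraction: float = 0.5
    refractory_ms: float = 0.0

    def resolved(self) -> "RetinaSpec":
        s = replace(self)
        if s.preset == "LE":
            s.pixel_pitch = 60.0 if s.pixel_pitch is None else s.pixel_pitch
            s.modality = "visual" if s.modality is None else s.modality
            s.noise_ratio = 0.1 if s.noise_ratio is None else s.noise_ratio
            s.gain = 120.0 if s.gain is None else s.gain
            s.baseline_rate = 2.0 if s.baseline_rate is None else s.baseline_rate
        elif s.preset == "RCS":
            s.pixel_pitch = 70.0 if s.pixel_pitch is None else s.pixel_pitch
            s.modality = "electrical" if s.modality is None else s.modality
            s.noise_ratio = 0.78 if s.noise_ratio is None else s.noise_ratio
            s.gain = 60.0 if s.gain is None else s.gain
            s.baseline_rate = 4.0 if s.baseline_rate is None else s.baseline_rate
            if s.implant_radius_um is None:
                H, W = s.field_shape
                s.implant_radius_um = 0.5 * min(H, W) * s.pixel_pitch
        elif s.preset == "custom":
            s.pixel_pitch = 60.0 if s.pixel_pitch is None else s.pixel_pitch
            s.modality = "visual" if s.modality is None else s.modality
            s.noise_ratio = 0.0 if s.noise_ratio is None else s.noise_ratio
            s.gain = 120.0 if s.gain is None else s.gain
            s.baseline_rate = 2.0 if s.baseline_rate is None else s.baseline_rate
        else:
            raise ValueError(f"unknown preset: {s.preset!r}")
        return s


def _jittered_grid(n: int, extent_y: float, extent_x: float, rng,
                   disc_center: tuple[float, float] | None = None,
                   disc_radius: float | None = None) -> np.ndarray:
    """n jittered RF centres (µm) tiling a rectangle, optionally within a disc."""
    m = max(1, math.ceil(math.sqrt(n)))
    while True:
        gy = (np.arange(m) + 0.5) * (extent_y / m)
        gx = (np.arange(m) + 0.5) * (extent_x / m)
        yy, xx = np.meshgrid(gy, gx, indexing="ij")
        pts = np.column_stack([yy.ravel(), xx.ravel()])
        jitter = (rng.random(pts.shape) - 0.5) * 0.5 * min(extent_y, extent_x) / m
        pts = pts + jitter
        if disc_radius is not None:
            cy, cx = disc_center
            d = np.hypot(pts[:, 0] - cy, pts[:, 1] - cx)
            pts = pts[d <= disc_radius]
        if len(pts) >= n:
            return pts[rng.permutation(len(pts))[:n]]
        m += 1


def build_population(spec: RetinaSpec, seed: int | None = None) -> list[GroundTruthCell]:
    """Build a ground-truth cell population from a retina specification."""
    spec = spec.resolved()
    rng = np.random.default_rng(seed)
    if spec.n_cells is None:
        counts = LE_CELL_COUNTS if spec.preset == "LE" else RCS_CELL_COUNTS
        n = int(rng.choice(counts)) if spec.preset in ("LE", "RCS") else 16
    else:
        n = int(spec.n_cells)
    if n < 1:
        raise ValueError("cell count must be >= 1")
    H, W = spec.field_shape
    ey, ex = H * spec.pixel_pitch, W * spec.pixel_pitch
    disc_center = disc_radius = None
    if spec.implant_radius_um is not None:
        disc_center = (ey / 2, ex / 2)
        disc_radius = spec.implant_radius_um
    centers = _jittered_grid(n, ey, ex, rng, disc_center, disc_radius)
    if isinstance(spec.noise_ratio, tuple):
        nrs = rng.uniform(spec.noise_ratio[0], spec.noise_ratio[1], size=n)
    else:
        nrs = np.full(n, float(spec.noise_ratio))
    # electrical responses: faster, weaker STAs than visual ones
    fast = spec.modality == "electrical"
    cells = []
    for i in range(n):
        cells.append(
            GroundTruthCell(
                cell_id=i,
                polarity="ON" if rng.random() < spec.on_fraction else "OFF",
                center_um=(float(centers[i, 0]), float(centers[i, 1])),
                sigma_center_um=0.9 * spec.pixel_pitch * rng.uniform(0.9, 1.1),
                sigma_surround_um=1.8 * spec.pixel_pitch * rng.uniform(0.9, 1.1),
                peak_frames=1.2 if fast else 2.5,
                trough_frames=2.8 if fast else 5.5,
                gain=float(spec.gain),
                baseline_rate=float(spec.baseline_rate),
                noise_ratio=float(nrs[i]),
                refractory_ms=spec.refractory_ms,
            )
        )
    return cells


def simulate_population(
    cells: list[GroundTruthCell],
    stimulus: StimulusMovie,
    seed: int | None = None,
    depth_frames: int = 24,
) -> list[SpikeTrain]:
    """Simulate every cell and apply its own noise ratio; one substream per cell."""
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(2 * len(cells))
    trains = []
    for i, cell in enumerate(cells):
        train = simulate_cell(cell, stimulus, seed=streams[2 * i], depth_frames=depth_frames)
        if cell.noise_ratio > 0:
            train = inject_noise(train, cell.noise_ratio, seed=streams[2 * i + 1])
        trains.append(train)
    return trains
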