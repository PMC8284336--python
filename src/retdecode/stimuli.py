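"""Stimulus generation: binary white-noise movies and pixelated Landolt-C optotypes.

Two stimulus families drive everything downstream:

* spatiotemporal binary white noise, used to map receptive fields and fit
  encoding models — every pixel in every frame is independently bright or
  dark with probability ``p_bright``;
* pixelated Landolt-C presentations, used by the ensemble orientation
  decoder — a ring optotype whose gap (1/5 of the letter diameter) points
  up, down, left or right, rendered at high resolution, block-averaged onto
  the stimulus pixel grid and quantized to a small number of grey levels.

Conventions: movies are time-major ``(T, H, W)`` arrays with intensities in
``[0, 1]``; visual stimulation runs at 30 Hz with 60 µm pixels, subretinal
electrical stimulation at 20 Hz with 70 µm pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "StimulusMovie",
    "LandoltSpec",
    "ORIENTATIONS",
    "VISUAL",
    "ELECTRICAL",
    "generate_white_noise",
    "generate_landolt_c",
    "save_movie",
    "load_movie",
]

ORIENTATIONS = ("up", "down", "left", "right")

#: canonical (frame_rate Hz, pixel_pitch µm) per stimulation modality
VISUAL = {"frame_rate": 30.0, "pixel_pitch": 60.0}
ELECTRICAL = {"frame_rate": 20.0, "pixel_pitch": 70.0}


@dataclass
class StimulusMovie:
    """A time-major stack of stimulus frames.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of intensities in ``[0, 1]``.
    frame_rate
        Presentation rate in Hz.
    pixel_pitch
        Width of one stimulus pixel on the retina, in µm.
    modality
        ``"visual"`` or ``"electrical"``.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float
    modality: str = "visual"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.modality not in ("visual", "electrical"):
            raise ValueError(f"unknown modality: {self.modality!r}")
        fmin, fmax = float(self.frames.min(initial=0.0)), float(self.frames.max(initial=0.0))
        if fmin < -1e-9 or fmax > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Total movie duration in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def dt(self) -> float:
        """Frame duration in seconds."""
        return 1.0 / self.frame_rate

    def save(self, path) -> None:
        save_movie(self, path)

    @classmethod
    def load(cls, path) -> "StimulusMovie":
        return load_movie(path)


def generate_white_noise(
    shape: tuple[int, int, int],
    frame_rate: float = 30.0,
    p_bright: float = 0.5,
    seed: int | None = None,
    pixel_pitch: float = 60.0,
    modality: str = "visual",
) -> StimulusMovie:
    """Generate a spatiotemporal binary white-noise movie.

    Each pixel in each frame is independently bright (1) with probability
    ``p_bright`` and dark (0) otherwise.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"shape must be a positive (T, H, W) triple, got {shape}")
    if not 0.0 <= p_bright <= 1.0:
        raise ValueError("p_bright must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = (rng.random(shape) < p_bright).astype(np.float32)
    return StimulusMovie(frames, frame_rate, pixel_pitch, modality)


@dataclass
class LandoltSpec:
    """Specification of a pixelated Landolt-C presentation.

    The letter is a ring whose stroke width equals the gap width, and the
    gap is 1/5 of the letter diameter (Sloan/Landolt convention). The movie
    holds ``n_dark_frames`` blank frames followed by ``n_bright_frames``
    identical frames showing the letter at a fixed position.
    """

    orientation: str = "up"
    size_px: int = 14
    grey_levels: int = 8
    canvas: tuple[int, int] = (64, 32)
    n_dark_frames: int = 19
    n_bright_frames: int = 5
    center: tuple[float, float] | None = None  # (row, col) in pixels; default canvas centre
    background_level: float = 1.0
    ring_level: float = 0.0
    frame_rate: float = 30.0
    pixel_pitch: float = 60.0
    modality: str = "visual"

    @property
    def gap_px(self) -> float:
        """Gap (and stroke) width in stimulus pixels: exactly size/5.

        The continuous letter keeps the Landolt ratio at every size; the
        gap only becomes fully resolved (a whole background pixel) once
        size reaches 5 px.
        """
        return self.size_px / 5.0

    @property
    def n_frames(self) -> int:
        return self.n_dark_frames + self.n_bright_frames


def _landolt_frame(spec: LandoltSpec, supersample: int = 16) -> np.ndarray:
    """Render one bright frame of the Landolt-C on the stimulus pixel grid."""
    H, W = spec.canvas
    size = float(spec.size_px)
    # the letter is continuous before pixelization: the gap (and the stroke)
    # is exactly 1/5 of the diameter, and sub-pixel gaps come out as grey
    # shades after block-averaging rather than being rounded away
    gap = size / 5.0
    if spec.center is not None:
        cy, cx = spec.center
    else:
        # snap the letter's bounding box to the pixel grid, as close to the
        # canvas centre as that allows, so a size-s letter spans exactly s pixels
        cy = (H - spec.size_px) // 2 + spec.size_px / 2.0
        cx = (W - spec.size_px) // 2 + spec.size_px / 2.0
    r_out = size / 2.0
    if cy - r_out < -1e-9 or cx - r_out < -1e-9 or cy + r_out > H + 1e-9 or cx + r_out > W + 1e-9:
        raise ValueError(
            f"Landolt-C of size {spec.size_px} px at centre ({cy}, {cx}) exceeds the {H}x{W} canvas"
        )
    S = int(supersample)
    y = (np.arange(H * S) + 0.5) / S - cy
    x = (np.arange(W * S) + 0.5) / S - cx
    dy = y[:, None]
    dx = x[None, :]
    r2 = dy * dy + dx * dx
    r_in = r_out - gap
    ring = (r2 <= r_out * r_out) & (r2 >= r_in * r_in)
    half = gap / 2.0
    if spec.orientation == "right":
        gap_mask = (np.abs(dy) <= half) & (dx > 0)
    elif spec.orientation == "left":
        gap_mask = (np.abs(dy) <= half) & (dx < 0)
    elif spec.orientation == "up":
        gap_mask = (np.abs(dx) <= half) & (dy < 0)
    elif spec.orientation == "down":
        gap_mask = (np.abs(dx) <= half) & (dy > 0)
    else:
        raise ValueError(f"unknown orientation: {spec.orientation!r}")
    letter = (ring & ~gap_mask).astype(np.float64)
    # block-average the supersampled raster onto the stimulus grid
    coverage = letter.reshape(H, S, W, S).mean(axis=(1, 3))
    frame = spec.background_level - (spec.background_level - spec.ring_level) * coverage
    # quantize to grey_levels evenly spaced values in [0, 1]; ties round half-up
    L = spec.grey_levels
    frame = np.floor(frame * (L - 1) + 0.5) / (L - 1)
    return np.clip(frame, 0.0, 1.0)


def generate_landolt_c(spec: LandoltSpec, supersample: int = 16) -> StimulusMovie:
    """Render a Landolt-C presentation movie (dark frames then bright frames).

    The letter is rasterized at ``supersample``x resolution, block-averaged
    to stimulus pixels and quantized to ``spec.grey_levels`` evenly spaced
    grey levels. Background sits at ``background_level`` (default bright),
    the ring at ``ring_level`` (default dark), the gap at background.
    """
    if spec.size_px < 2:
        raise ValueError("size_px must be >= 2")
    H, W = spec.canvas
    bright = _landolt_frame(spec, supersample=supersample)
    frames = np.zeros((spec.n_frames, H, W), dtype=np.float64)
    frames[spec.n_dark_frames :] = bright
    return StimulusMovie(frames, spec.frame_rate, spec.pixel_pitch, spec.modality)


def save_movie(movie: StimulusMovie, path) -> None:
    """Write a movie to HDF5 (dataset ``frames`` + scalar attributes)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=movie.frames)
        d.attrs["frame_rate"] = movie.frame_rate
        d.attrs["pixel_pitch"] = movie.pixel_pitch
        d.attrs["modality"] = movie.modality


def load_movie(path) -> StimulusMovie:
    with h5py.File(path, "r") as f:
        d = f["frames"]
        return StimulusMovie(
            d[...],
            float(d.attrs["frame_rate"]),
            float(d.attrs["pixel_pitch"]),
            str(d.attrs["modality"]),
        )
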