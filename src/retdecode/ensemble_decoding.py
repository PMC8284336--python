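"""Population template decoding of Landolt-C orientation.

The decoder asks how much pattern information the population carries,
without ever presenting the letter to the model retina directly. For each
cell, the pixelated Landolt-C movie ``s_hat`` is dotted with the cell's STA
``w`` to give a target input strength; the white-noise recording is then
scanned for the ``k`` blocks of consecutive frames ``s`` minimizing
``|w.s - w.s_hat|`` (Eq.-style matched filtering). The cell's average
firing in the 30 ms after each matched block, binned at 5 ms (6 bins),
is its expected response to the letter; concatenating all cells gives a
per-orientation template. Trials draw Poisson counts from the
true-orientation template (summed over ``n_flashes`` presentations) and are
decoded by the highest Pearson correlation against the four templates.

Three experiment axes mirror the fidelity questions: number of cells
(ranked by independent single-cell accuracy, letter fixed at 14 px),
letter size (gap resolution), and number of flashes (information
accumulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import ORIENTATIONS, LandoltSpec, StimulusMovie, generate_landolt_c
from .synthetic_retina import SpikeTrain

__all__ = [
    "ResponseTemplate",
    "DecodingResult",
    "EnsembleDecoder",
    "input_strength",
    "find_matching_blocks",
    "build_templates",
    "simulate_trial",
    "decode_trial",
    "decode_accuracy",
    "run_experiment",
]

DEFAULT_WINDOW_MS = 30.0
DEFAULT_BIN_MS = 5.0
DEFAULT_K_BLOCKS = 500


@dataclass
class ResponseTemplate:
    """Per-orientation concatenated population rate vector.

    ``rates`` holds mean spike counts per bin (bin width ``bin_ms``), cell
    by cell: length = n_cells * n_bins, all entries >= 0.
    """

    orientation: str
    rates: np.ndarray
    n_cells: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.rates.shape != (self.n_cells * self.n_bins,):
            raise ValueError("template length must be n_cells * n_bins")
        if np.any(self.rates < 0):
            raise ValueError("template rates must be nonnegative")


@dataclass
class DecodingResult:
    accuracy: float
    n_trials: int
    n_correct: int
    config: dict
    seed: int | None = None
    truths: np.ndarray | None = None
    decoded: np.ndarray | None = None


def input_strength(w: np.ndarray, block: np.ndarray) -> float:
    """Inner product of a (depth, H, W) kernel with a stimulus block."""
    w = np.asarray(w, dtype=float)
    block = np.asarray(block, dtype=float)
    if w.shape != block.shape:
        raise ValueError(f"kernel shape {w.shape} != block shape {block.shape}")
    return float(np.vdot(w, block))


def sliding_strengths(movie: StimulusMovie, w: np.ndarray, center: float | None = None) -> np.ndarray:
    """w . s for every block start; entry t is the block starting at frame t."""
    depth = w.shape[0]
    c = movie.frames.mean() if center is None else center
    ff = (movie.frames - c).reshape(movie.n_frames, -1)
    kf = np.asarray(w, dtype=float).reshape(depth, -1)
    T = movie.n_frames
    acc = np.zeros(T - depth + 1)
    for lag in range(depth):
        acc += ff[lag : T - depth + 1 + lag] @ kf[lag]
    return acc


def find_matching_blocks(
    movie: StimulusMovie,
    w: np.ndarray,
    target_strength: float,
    k: int = DEFAULT_K_BLOCKS,
    strengths: np.ndarray | None = None,
    disjoint: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """The k block start-frames minimizing |w.s - target|, ranked ascending.

    Candidate blocks stride one frame and may overlap; ``disjoint=True``
    greedily enforces non-overlapping blocks. Precomputed ``strengths``
    (from :func:`sliding_strengths`) can be passed to amortize the scan.
    """
    if strengths is None:
        strengths = sliding_strengths(movie, w)
    resid = np.abs(strengths - target_strength)
    depth = w.shape[0]
    if not disjoint:
        if k > resid.size:
            raise ValueError(f"k={k} exceeds the {resid.size} available blocks")
        order = np.argsort(resid, kind="stable")[:k]
        return order, resid[order]
    order = np.argsort(resid, kind="stable")
    starts: list[int] = []
    for t in order:
        if all(abs(t - s) >= depth for s in starts):
            starts.append(int(t))
            if len(starts) == k:
                break
    if len(starts) < k:
        raise ValueError(f"only {len(starts)} disjoint blocks available; k={k}")
    starts = np.asarray(starts)
    return starts, resid[starts]


def _binned_counts(train: SpikeTrain, bin_s: float) -> np.ndarray:
    nb = int(np.ceil(train.duration / bin_s)) + 1
    idx = np.floor(train.times / bin_s + 1e-9).astype(np.int64)
    return np.bincount(idx, minlength=nb).astype(np.float64)


def build_templates(
    kernels: list[np.ndarray],
    trains: list[SpikeTrain],
    movie: StimulusMovie,
    landolt_movies: dict[str, StimulusMovie],
    k: int = DEFAULT_K_BLOCKS,
    window_ms: float = DEFAULT_WINDOW_MS,
    bin_ms: float = DEFAULT_BIN_MS,
    strengths: list[np.ndarray] | None = None,
) -> dict[str, ResponseTemplate]:
    """Per-orientation population templates from matched white-noise blocks.

    ``kernels`` are the cells' mean-subtracted STA kernels on the
    white-noise movie that also produced ``trains``. Matching is per cell:
    each cell's own kernel defines its target strength and its k blocks.
    """
    n_bins = int(round(window_ms / bin_ms))
    bin_s = bin_ms / 1000.0
    depth = kernels[0].shape[0]
    c = float(movie.frames.mean())
    if strengths is None:
        strengths = [sliding_strengths(movie, w, center=c) for w in kernels]
    counts = [_binned_counts(tr, bin_s) for tr in trains]
    templates = {}
    for orient, lmovie in landolt_movies.items():
        tail = lmovie.frames[-depth:] - c  # the letter-bearing end of s_hat
        rows = []
        for w, s, cnt, tr in zip(kernels, strengths, counts, trains):
            target = float(np.vdot(w, tail))
            starts, _ = find_matching_blocks(movie, w, target, k, strengths=s)
            end_t = (starts + depth) * movie.dt
            b0 = np.floor(end_t / bin_s + 1e-9).astype(np.int64)
            ok = b0 + n_bins <= len(cnt)
            b0 = b0[ok]
            if b0.size == 0:
                rows.append(np.zeros(n_bins))
                continue
            resp = cnt[b0[:, None] + np.arange(n_bins)[None, :]]
            rows.append(resp.mean(axis=0))
        templates[orient] = ResponseTemplate(orient, np.concatenate(rows),
                                             len(kernels), n_bins)
    return templates


def simulate_trial(
    template: ResponseTemplate | np.ndarray, n_flashes: int = 1, seed=None
) -> np.ndarray:
    """Poisson spike counts per bin, summed over n_flashes presentations."""
    if n_flashes < 1:
        raise ValueError("n_flashes must be >= 1")
    rates = template.rates if isinstance(template, ResponseTemplate) else np.asarray(template)
    rng = np.random.default_rng(seed)
    return rng.poisson(rates * n_flashes)


def _template_matrix(templates) -> tuple[np.ndarray, list[str]]:
    if isinstance(templates, dict):
        names = [o for o in ORIENTATIONS if o in templates] or list(templates)
        mat = np.stack([np.asarray(templates[o].rates if isinstance(templates[o], ResponseTemplate)
                                   else templates[o]) for o in names])
    else:
        mat = np.asarray(templates, dtype=float)
        names = list(ORIENTATIONS[: mat.shape[0]])
    return mat, names


def decode_trial(trial: np.ndarray, templates, seed=None) -> str:
    """Orientation whose template correlates best with the trial vector.

    Ties (including zero-variance trials, which correlate with nothing) are
    broken uniformly at random from the trial's seed stream.
    """
    mat, names = _template_matrix(templates)
    rng = np.random.default_rng(seed)
    trial = np.asarray(trial, dtype=float)
    tc = trial - trial.mean()
    tn = np.linalg.norm(tc)
    mc = mat - mat.mean(axis=1, keepdims=True)
    mn = np.linalg.norm(mc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ tc) / (mn * tn)
    r = np.where(np.isfinite(r), r, -np.inf)
    if np.all(np.isinf(r)):
        return names[rng.integers(len(names))]
    best = np.flatnonzero(r == r.max())
    return names[int(rng.choice(best))]


def decode_accuracy(
    templates,
    n_trials: int = 10_000,
    n_flashes: int = 1,
    seed: int | None = None,
    keep_trials: bool = False,
) -> DecodingResult:
    """Accuracy over trials with uniformly random true orientations."""
    mat, names = _template_matrix(templates)
    rng = np.random.default_rng(seed)
    truths = rng.integers(len(names), size=n_trials)
    X = rng.poisson(mat[truths] * n_flashes).astype(np.float64)
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn = np.linalg.norm(Xc, axis=1)
    mc = mat - mat.mean(axis=1, keepdims=True)
    mn = np.linalg.norm(mc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc @ mc.T) / (Xn[:, None] * mn[None, :])
    R = np.where(np.isfinite(R), R, -np.inf)
    # random tie-break: jitter equal maxima by an infinitesimal random key
    tie_key = rng.random(R.shape)
    best = np.lexsort((tie_key, R), axis=1)[:, -1]
    all_tied = np.all(np.isinf(R), axis=1)
    if np.any(all_tied):
        best[all_tied] = rng.integers(len(names), size=int(all_tied.sum()))
    n_correct = int(np.sum(best == truths))
    return DecodingResult(
        accuracy=n_correct / n_trials,
        n_trials=n_trials,
        n_correct=n_correct,
        config={"n_flashes": n_flashes, "n_templates": len(names)},
        seed=seed,
        truths=truths if keep_trials else None,
        decoded=best if keep_trials else None,
    )


@dataclass
class EnsembleDecoder:
    """Binds a population (STA kernels + spike trains) to its white-noise movie."""

    kernels: list  # per-cell (depth, H, W) mean-subtracted STA kernels
    trains: list
    movie: StimulusMovie
    k_blocks: int = DEFAULT_K_BLOCKS
    window_ms: float = DEFAULT_WINDOW_MS
    bin_ms: float = DEFAULT_BIN_MS
    grey_levels: int = 8
    _strengths: list = field(default=None, repr=False)

    def strengths(self) -> list[np.ndarray]:
        if self._strengths is None:
            c = float(self.movie.frames.mean())
            self._strengths = [sliding_strengths(self.movie, w, center=c)
                               for w in self.kernels]
        return self._strengths

    def landolt_movies(self, size_px: int) -> dict[str, StimulusMovie]:
        H, W = self.movie.spatial_shape
        return {
            o: generate_landolt_c(
                LandoltSpec(orientation=o, size_px=size_px, canvas=(H, W),
                            grey_levels=self.grey_levels,
                            frame_rate=self.movie.frame_rate,
                            pixel_pitch=self.movie.pixel_pitch,
                            modality=self.movie.modality)
            )
            for o in ORIENTATIONS
        }

    def templates_for(self, size_px: int, cell_idx=None) -> dict[str, ResponseTemplate]:
        idx = list(range(len(self.kernels))) if cell_idx is None else list(cell_idx)
        strengths = self.strengths()
        return build_templates(
            [self.kernels[i] for i in idx],
            [self.trains[i] for i in idx],
            self.movie,
            self.landolt_movies(size_px),
            k=min(self.k_blocks, len(strengths[0]) if strengths else self.k_blocks),
            window_ms=self.window_ms,
            bin_ms=self.bin_ms,
            strengths=[strengths[i] for i in idx],
        )

    def accuracy(self, size_px: int = 14, n_flashes: int = 1,
                 n_trials: int = 10_000, seed: int | None = None,
                 cell_idx=None) -> DecodingResult:
        templates = self.templates_for(size_px, cell_idx)
        res = decode_accuracy(templates, n_trials, n_flashes, seed)
        res.config.update({"c_size_px": size_px,
                           "n_cells": len(cell_idx) if cell_idx is not None
                           else len(self.kernels)})
        return res


def rank_cells(decoder: EnsembleDecoder, c_size: int = 14,
               n_trials: int = 1000, seed: int | None = None) -> list[int]:
    """Cells ordered by independent single-cell decoding accuracy (best first)."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(decoder.kernels))]
    accs = [
        decoder.accuracy(c_size, 1, n_trials, seeds[i], cell_idx=[i]).accuracy
        for i in range(len(decoder.kernels))
    ]
    return list(np.argsort(accs)[::-1])


def run_experiment(
    decoder: EnsembleDecoder,
    axis: str,
    grid,
    n_trials: int = 10_000,
    seed: int | None = None,
    c_size: int = 14,
    n_flashes: int = 1,
) -> list[DecodingResult]:
    """Decoding accuracy along one experiment axis.

    ``axis`` is ``"n_cells"`` (cells added in rank order by independent
    single-cell accuracy; letter fixed at ``c_size``), ``"c_size"`` (all
    cells, letter size varies) or ``"n_flashes"`` (all cells, presentations
    vary).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(grid) + 1)]
    results = []
    if axis == "n_cells":
        ranked = rank_cells(decoder, c_size, n_trials=min(1000, n_trials),
                            seed=seeds[-1])
        for g, s in zip(grid, seeds):
            res = decoder.accuracy(c_size, n_flashes, n_trials, s,
                                   cell_idx=ranked[: int(g)])
            res.config["axis"] = ("n_cells", int(g))
            results.append(res)
    elif axis == "c_size":
        for g, s in zip(grid, seeds):
            res = decoder.accuracy(int(g), n_flashes, n_trials, s)
            res.config["axis"] = ("c_size", int(g))
            results.append(res)
    elif axis == "n_flashes":
        templates = decoder.templates_for(c_size)
        for g, s in zip(grid, seeds):
            res = decode_accuracy(templates, n_trials, int(g), s)
            res.config.update({"axis": ("n_flashes", int(g)), "c_size_px": c_size,
                               "n_cells": len(decoder.kernels)})
            results.append(res)
    else:
        raise ValueError(f"unknown axis: {axis!r}")
    return results
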