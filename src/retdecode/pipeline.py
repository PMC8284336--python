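"""Experiment configuration, orchestration and reporting.

One :class:`ExperimentConfig` (a nested key/value structure, YAML on disk)
describes a full experiment: stimulus, synthetic population, which stages
to run, model and noise-estimation settings, decoding axes, and a master
seed. :func:`run_pipeline` executes the requested stages in dependency
order, writes every artifact under an output directory and records a
manifest (config echo, per-stage seeds, artifact hashes, versions) so a
rerun of the same config reproduces the same outputs.

Every random draw is attributable: the master seed is expanded into one
named substream per stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .stimuli import StimulusMovie, generate_white_noise, save_movie, load_movie
from .synthetic_retina import (RetinaSpec, SpikeTrain, build_population,
                               simulate_population)
from .receptive_fields import (CellRecord, classify_polarity, compute_sta,
                               compute_snr, extract_time_course, select_cells)
from .preprocess import estimate_contamination
from .encoding_models import TrainTestSplit, fit_ln, five_fold_cv
from .noise_estimation import (build_noise_family, compute_auc, compute_ccc,
                               match_noise_ratio, select_reference_cell)
from .ensemble_decoding import EnsembleDecoder, run_experiment

__all__ = ["ExperimentConfig", "run_pipeline", "report", "demo_config",
           "save_spikes_csv", "load_spikes_csv"]

_STAGES = ("stim", "simulate", "sta", "fit", "noise", "decode", "report")


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment."""

    seed: int = 0
    stages: list = field(default_factory=lambda: list(_STAGES))
    stimulus: dict = field(default_factory=lambda: {
        "n_frames": 3600, "height": 16, "width": 16,
        "frame_rate": 30.0, "pixel_pitch": 60.0, "modality": "visual",
        "p_bright": 0.5,
    })
    population: dict = field(default_factory=lambda: {
        "preset": "LE", "n_cells": 20, "field_shape": [16, 16],
    })
    selection: dict = field(default_factory=lambda: {
        "max_contamination": 0.10, "min_snr": 3.0,
    })
    models: dict = field(default_factory=lambda: {
        "ln": True, "five_fold": False, "depth_frames": 24,
    })
    noise: dict = field(default_factory=lambda: {
        "nr_grid": [0.0, 0.25, 0.5, 0.75, 1.0], "n_seeds": 2,
    })
    decode: dict = field(default_factory=lambda: {
        "axis": "n_flashes", "grid": [1, 2, 4], "n_trials": 1000,
        "c_size": 14, "k_blocks": 200,
    })

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def demo_config(seed: int = 0) -> ExperimentConfig:
    """A small end-to-end configuration: LE-like 20-cell retina, 2 min of noise."""
    return ExperimentConfig(seed=seed)


def save_spikes_csv(trains: list[SpikeTrain], path) -> None:
    rows = [(tr.cell_id, t) for tr in trains for t in tr.times]
    pd.DataFrame(rows, columns=["cell_id", "spike_time_s"]).to_csv(path, index=False)


def load_spikes_csv(path, duration: float) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(np.sort(g["spike_time_s"].to_numpy()), duration, cell_id=cid)
        for cid, g in df.groupby("cell_id", sort=True)
    ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % 2**31


def run_pipeline(config: ExperimentConfig, outdir) -> dict:
    """Execute the configured stages; return (and write) the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "versions": {"retdecode": __version__, "numpy": np.__version__},
        "stages": {},
        "artifacts": {},
    }
    stages = [s for s in _STAGES if s in config.stages]
    movie = trains = cells = None
    stas = {}
    cell_table = None

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "seed": _stage_seed(config.seed, stage),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        for p in paths:
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)

    def need(what, value, stage):
        if value is None:
            raise RuntimeError(f"stage '{stage}' requires missing upstream artifact: {what}")
        return value

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "stim":
            s = config.stimulus
            movie = generate_white_noise(
                (s["n_frames"], s["height"], s["width"]),
                frame_rate=s["frame_rate"], p_bright=s.get("p_bright", 0.5),
                seed=_stage_seed(config.seed, stage),
                pixel_pitch=s["pixel_pitch"], modality=s["modality"])
            p = out / "movie.h5"
            save_movie(movie, p)
            record(stage, [p], t0)
        elif stage == "simulate":
            movie = need("stimulus movie", movie, stage)
            pop = dict(config.population)
            pop["field_shape"] = tuple(pop.get("field_shape", movie.spatial_shape))
            spec = RetinaSpec(**pop)
            cells = build_population(spec, seed=_stage_seed(config.seed, stage))
            trains = simulate_population(cells, movie,
                                         seed=_stage_seed(config.seed, stage) + 1)
            p = out / "spikes.csv"
            save_spikes_csv(trains, p)
            pc = out / "population.json"
            pc.write_text(json.dumps([asdict(c) for c in cells], indent=1))
            record(stage, [p, pc], t0)
        elif stage == "sta":
            movie = need("stimulus movie", movie, stage)
            trains = need("spike trains", trains, stage)
            depth = config.models.get("depth_frames", 24)
            rows = []
            records = []
            retina_type = "RCS" if config.population.get("preset") == "RCS" else "LE"
            for tr in trains:
                sta = compute_sta(tr, movie, depth)
                stas[tr.cell_id] = sta
                tc = extract_time_course(sta)
                snr = compute_snr(tc)
                pol = classify_polarity(tc, movie.modality, retina_type)
                cont = estimate_contamination(tr)
                rows.append({"cell_id": tr.cell_id, "n_spikes": tr.n_spikes,
                             "snr": snr, "polarity": pol, "contamination": cont})
                records.append(CellRecord(tr.cell_id, snr, cont, pol))
            cell_table = pd.DataFrame(rows)
            kept, audit = select_cells(records, **config.selection)
            cell_table["kept"] = cell_table["cell_id"].isin([r.cell_id for r in kept])
            p1 = out / "cells.csv"
            cell_table.to_csv(p1, index=False)
            p2 = out / "selection_audit.csv"
            audit.to_csv(p2, index=False)
            record(stage, [p1, p2], t0)
        elif stage == "fit":
            movie = need("stimulus movie", movie, stage)
            trains = need("spike trains", trains, stage)
            rows = []
            for tr in trains:
                try:
                    if config.models.get("five_fold"):
                        df = five_fold_cv(movie, tr,
                                          config.models.get("depth_frames", 24))
                        for _, r in df.iterrows():
                            rows.append({"cell_id": tr.cell_id, "model": "ln",
                                         "fold": int(r["fold"]), "r": r["r"]})
                    else:
                        from .encoding_models import _ln_fold_r
                        r = _ln_fold_r(movie, tr, TrainTestSplit(),
                                       config.models.get("depth_frames", 24))
                        rows.append({"cell_id": tr.cell_id, "model": "ln",
                                     "fold": -1, "r": r})
                except ValueError:
                    rows.append({"cell_id": tr.cell_id, "model": "ln",
                                 "fold": -1, "r": np.nan})
            p = out / "model_eval.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            record(stage, [p], t0)
        elif stage == "noise":
            movie = need("stimulus movie", movie, stage)
            trains = need("spike trains", trains, stage)
            usable = [tr for tr in trains if tr.n_spikes >= 50]
            curves = {tr.cell_id: compute_ccc(tr, movie) for tr in usable}
            aucs = {cid: compute_auc(c) for cid, c in curves.items()}
            ref_id = select_reference_cell(aucs)
            ref = next(tr for tr in usable if tr.cell_id == ref_id)
            family = build_noise_family(
                ref, movie, nr_grid=config.noise["nr_grid"],
                n_seeds=config.noise.get("n_seeds", 2),
                seed=_stage_seed(config.seed, stage))
            rows = [{"cell_id": cid, "auc": aucs[cid],
                     "nr_estimate": match_noise_ratio(aucs[cid], family),
                     "is_reference": cid == ref_id}
                    for cid in aucs]
            p = out / "noise_ratio.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            record(stage, [p], t0)
        elif stage == "decode":
            movie = need("stimulus movie", movie, stage)
            trains = need("spike trains", trains, stage)
            depth = config.models.get("depth_frames", 24)
            kernels = []
            for tr in trains:
                sta = stas.get(tr.cell_id) or compute_sta(tr, movie, depth)
                kernels.append(sta.kernel - sta.stimulus_mean)
            dec = EnsembleDecoder(kernels, trains, movie,
                                  k_blocks=config.decode.get("k_blocks", 500))
            results = run_experiment(
                dec, config.decode["axis"], config.decode["grid"],
                n_trials=config.decode.get("n_trials", 10_000),
                seed=_stage_seed(config.seed, stage),
                c_size=config.decode.get("c_size", 14))
            p = out / "decoding.csv"
            pd.DataFrame([
                {"axis": res.config["axis"][0], "value": res.config["axis"][1],
                 "accuracy": res.accuracy, "n_trials": res.n_trials,
                 "seed": res.seed}
                for res in results
            ]).to_csv(p, index=False)
            record(stage, [p], t0)
        elif stage == "report":
            paths = report(out)
            record(stage, paths, t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def report(outdir) -> list[Path]:
    """Summary tables and figures from whatever artifacts are present."""
    out = Path(outdir)
    produced: list[Path] = []
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is optional
        plt = None

    eval_csv = out / "model_eval.csv"
    if eval_csv.exists():
        df = pd.read_csv(eval_csv)
        summary = df.groupby("model")["r"].agg(["mean", "std", "count"])
        p = out / "report_model_summary.csv"
        summary.to_csv(p)
        produced.append(p)
    noise_csv = out / "noise_ratio.csv"
    if noise_csv.exists() and plt is not None:
        df = pd.read_csv(noise_csv)
        fig, axes = plt.subplots(1, 2, figsize=(8, 3))
        axes[0].hist(df["auc"], bins=15)
        axes[0].set_xlabel("AUC")
        axes[1].hist(df["nr_estimate"], bins=15)
        axes[1].set_xlabel("estimated noise ratio")
        fig.tight_layout()
        p = out / "report_noise.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        produced.append(p)
    dec_csv = out / "decoding.csv"
    if dec_csv.exists():
        df = pd.read_csv(dec_csv)
        p = out / "report_decoding.csv"
        df.to_csv(p, index=False)
        produced.append(p)
        if plt is not None:
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.plot(df["value"], df["accuracy"], "o-")
            ax.axhline(0.25, ls="--", c="grey")
            ax.set_xlabel(df["axis"].iloc[0])
            ax.set_ylabel("accuracy")
            fig.tight_layout()
            pf = out / "report_decoding.png"
            fig.savefig(pf, dpi=100)
            plt.close(fig)
            produced.append(pf)
    return produced
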