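"""End-to-end orchestration: simulate -> tfr -> detect -> features ->
propagate -> validate -> stats, with provenance and idempotent re-runs.

Every stage writes its artefacts into the run directory together with a
completion marker carrying the configuration hash and seed; re-running with
the same configuration reuses completed stages, and any change to the
configuration invalidates them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import bwave
from bwave.detect import (binarize, cluster_bursts, filter_min_size,
                          select_threshold)
from bwave.features import burst_extent, features_table
from bwave.mesh import GeodesicSolver, adjacency_distance_threshold
from bwave.preprocess import EpochArray, bandpass_filter, baseline_correct, \
    multitaper_tfr
from bwave.propagation import summarize_propagation, circ_dist
from bwave.stats import fit_vonmises_mixture
from bwave.synth import SyntheticConfig, simulate_dataset, save_dataset, \
    load_dataset
from bwave.validation import gradient_error_sweep

_STAGES = ("simulate", "tfr", "detect", "features", "propagate", "validate",
           "stats")


@dataclass
class PipelineConfig:
    """All stage parameters with the analysis defaults.

    The fixed analysis constants keep their standard values: threshold grid
    0..7 SD in 0.25 steps, R^2 gate 0.2, planarity circular-SD gate pi/4,
    x10 interpolation, 1000 surrogates, 500 split halves, 5000
    permutations, 4 mixture components.
    """

    out_dir: str = "bwave_run"
    stages: tuple = _STAGES
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    band: tuple = (13.0, 30.0)
    tfr_window: float = 1.6
    tfr_step: float = 0.2
    baseline: tuple = (-1.8, -1.1)
    d_max_override: float = None
    r2_gate: float = 0.2
    upsample_factor: int = 10
    n_surrogates: int = 1000
    n_splits: int = 500
    n_perm: int = 5000
    mixture_k: int = 4
    validate_angles_step: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            s = dict(d["synth"])
            if "freq_range_hz" in s:
                s["freq_range_hz"] = tuple(s["freq_range_hz"])
            if "directions" in s:
                s["directions"] = tuple(tuple(x) for x in s["directions"])
            d["synth"] = SyntheticConfig(**s)
        for key in ("stages", "band", "baseline"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _marker(run: Path, stage: str) -> Path:
    return run / f".{stage}.done"


def _stage_done(run: Path, stage: str, cfg_hash: str) -> bool:
    m = _marker(run, stage)
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text())["config_hash"] == cfg_hash
    except Exception:
        return False


def _mark(run: Path, stage: str, cfg: PipelineConfig) -> None:
    _marker(run, stage).write_text(json.dumps({
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "version": bwave.__version__}))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    (run / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, default=str))

    def enabled(stage):
        return stage in config.stages

    def require(path, stage):
        if not Path(path).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs missing artefact {path}; enable the "
                f"producing stage or provide it")

    if enabled("simulate") and not _stage_done(run, "simulate", h):
        ds = simulate_dataset(config.synth)
        save_dataset(ds, run / "data")
        _mark(run, "simulate", config)

    if enabled("tfr") and not _stage_done(run, "tfr", h):
        require(run / "data" / "epochs.h5", "tfr")
        ds = load_dataset(run / "data")
        epochs = EpochArray(ds.epochs, fs=ds.config.fs,
                            t_start=float(ds.times[0]))
        filtered = bandpass_filter(epochs, *config.band)
        power, freqs, times = multitaper_tfr(
            epochs, window=config.tfr_window, step=config.tfr_step,
            fmin=config.band[0], fmax=config.band[1])
        tf = baseline_correct(power, freqs, times, baseline=config.baseline)
        import h5py

        with h5py.File(run / "tfr.h5", "w") as f:
            f.create_dataset("power_db", data=tf.power)
            f.create_dataset("freqs", data=tf.freqs)
            f.create_dataset("times", data=tf.times)
            f.create_dataset("filtered", data=filtered.data)
            f.attrs["fs"] = epochs.fs
            f.attrs["t_start"] = epochs.t_start
        _mark(run, "tfr", config)

    if enabled("detect") and not _stage_done(run, "detect", h):
        require(run / "tfr.h5", "detect")
        tf, _, _ = _load_tfr(run)
        ds = load_dataset(run / "data")
        d_max = config.d_max_override or \
            adjacency_distance_threshold(ds.locations)
        thr, k = select_threshold(tf, ds.locations, d_max)
        mask = binarize(tf, thr)
        bursts = filter_min_size(cluster_bursts(mask, ds.locations, d_max))
        rows = [{"id": b.id, "epoch": b.epoch,
                 "cells": json.dumps(sorted(b.cells))} for b in bursts]
        pd.DataFrame(rows).to_csv(run / "bursts.csv", index=False)
        (run / "detect.json").write_text(json.dumps(
            {"threshold_db": thr, "k": k, "d_max_mm": d_max,
             "n_bursts": len(bursts)}))
        _mark(run, "detect", config)

    if enabled("features") and not _stage_done(run, "features", h):
        require(run / "bursts.csv", "features")
        tf, _, _ = _load_tfr(run)
        ds = load_dataset(run / "data")
        bursts = _load_bursts(run)
        feats = features_table(bursts, tf, ds.locations)
        if len(feats) >= 3:
            try:
                extent, var = burst_extent(feats)
                feats["extent"] = extent
                (run / "extent_pca.json").write_text(json.dumps(
                    {"variance_fractions": var.tolist()}))
            except ValueError:
                pass
        feats.to_csv(run / "features.csv", index=False)
        _mark(run, "features", config)

    if enabled("propagate") and not _stage_done(run, "propagate", h):
        require(run / "features.csv", "propagate")
        ds = load_dataset(run / "data")
        bursts = _load_bursts(run)
        feats = pd.read_csv(run / "features.csv")
        import h5py

        with h5py.File(run / "tfr.h5", "r") as f:
            filtered = f["filtered"][()]
            fs = float(f.attrs["fs"])
            t_start = float(f.attrs["t_start"])
        solver = GeodesicSolver(ds.mesh)
        rows = []
        for b in bursts:
            row = feats.loc[feats.burst_id == b.id]
            if not len(row):
                continue
            row = row.iloc[0]
            i0 = int(round((row.onset - t_start) * fs))
            i1 = int(round((row.offset - t_start) * fs)) + 1
            faces = b.faces
            x = filtered[b.epoch, faces, i0:i1]
            est = summarize_propagation(
                x, faces, ds.mesh, fs, row.f_centre, burst_id=b.id,
                upsample_factor=config.upsample_factor, solver=solver,
                r2_gate=config.r2_gate)
            rows.append({"id": b.id, "pattern": est.pattern,
                         "theta_deg": np.rad2deg(est.theta),
                         "r2": est.r2, "speed_mps": est.speed,
                         "speed_sd": est.speed_sd, "n_cp": est.n_cp,
                         "retained": est.retained})
        pd.DataFrame(rows).to_csv(run / "propagation.csv", index=False)
        _mark(run, "propagate", config)

    if enabled("validate") and not _stage_done(run, "validate", h):
        angles = np.arange(1, 361, config.validate_angles_step)
        table = gradient_error_sweep(
            "square", ("N",), angles=angles, area_cm2=config.synth.mesh_area_cm2,
            seed=config.seed)
        table.to_csv(run / "mesh_errors.csv", index=False)
        _mark(run, "validate", config)

    if enabled("stats") and not _stage_done(run, "stats", h):
        require(run / "propagation.csv", "stats")
        prop = pd.read_csv(run / "propagation.csv")
        out = {}
        retained = prop[prop.retained == True]  # noqa: E712
        if len(retained) >= 2 * config.mixture_k:
            theta = np.deg2rad(retained.theta_deg.to_numpy())
            mix = fit_vonmises_mixture(theta, k=config.mixture_k,
                                       seed=config.seed)
            out["mixture"] = {"mu_deg": np.rad2deg(mix.mu).tolist(),
                              "kappa": mix.kappa.tolist(),
                              "w": mix.w.tolist(),
                              "loglik": mix.loglik}
        (run / "stats.json").write_text(json.dumps(out, indent=2))
        _mark(run, "stats", config)

    return run


def _load_tfr(run: Path):
    import h5py

    from bwave.preprocess import TFPower

    with h5py.File(run / "tfr.h5", "r") as f:
        tf = TFPower(power=f["power_db"][()], freqs=f["freqs"][()],
                     times=f["times"][()])
        return tf, float(f.attrs["fs"]), float(f.attrs["t_start"])


def _load_bursts(run: Path):
    from bwave.detect import BurstSupport

    df = pd.read_csv(run / "bursts.csv")
    return [BurstSupport(epoch=int(r.epoch),
                         cells={tuple(c) for c in json.loads(r.cells)},
                         id=int(r.id))
            for r in df.itertuples()]


def report(run_dir) -> dict:
    """Summary of a completed (or partial) run: pattern-class fractions,
    pre/post counts, per-class medians, direction histogram and the fitted
    mixture."""
    run = Path(run_dir)
    out = {"warnings": []}
    feats = prop = None
    if (run / "features.csv").exists():
        feats = pd.read_csv(run / "features.csv")
    else:
        out["warnings"].append("features.csv missing")
    if (run / "propagation.csv").exists():
        prop = pd.read_csv(run / "propagation.csv")
    else:
        out["warnings"].append("propagation.csv missing")

    if feats is not None:
        counts = feats.phase.value_counts().to_dict()
        out["n_bursts"] = int(len(feats))
        out["phase_counts"] = {k: int(v) for k, v in counts.items()}
        out["median_amplitude_db"] = float(feats.amp_mean.median()) \
            if len(feats) else 0.0
    if prop is not None and len(prop):
        frac = prop.pattern.value_counts(normalize=True).to_dict()
        out["pattern_fractions"] = {k: float(v) for k, v in frac.items()}
        out["n_retained"] = int(prop.retained.sum())
        ret = prop[prop.retained == True]  # noqa: E712
        if len(ret):
            out["median_speed_mps"] = float(ret.speed_mps.median())
            hist, edges = np.histogram(
                np.deg2rad(ret.theta_deg.to_numpy()) % (2 * np.pi),
                bins=24, range=(0, 2 * np.pi))
            out["direction_histogram"] = {
                "counts": hist.tolist(),
                "bin_edges_deg": np.rad2deg(edges).tolist()}
    elif prop is not None:
        out["pattern_fractions"] = {}
        out["n_retained"] = 0
    if (run / "stats.json").exists():
        out["stats"] = json.loads((run / "stats.json").read_text())
    (run / "report.json").write_text(json.dumps(out, indent=2))
    return out


def assign_axis(theta_deg: np.ndarray, mixture_mu_deg: np.ndarray) -> np.ndarray:
    """Component index of the mixture mean circularly nearest each burst."""
    t = np.deg2rad(np.asarray(theta_deg, float))[:, None]
    mu = np.deg2rad(np.asarray(mixture_mu_deg, float))[None, :]
    return np.argmin(circ_dist(t, mu), axis=1)
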