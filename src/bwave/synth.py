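"""Synthetic meshes, planar gradients and epoched burst time series.

The generator emulates the statistics of source-space sensorimotor
recordings: an irregular cortical-like patch of ~60 cm^2 sampled at roughly
27 locations per cm^2, 1/f background noise, and transient beta bursts
(~240 ms long, ~3 Hz wide, ~6 cm^2 across) whose waveform sweeps across the
patch as a planar travelling wave at a configurable direction and speed
(~2-3 m/s). Every planted burst is recorded in a ground-truth table so that
detection, feature and propagation stages can be scored against known
answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from bwave.mesh import TriMesh, SurfaceLocations, face_geometry, save_mesh, load_mesh

# locations per cm^2 at sampling level N, matching the density of a
# down-sampled cortical surface mesh
_DENSITY_N = 27.0
_SAMPLING_FACTORS = {"N_half": 0.5, "N": 1.0, "N_double": 2.0}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the observed scale of sensorimotor beta bursts:
    238 +- 23 ms duration, 3 Hz spectral spread, 6 cm^2 spatial width,
    propagation at ~2.8 m/s along two orthogonal axes (66/248 and 142/324
    degrees), and a higher burst rate after the movement (t=0) than before.
    """

    mesh_kind: str = "cortical_like"        # square | circle | random | cortical_like
    sampling: str = "N"                     # N_half | N | N_double
    mesh_area_cm2: float = 60.0
    t_start: float = -2.0                   # s, relative to the event
    t_stop: float = 2.0
    fs: float = 300.0                       # Hz
    n_epochs: int = 10
    burst_rate_pre: float = 0.5             # bursts / s before t=0
    burst_rate_post: float = 0.9            # bursts / s after t=0
    spanning_frac: float = 0.05             # fraction of extra bursts crossing t=0
    duration_mean_ms: float = 238.0
    duration_sd_ms: float = 23.0
    freq_range_hz: tuple = (15.0, 28.0)     # burst centre frequency drawn uniformly
    freq_spread_hz: float = 3.0
    width_cm2: float = 6.0
    directions: tuple = ((66.0, 8.0), (248.0, 8.0), (142.0, 8.0), (324.0, 8.0))
    # (mean deg, von Mises concentration) per component, equal weights
    speed_mps: float = 2.8
    burst_amp: float = 1.0
    noise_std: float = 0.25                 # per-face 1/f noise SD
    common_noise_frac: float = 0.3          # spatially common 1/f, fraction of noise_std
    noise_exponent: float = 1.0             # 1/f^exponent power spectrum
    avoid_overlap: bool = False             # keep bursts temporally disjoint
    seed: int = 0

    def __post_init__(self):
        if not (self.t_start < 0.0 < self.t_stop):
            raise ValueError("epoch window must contain the event at t=0")
        for name in ("duration_mean_ms", "width_cm2", "speed_mps", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burst_rate_pre < 0 or self.burst_rate_post < 0:
            raise ValueError("burst rates must be non-negative")

    def times(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) * self.fs)) + 1
        return self.t_start + np.arange(n) / self.fs


@dataclass
class GroundTruthBurst:
    """One planted burst: where it is and how it travels."""

    epoch: int
    onset: float                    # s
    offset: float                   # s
    freq_lo: float                  # Hz
    freq_hi: float
    faces: np.ndarray               # face indices of the spatial disc
    theta: float                    # propagation direction, rad in [0, 2pi)
    speed: float                    # m/s
    amplitude: float
    centre_face: int

    def __post_init__(self):
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size == 0:
            raise ValueError("burst support must be non-empty")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        self.theta = float(np.mod(self.theta, 2 * np.pi))

    def support_cells(self, times: np.ndarray, freqs: np.ndarray,
                      window: float = 0.0, freq_pad: float = 0.0) -> set:
        """Rasterise to (time index, frequency index, face) cells on a TF grid.

        ``window`` (s) widens the temporal footprint by half the spectrogram
        analysis window on each side: a timestep is covered whenever its
        window overlaps the burst, which is the support a windowed power
        estimate can actually resolve. ``freq_pad`` (Hz) likewise widens the
        band for the spectral leakage of a burst much shorter than 1 s.
        """
        half_w = window / 2.0
        ti = np.flatnonzero((times >= self.onset - half_w)
                            & (times <= self.offset + half_w))
        fi = np.flatnonzero((freqs >= self.freq_lo - 0.5 - freq_pad)
                            & (freqs <= self.freq_hi + 0.5 + freq_pad))
        return {(int(t), int(f), int(s)) for t in ti for f in fi for s in self.faces}


@dataclass
class SyntheticDataset:
    mesh: TriMesh
    locations: SurfaceLocations
    epochs: np.ndarray              # (n_epochs, n_faces, n_samples)
    times: np.ndarray               # s
    truth: list
    config: SyntheticConfig = field(repr=False, default=None)

    def __post_init__(self):
        e, l, t = self.epochs.shape
        if l != self.mesh.n_faces or t != len(self.times):
            raise ValueError("epoch array inconsistent with mesh / time axis")


# ---------------------------------------------------------------------------
# Meshes

def make_mesh(kind: str, sampling: str = "N", seed: int = 0,
              area_cm2: float = 60.0) -> TriMesh:
    """Build a test surface of the requested kind and sampling density.

    Density at level ``N`` is ~27 face centres per cm^2; ``N_half`` and
    ``N_double`` halve and double the location count. ``square``,
    ``circle`` and ``random`` are planar (z=0); ``cortical_like`` is a
    jittered, gently undulating patch.
    """
    if sampling not in _SAMPLING_FACTORS:
        raise ValueError(f"unknown sampling level {sampling!r}")
    density = _DENSITY_N * _SAMPLING_FACTORS[sampling]  # faces / cm^2
    density_mm = density / 100.0                        # faces / mm^2
    rng = np.random.default_rng(seed)

    if kind == "square":
        return _square_mesh(area_cm2, density_mm, name=f"square_{sampling}")
    if kind == "cortical_like":
        return _cortical_mesh(area_cm2, density_mm, rng,
                              name=f"cortical_{sampling}")
    if kind == "circle":
        return _disk_mesh(area_cm2, density_mm, name=f"circle_{sampling}")
    if kind == "random":
        return _random_mesh(area_cm2, density_mm, rng,
                            name=f"random_{sampling}")
    raise ValueError(f"unknown mesh kind {kind!r}")


def _grid(area_cm2, density_mm):
    side = np.sqrt(area_cm2 * 100.0)
    h = np.sqrt(2.0 / density_mm)           # 2 faces per grid cell
    m = max(2, int(round(side / h)) + 1)
    xs = np.linspace(0, side, m)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    return xx, yy, m


def _grid_faces(m):
    idx = np.arange(m * m).reshape(m, m)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[:-1, 1:].ravel()
    d = idx[1:, 1:].ravel()
    return np.vstack([np.column_stack([a, b, d]), np.column_stack([a, d, c])])


def _square_mesh(area_cm2, density_mm, name):
    xx, yy, m = _grid(area_cm2, density_mm)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(m * m)])
    return TriMesh(verts, _grid_faces(m), name=name)


def _cortical_mesh(area_cm2, density_mm, rng, name, jitter=0.22,
                   fold_amp=1.0, fold_wavelength=30.0):
    # gentle undulation emulating an inflated cortical patch (the surface on
    # which directions are fitted), with irregular in-plane sampling
    xx, yy, m = _grid(area_cm2, density_mm)
    h = xx[1, 0] - xx[0, 0]
    x = xx.ravel() + rng.normal(0, jitter * h, m * m)
    y = yy.ravel() + rng.normal(0, jitter * h, m * m)
    z = fold_amp * np.sin(2 * np.pi * x / fold_wavelength) * \
        np.sin(2 * np.pi * y / fold_wavelength)
    verts = np.column_stack([x, y, z])
    return TriMesh(verts, _grid_faces(m), name=name)


def _delaunay_mesh(pts, name):
    tri = Delaunay(pts)
    faces = tri.simplices
    a, b, c = pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]]
    u, v = b - a, c - a
    area2 = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    faces = faces[area2 > 1e-9]
    verts = np.column_stack([pts, np.zeros(len(pts))])
    return TriMesh(verts, faces, name=name)


def _disk_mesh(area_cm2, density_mm, name):
    r = np.sqrt(area_cm2 * 100.0 / np.pi)
    n_pts = max(8, int(round(area_cm2 * 100.0 * density_mm / 2.0)))
    # sunflower layout: even coverage of the disk
    k = np.arange(1, n_pts + 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    rad = r * np.sqrt((k - 0.5) / n_pts)
    ang = k * golden
    pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    return _delaunay_mesh(pts, name)


def _random_mesh(area_cm2, density_mm, rng, name):
    side = np.sqrt(area_cm2 * 100.0)
    n_pts = max(8, int(round(area_cm2 * 100.0 * density_mm / 2.0)))
    pts = rng.uniform(0, side, size=(n_pts, 2))
    return _delaunay_mesh(pts, name)


# ---------------------------------------------------------------------------
# Gradients

def make_gradient_field(mesh: TriMesh, angle_deg: float,
                        speed_mps: float) -> np.ndarray:
    """Noise-free planar latency field (ms) sampled at the face centres.

    latency(face) = (cos(theta) x + sin(theta) y) / v, with coordinates in mm
    and v in m/s (= mm/ms): latency increases along the propagation direction.
    """
    if speed_mps <= 0:
        raise ValueError("speed must be positive")
    theta = np.deg2rad(angle_deg)
    centres = mesh.vertices[mesh.faces].mean(axis=1)
    return (np.cos(theta) * centres[:, 0] + np.sin(theta) * centres[:, 1]) / speed_mps


# ---------------------------------------------------------------------------
# Noise and bursts

def _one_over_f_noise(rng, shape, n_samples, fs, exponent):
    """Coloured noise with power spectrum ~ 1/f^exponent, unit SD."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1) * gain
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _draw_direction(rng, directions):
    mu_deg, kappa = directions[rng.integers(len(directions))]
    return np.mod(rng.vonmises(np.deg2rad(mu_deg), kappa), 2 * np.pi)


def simulate_dataset(config: SyntheticConfig,
                     mesh: TriMesh | None = None) -> SyntheticDataset:
    """Generate epoched source time series with known planted bursts.

    Each burst is a Hann-windowed sinusoid at its centre frequency whose
    entire waveform is delayed at each face by the planar latency field of
    the burst's direction and speed, tapered spatially by a raised-cosine
    disc. Independent 1/f noise is added at every face, plus a small
    spatially common 1/f component.
    """
    rng = np.random.default_rng(config.seed)
    if mesh is None:
        mesh = make_mesh(config.mesh_kind, config.sampling,
                         seed=int(rng.integers(2**31)),
                         area_cm2=config.mesh_area_cm2)
    locations = face_geometry(mesh)
    centres = locations.centres
    total_area_cm2 = locations.areas.sum() / 100.0
    if config.width_cm2 > total_area_cm2:
        raise ValueError("burst spatial width exceeds the ROI area")

    times = config.times()
    nt = len(times)
    nf = mesh.n_faces
    tree = cKDTree(centres[:, :2])
    # width_cm2 is the nominal burst footprint; the raised-cosine spatial
    # taper reaches zero at 1.5x that radius so that the detectable support
    # at ordinary thresholds matches the nominal width
    disc_r = np.sqrt(config.width_cm2 * 100.0 / np.pi)   # mm
    outer_r = 1.5 * disc_r

    epochs = np.zeros((config.n_epochs, nf, nt), dtype=np.float64)
    truth: list[GroundTruthBurst] = []

    for ep in range(config.n_epochs):
        noise = _one_over_f_noise(rng, (nf,), nt, config.fs,
                                  config.noise_exponent) * config.noise_std
        common = _one_over_f_noise(rng, (), nt, config.fs,
                                   config.noise_exponent)
        epochs[ep] = noise + config.common_noise_frac * config.noise_std * common

        # burst times: Poisson counts pre / post, plus optional spanning bursts
        n_pre = rng.poisson(config.burst_rate_pre * (-config.t_start))
        n_post = rng.poisson(config.burst_rate_post * config.t_stop)
        n_span = rng.poisson(config.spanning_frac * (n_pre + n_post))
        phases = ["pre"] * n_pre + ["post"] * n_post + ["span"] * n_span

        for phase in phases:
            dur_s = max(0.1, rng.normal(config.duration_mean_ms,
                                        config.duration_sd_ms) / 1000.0)
            half = dur_s / 2.0
            if phase == "pre":
                lo, hi = config.t_start + half, -half
            elif phase == "post":
                lo, hi = half, config.t_stop - half
            else:
                lo, hi = -half * 0.9, half * 0.9
            if lo >= hi:
                continue
            tc = rng.uniform(lo, hi)
            if config.avoid_overlap:
                placed = [(b.onset, b.offset) for b in truth if b.epoch == ep]
                ok = False
                for _ in range(20):
                    if all(tc + half < on or tc - half > off
                           for on, off in placed):
                        ok = True
                        break
                    tc = rng.uniform(lo, hi)
                if not ok:
                    continue
            f0 = rng.uniform(*config.freq_range_hz)
            theta = _draw_direction(rng, config.directions)
            cf = int(rng.integers(nf))
            disc = np.asarray(tree.query_ball_point(centres[cf, :2], outer_r),
                              dtype=np.int64)
            dx = centres[disc, 0] - centres[cf, 0]
            dy = centres[disc, 1] - centres[cf, 1]
            d = np.sqrt(dx**2 + dy**2)
            core = disc[d < disc_r]          # nominal (truth) support
            if core.size < 3:
                continue

            # per-face latency of the travelling waveform, in seconds
            lat_s = (np.cos(theta) * dx + np.sin(theta) * dy) \
                / config.speed_mps / 1000.0
            spatial = 0.5 * (1.0 + np.cos(np.pi * np.minimum(d / outer_r, 1.0)))

            tau = times[None, :] - tc - lat_s[:, None]
            env = np.where(np.abs(tau) <= half,
                           0.5 * (1.0 + np.cos(np.pi * tau / half)), 0.0)
            wave = env * np.cos(2 * np.pi * f0 * tau)
            epochs[ep, disc] += config.burst_amp * spatial[:, None] * wave

            truth.append(GroundTruthBurst(
                epoch=ep, onset=tc - half, offset=tc + half,
                freq_lo=f0 - config.freq_spread_hz / 2.0,
                freq_hi=f0 + config.freq_spread_hz / 2.0,
                faces=core, theta=theta, speed=config.speed_mps,
                amplitude=config.burst_amp, centre_face=cf))

    return SyntheticDataset(mesh=mesh, locations=locations, epochs=epochs,
                            times=times, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Serialisation

def save_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write a dataset as HDF5 signals + OFF mesh + JSON truth/config."""
    import h5py

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_mesh(ds.mesh, out / "mesh.off")
    with h5py.File(out / "epochs.h5", "w") as f:
        f.create_dataset("epochs", data=ds.epochs)
        f.create_dataset("times", data=ds.times)
        f.attrs["fs"] = ds.config.fs if ds.config else 1.0 / np.diff(ds.times).mean()
    truth = [
        {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in asdict(b).items()}
        for b in ds.truth
    ]
    (out / "truth.json").write_text(json.dumps(truth))
    if ds.config is not None:
        cfg = asdict(ds.config)
        (out / "config.json").write_text(json.dumps(cfg))


def load_dataset(in_dir) -> SyntheticDataset:
    import h5py

    src = Path(in_dir)
    mesh = load_mesh(src / "mesh.off")
    with h5py.File(src / "epochs.h5", "r") as f:
        epochs = f["epochs"][()]
        times = f["times"][()]
    truth = [GroundTruthBurst(**{**b, "faces": np.asarray(b["faces"])})
             for b in json.loads((src / "truth.json").read_text())]
    config = None
    cfg_path = src / "config.json"
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        raw["freq_range_hz"] = tuple(raw["freq_range_hz"])
        raw["directions"] = tuple(tuple(d) for d in raw["directions"])
        config = SyntheticConfig(**raw)
    return SyntheticDataset(mesh=mesh, locations=face_geometry(mesh),
                            epochs=epochs, times=times, truth=truth,
                            config=config)
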