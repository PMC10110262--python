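"""Per-burst travelling-wave direction and speed estimation.

For each burst the band-limited source time series of its faces are
sign-aligned, Fourier-interpolated (x10), and reduced to the critical
points of the spatially averaged oscillation (peak, trough and the two
zero-crossing midpoints of every cycle). At each critical point the
relative latency of every face - the time of its own same-type critical
point minus that of the spatial average - is regressed on the x and y face
coordinates by two simple linear regressions; the coefficient pair gives
the propagation direction (towards increasing latency) and the mean of the
two R^2 values the planarity strength. Directions across critical points
are clustered spectrally: a single tight cluster (circular SD < pi/4) is a
planar wave, otherwise the pattern is complex. Speed is the geodesic
distance between the earliest and latest face divided by their latency
difference; with mm and ms this is numerically m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.cluster import SpectralClustering

from bwave.mesh import TriMesh, GeodesicSolver, _get_solver

R2_GATE = 0.2
PLANAR_SD_GATE = np.pi / 4


@dataclass
class CriticalPoint:
    time_ms: float
    kind: str                       # peak | trough | rise-mid | fall-mid
    latencies: np.ndarray = field(repr=False, default=None)  # ms, NaN = missing
    theta: float = np.nan           # rad in [0, 2pi)
    r2: float = np.nan              # mean of the two regression R^2s
    speed: float = np.nan           # m/s


@dataclass
class PropagationEstimate:
    burst_id: int
    pattern: str                    # planar | complex_spread | complex_multicluster
    theta: float                    # circular mean over critical points, rad
    r2: float
    speed: float                    # m/s, mean over critical points
    speed_sd: float
    n_cp: int
    retained: bool
    cps: list = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# circular helpers

def circ_mean(angles: np.ndarray) -> float:
    return float(np.mod(np.angle(np.exp(1j * np.asarray(angles)).mean()), 2 * np.pi))


def circ_r(angles: np.ndarray) -> float:
    return float(np.abs(np.exp(1j * np.asarray(angles)).mean()))


def circ_sd(angles: np.ndarray) -> float:
    """Angular deviation sqrt(2 (1 - R))."""
    return float(np.sqrt(2.0 * (1.0 - circ_r(angles))))


def circ_dist(a, b):
    """Absolute circular distance in radians, in [0, pi]."""
    return np.abs(np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b)))))


# ---------------------------------------------------------------------------
# stages

def align_signs(x: np.ndarray, max_iter: int = 50):
    """Resolve per-location sign ambiguity of beamformed series.

    Greedy: starting from the highest-variance location, repeatedly flip any
    location whose correlation with the running mean is negative until no
    flips remain. Returns ``(aligned, signs)``; the result is defined up to
    one global sign.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (locations, samples) array with >= 2 rows")
    n = x.shape[0]
    signs = np.ones(n)
    var = x.var(axis=1)
    if np.all(var == 0):
        return x.copy(), signs
    seed = int(np.argmax(var))
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    xn = xc / norm[:, None]
    # initialise against the seed, then refine against the running mean
    corr_seed = xn @ xn[seed]
    init_flip = (corr_seed < 0) & (var > 0)
    signs[init_flip] = -1
    for _ in range(max_iter):
        mean = (signs[:, None] * xn).mean(axis=0)
        corr = xn @ mean
        flips = (signs * corr < 0) & (np.arange(n) != seed) & (var > 0)
        if not flips.any():
            break
        signs[flips] *= -1
    return x * signs[:, None], signs


def upsample(x: np.ndarray, factor: int = 10) -> np.ndarray:
    """Band-limited (Fourier) resampling along the last axis."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    return sps.resample(x, x.shape[-1] * factor, axis=-1)


_CYCLE_AFTER = {"peak": "fall-mid", "fall-mid": "trough",
                "trough": "rise-mid", "rise-mid": "peak"}


def find_critical_points(x: np.ndarray, fs: float):
    """Critical points of a band-limited series: list of (time_ms, kind).

    Peaks and troughs are local extrema of the series; midpoints are the
    zero crossings of the mean-removed series between consecutive opposite
    extrema, typed rise (trough to peak) or fall (peak to trough).
    """
    x = np.asarray(x, dtype=float)
    xm = x - x.mean()
    peaks, _ = sps.find_peaks(xm)
    troughs, _ = sps.find_peaks(-xm)
    ext = sorted([(int(i), "peak") for i in peaks] +
                 [(int(i), "trough") for i in troughs])
    if len(ext) < 2:
        return []
    out = []
    for (i0, k0), (i1, k1) in zip(ext[:-1], ext[1:]):
        out.append((i0 * 1000.0 / fs, k0))
        if k0 == k1:
            continue
        seg = xm[i0:i1 + 1]
        sign_change = np.flatnonzero(np.diff(np.signbit(seg)))
        if sign_change.size:
            j = int(sign_change[0]) + i0
            # linear interpolation of the crossing time
            if xm[j + 1] != xm[j]:
                frac = -xm[j] / (xm[j + 1] - xm[j])
            else:
                frac = 0.0
            t = (j + frac) * 1000.0 / fs
            out.append((t, "fall-mid" if k0 == "peak" else "rise-mid"))
    out.append((ext[-1][0] * 1000.0 / fs, ext[-1][1]))
    return out


def _critical_times_by_kind(x: np.ndarray, fs: float) -> list:
    """Per-location dict: kind -> sorted times (ms) of its critical points."""
    out = []
    for row in np.atleast_2d(x):
        d: dict[str, list] = {}
        for t, k in find_critical_points(row, fs):
            d.setdefault(k, []).append(t)
        out.append({k: np.asarray(v) for k, v in d.items()})
    return out


def relative_latencies(x: np.ndarray, cp_time_ms: float, cp_kind: str,
                       fs: float, period_ms: float,
                       own_times: list = None) -> np.ndarray:
    """Per-location latency (ms) of one critical point of the spatial average.

    For each location, the same-type critical point of its own series
    nearest in time to the reference, within +- half a period; locations
    with no match are NaN. ``own_times`` may carry the per-location critical
    points precomputed by ``_critical_times_by_kind`` to avoid recomputing
    them for every reference point.
    """
    x = np.asarray(x, dtype=float)
    if own_times is None:
        own_times = _critical_times_by_kind(x, fs)
    lat = np.full(len(own_times), np.nan)
    half = period_ms / 2.0
    for i, d in enumerate(own_times):
        own = d.get(cp_kind)
        if own is None or own.size == 0:
            continue
        j = int(np.argmin(np.abs(own - cp_time_ms)))
        if np.abs(own[j] - cp_time_ms) <= half:
            lat[i] = own[j] - cp_time_ms
    return lat


def fit_direction(latencies: np.ndarray, coords: np.ndarray):
    """Planar gradient fit: two simple regressions of latency on x and y.

    Returns ``(theta, r2)`` where theta in [0, 2pi) points towards
    increasing latency (the propagation direction) and r2 is the mean of the
    two coefficients of determination.
    """
    latencies = np.asarray(latencies, dtype=float)
    coords = np.asarray(coords, dtype=float)
    ok = np.isfinite(latencies)
    lat = latencies[ok]
    xy = coords[ok, :2]
    if lat.size < 3:
        raise ValueError("need >= 3 non-missing latencies")
    if np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
        raise ValueError("collinear coordinates")
    slopes = np.empty(2)
    r2 = np.empty(2)
    lc = lat - lat.mean()
    ss_tot = (lc**2).sum()
    for d in range(2):
        c = xy[:, d] - xy[:, d].mean()
        b = (c @ lc) / (c @ c)
        slopes[d] = b
        resid = lc - b * c
        r2[d] = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    theta = float(np.mod(np.arctan2(slopes[1], slopes[0]), 2 * np.pi))
    return theta, float(r2.mean())


def cluster_directions(thetas: np.ndarray, k_max: int = 3, seed: int = 0):
    """Spectral clustering of critical-point directions and pattern class.

    The affinity is a Gaussian kernel on circular distance; the number of
    clusters in {1..k_max} is chosen by the largest eigengap of the
    normalised Laplacian. One tight cluster (circular SD < pi/4) is
    ``planar``; one loose cluster is ``complex_spread``; several clusters
    are ``complex_multicluster``. Returns ``(labels, pattern)``.
    """
    thetas = np.asarray(thetas, dtype=float)
    n = thetas.size
    if n < 2:
        raise ValueError("need >= 2 critical-point directions")
    d = circ_dist(thetas[:, None], thetas[None, :])
    sigma = np.pi / 4
    aff = np.exp(-(d**2) / (2 * sigma**2))
    deg = aff.sum(axis=1)
    lap = np.eye(n) - aff / np.sqrt(np.outer(deg, deg))
    evals = np.sort(np.linalg.eigvalsh(lap))
    kk = min(k_max, n - 1)
    gaps = np.diff(evals[:kk + 1])
    k = int(np.argmax(gaps)) + 1
    if k == 1:
        labels = np.zeros(n, dtype=int)
        pattern = "planar" if circ_sd(thetas) < PLANAR_SD_GATE else "complex_spread"
    else:
        sc = SpectralClustering(n_clusters=k, affinity="precomputed",
                                random_state=seed, assign_labels="discretize")
        labels = sc.fit_predict(aff)
        pattern = "complex_multicluster"
    return labels, pattern


def estimate_speed(latencies: np.ndarray, mesh: TriMesh,
                   faces: np.ndarray,
                   solver: GeodesicSolver | None = None) -> float:
    """Propagation speed (m/s) at one critical point.

    Geodesic distance (mm) between the faces with the largest and smallest
    relative latency divided by their latency difference (ms).
    """
    latencies = np.asarray(latencies, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    ok = np.isfinite(latencies)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing latencies")
    lat = latencies[ok]
    f = faces[ok]
    i_min, i_max = int(np.argmin(lat)), int(np.argmax(lat))
    dt = lat[i_max] - lat[i_min]
    if dt <= 0:
        raise ValueError("zero latency range: speed undefined")
    if solver is None:
        solver = _get_solver(mesh)
    dist = solver.distance(int(f[i_min]), int(f[i_max]))
    return float(dist / dt)


def summarize_propagation(x: np.ndarray, faces: np.ndarray, mesh: TriMesh,
                          fs: float, f_centre: float, burst_id: int = -1,
                          upsample_factor: int = 10,
                          solver: GeodesicSolver | None = None,
                          presigned: bool = False,
                          r2_gate: float = R2_GATE) -> PropagationEstimate:
    """Full per-burst propagation estimate.

    ``x`` is the (faces, samples) band-limited burst series; ``faces`` the
    matching face indices. Runs sign alignment, x10 interpolation, critical
    points of the spatial average, per-critical-point latency regression and
    speed, then direction clustering. The burst is retained when the pattern
    is planar and the mean R^2 passes the gate.
    """
    x = np.asarray(x, dtype=float)
    if solver is None:
        solver = _get_solver(mesh)
    aligned = x if presigned else align_signs(x)[0]
    up = upsample(aligned, upsample_factor)
    fs_up = fs * upsample_factor
    mean_ts = up.mean(axis=0)
    cps_raw = find_critical_points(mean_ts, fs_up)
    # only measure latencies where the averaged oscillation is actually
    # present: drop critical points in the low-envelope tails
    env = np.abs(sps.hilbert(mean_ts - mean_ts.mean()))
    if env.max() > 0:
        gate = 0.2 * env.max()
        cps_raw = [(t, k) for t, k in cps_raw
                   if env[min(len(env) - 1, int(round(t * fs_up / 1000.0)))] >= gate]
    period_ms = 1000.0 / f_centre
    centres = mesh.vertices[mesh.faces].mean(axis=1)
    coords = centres[np.asarray(faces, dtype=np.int64)]

    own = _critical_times_by_kind(up, fs_up)
    cps = []
    for t_ms, kind in cps_raw:
        lat = relative_latencies(up, t_ms, kind, fs_up, period_ms, own_times=own)
        cp = CriticalPoint(time_ms=t_ms, kind=kind, latencies=lat)
        try:
            cp.theta, cp.r2 = fit_direction(lat, coords)
        except ValueError:
            cps.append(cp)
            continue
        try:
            cp.speed = estimate_speed(lat, mesh, faces, solver=solver)
        except ValueError:
            pass
        cps.append(cp)

    usable = [c for c in cps if np.isfinite(c.theta)]
    if len(usable) < 2:
        return PropagationEstimate(burst_id=burst_id, pattern="unestimable",
                                   theta=np.nan, r2=np.nan, speed=np.nan,
                                   speed_sd=np.nan, n_cp=len(usable),
                                   retained=False, cps=cps)
    thetas = np.array([c.theta for c in usable])
    _, pattern = cluster_directions(thetas)
    r2 = float(np.mean([c.r2 for c in usable]))
    speeds = np.array([c.speed for c in usable if np.isfinite(c.speed)])
    return PropagationEstimate(
        burst_id=burst_id, pattern=pattern, theta=circ_mean(thetas), r2=r2,
        speed=float(speeds.mean()) if speeds.size else np.nan,
        speed_sd=float(speeds.std()) if speeds.size else np.nan,
        n_cp=len(usable),
        retained=(pattern == "planar" and r2 >= r2_gate),
        cps=cps)
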