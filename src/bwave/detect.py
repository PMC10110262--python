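"""Threshold selection, binarisation and 5D burst clustering.

A burst is a connected set of suprathreshold (time, frequency, location)
cells within one epoch. Connectivity is defined in three stages: (1)
time-frequency cells with at least one "on" location are clustered with
eight-connectivity; (2) within each on cell, locations are clustered by
single linkage with radius d_max (the largest adjacent-face centre
distance); (3) spatial clusters in eight-adjacent time-frequency cells are
merged when they share at least one face. The equivalent flat formulation
used here is a union-find over on-cells with two link rules: same
time-frequency cell and centre distance < d_max, or same face and
eight-adjacent time-frequency cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from bwave.mesh import SurfaceLocations
from bwave.preprocess import TFPower


@dataclass
class BinaryMask:
    """Suprathreshold occupancy: (epochs, freqs, timesteps, locations)."""

    on: np.ndarray
    threshold: float            # dB
    k: float                    # multiples of SD above the median

    def __post_init__(self):
        self.on = np.asarray(self.on, dtype=bool)
        if self.on.ndim != 4:
            raise ValueError("mask must be (epochs, freqs, times, locations)")


@dataclass
class BurstSupport:
    """One burst: its epoch and set of (timestep, frequency, location) cells."""

    epoch: int
    cells: frozenset            # of (t_idx, f_idx, loc_idx)
    id: int = -1

    def __post_init__(self):
        self.cells = frozenset(tuple(map(int, c)) for c in self.cells)
        if not self.cells:
            raise ValueError("burst support must be non-empty")

    @property
    def timesteps(self) -> np.ndarray:
        return np.unique([c[0] for c in self.cells])

    @property
    def freq_bins(self) -> np.ndarray:
        return np.unique([c[1] for c in self.cells])

    @property
    def faces(self) -> np.ndarray:
        return np.unique([c[2] for c in self.cells])


# ---------------------------------------------------------------------------
# Thresholding

def threshold_grid(k_max: float = 7.0, k_step: float = 0.25) -> np.ndarray:
    """Candidate thresholds in SD multiples above the median: 0, 0.25, ..., 7."""
    return np.arange(0.0, k_max + k_step / 2, k_step)


def select_threshold(tf: TFPower, locations: SurfaceLocations = None,
                     d_max: float = None, centre: str = "median",
                     objective: str = "burst_count"):
    """Pick the session threshold maximising the power-burst correlation.

    Candidates run from the centre (median by default, mean optionally) of
    all in-scope power values to centre + 7 SD in steps of 0.25 SD. For
    each candidate a per-epoch burst measure is correlated across epochs
    with the per-epoch mean power, and the candidate with the highest
    Pearson correlation wins; ties go to the lower threshold.

    The default measure (``objective="burst_count"``, requires
    ``locations`` and ``d_max``) is the per-epoch number of bursts after 5D
    clustering and the minimum-size filter: it penalises both low
    thresholds (everything merges into one event) and high ones (events
    shrink below the minimum size), so the correlation peaks where
    burst-like activity is actually segmented. ``objective="occupancy"``
    (the per-epoch suprathreshold fraction) needs no geometry but is
    monotone with mean power.

    Returns ``(threshold_db, k)``.
    """
    if tf.power.shape[0] < 10:
        raise ValueError("threshold selection needs at least 10 epochs")
    if objective == "burst_count" and (locations is None or d_max is None):
        raise ValueError("burst_count objective needs locations and d_max")
    vals = tf.power.ravel()
    sd = vals.std()
    if sd == 0:
        raise ValueError("constant power array: threshold undefined")
    c = np.median(vals) if centre == "median" else vals.mean()
    per_epoch_power = tf.power.mean(axis=(1, 2, 3))
    if per_epoch_power.std() == 0:
        raise ValueError("no across-epoch power variance")

    n_epochs = tf.power.shape[0]
    best = None
    for k in threshold_grid():
        thr = c + k * sd
        mask = tf.power > thr
        if objective == "occupancy":
            measure = mask.mean(axis=(1, 2, 3))
        else:
            bursts = filter_min_size(
                cluster_bursts(BinaryMask(mask, thr, k), locations, d_max))
            measure = np.bincount([b.epoch for b in bursts],
                                  minlength=n_epochs).astype(float)
        if measure.min() == measure.max():  # degenerate: all-on/off/constant
            continue
        r = pearsonr(per_epoch_power, measure)[0]
        if best is None or r > best[0] + 1e-12:
            best = (r, thr, k)
    if best is None:
        raise ValueError("all candidate thresholds degenerate")
    return float(best[1]), float(best[2])


def binarize(tf: TFPower, threshold: float) -> BinaryMask:
    """Cell on iff baseline-corrected power exceeds the threshold."""
    if not np.isfinite(threshold):
        on = tf.power > threshold  # +-inf behave as all-off / all-on
    else:
        on = tf.power > threshold
    return BinaryMask(on=on, threshold=float(threshold), k=np.nan)


# ---------------------------------------------------------------------------
# Clustering

def cluster_bursts(mask: BinaryMask, locations: SurfaceLocations,
                   d_max: float) -> list:
    """Partition the on-cells of every epoch into bursts (5D clustering)."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if mask.on.shape[3] != locations.n_faces:
        raise ValueError("mask / locations shape mismatch")
    # location pairs linkable within one TF cell (strictly closer than d_max)
    tree = cKDTree(locations.centres)
    pairs = tree.query_pairs(d_max, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(locations.centres[pairs[:, 0]]
                           - locations.centres[pairs[:, 1]], axis=1)
        pairs = pairs[d < d_max]
    bursts = []
    next_id = 0
    for ep in range(mask.on.shape[0]):
        for cells in _cluster_epoch(mask.on[ep], pairs):
            bursts.append(BurstSupport(epoch=ep, cells=cells, id=next_id))
            next_id += 1
    return bursts


def _cluster_epoch(on: np.ndarray, loc_pairs: np.ndarray):
    """Cluster one epoch's (freqs, times, locations) boolean array.

    Connected components over on-cells with edges (a) same TF cell and
    spatially linkable locations, (b) same location and eight-adjacent TF
    cells.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = int(on.sum())
    if n == 0:
        return []
    ids = np.full(on.shape, -1, dtype=np.int64)
    ids[on] = np.arange(n)

    rows, cols = [], []
    # rule (b): eight-connectivity across the (frequency, time) plane
    nf, nt, _ = on.shape
    for df, dt in ((0, 1), (1, 0), (1, 1), (1, -1)):
        f0, f1 = max(0, -df), min(nf, nf - df)
        t0, t1 = max(0, -dt), min(nt, nt - dt)
        a = ids[f0:f1, t0:t1, :]
        b = ids[f0 + df:f1 + df, t0 + dt:t1 + dt, :]
        ok = (a >= 0) & (b >= 0)
        rows.append(a[ok])
        cols.append(b[ok])
    # rule (a): spatial linkage within each TF cell
    if len(loc_pairs):
        a = ids[:, :, loc_pairs[:, 0]]
        b = ids[:, :, loc_pairs[:, 1]]
        ok = (a >= 0) & (b >= 0)
        rows.append(a[ok])
        cols.append(b[ok])

    rows = np.concatenate(rows) if rows else np.empty(0, np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, np.int64)
    g = coo_matrix((np.ones(len(rows), bool), (rows, cols)), shape=(n, n))
    _, labels = connected_components(g, directed=False)

    fi, ti, si = np.nonzero(on)
    lab = labels[ids[fi, ti, si]]
    comps: dict[int, set] = {}
    for t, f, s, c in zip(ti, fi, si, lab):
        comps.setdefault(int(c), set()).add((int(t), int(f), int(s)))
    return list(comps.values())


def filter_min_size(bursts: list) -> list:
    """Keep bursts spanning >= 2 timesteps, >= 2 frequencies and >= 2 faces."""
    return [b for b in bursts
            if len(b.timesteps) >= 2 and len(b.freq_bins) >= 2
            and len(b.faces) >= 2]


def burst_probability(bursts: list, n_epochs: int, n_bins: int,
                      axis: str = "time") -> np.ndarray:
    """Per-bin burst probability: bursts covering the bin / number of epochs."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    ax = {"time": "timesteps", "frequency": "freq_bins", "space": "faces"}[axis]
    counts = np.zeros(n_bins)
    for b in bursts:
        counts[getattr(b, ax)] += 1
    return counts / n_epochs
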