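"""First- and second-level burst characteristics.

First-level features describe a burst separately in each signal domain:
temporal on/offset, duration and centre; frequency bounds, spread and
centre; spatial width (summed face area), bounding-box extents and the
on-surface spatial centre; and burst amplitude (mean and 95th percentile of
baseline-corrected power over all burst cells). Second-level features
combine these: "burst extent" is the first principal component of
(duration, spread, width), and the spatial centre can alternatively be
expressed by the first two principal components of its Cartesian
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from bwave.detect import BurstSupport
from bwave.mesh import SurfaceLocations
from bwave.preprocess import TFPower


@dataclass
class BurstFeatures:
    burst_id: int
    epoch: int
    onset: float                # s
    offset: float
    duration: float             # s
    t_centre: float
    fmin: float                 # Hz
    fmax: float
    spread: float
    f_centre: float
    width_cm2: float
    bbox_mm: tuple              # extent along x, y, z
    centre_face: int
    centre_xyz: tuple
    amp_mean: float             # dB
    amp_p95: float
    phase: str = ""             # pre | post | spanning

    def __post_init__(self):
        if self.offset < self.onset:
            raise ValueError("offset before onset")
        if self.fmax < self.fmin:
            raise ValueError("fmax below fmin")
        if self.width_cm2 <= 0:
            raise ValueError("width must be positive")


def compute_features(burst: BurstSupport, tf: TFPower,
                     locations: SurfaceLocations,
                     weighted_centre: bool = True) -> BurstFeatures:
    """All first-level characteristics of one burst.

    The spatial centre is the (by default amplitude-weighted) centre of mass
    of the burst's face centres, projected onto the surface by snapping to
    the nearest burst face centre.
    """
    if not burst.cells:
        raise ValueError("empty burst")
    t_idx = burst.timesteps
    f_idx = burst.freq_bins
    faces = burst.faces
    onset, offset = tf.times[t_idx.min()], tf.times[t_idx.max()]
    fmin, fmax = tf.freqs[f_idx.min()], tf.freqs[f_idx.max()]

    amps = np.array([tf.power[burst.epoch, f, t, s]
                     for (t, f, s) in burst.cells])

    face_amp = {int(s): 0.0 for s in faces}
    for (t, f, s), a in zip(burst.cells, amps):
        face_amp[int(s)] += a
    w = np.array([face_amp[int(s)] for s in faces])
    if not weighted_centre or w.sum() <= 0 or np.any(w < 0):
        w = np.ones(len(faces))
    pts = locations.centres[faces]
    com = (pts * w[:, None]).sum(axis=0) / w.sum()
    snap = int(faces[np.argmin(np.linalg.norm(pts - com, axis=1))])

    bbox = tuple(float(v) for v in pts.max(axis=0) - pts.min(axis=0))
    return BurstFeatures(
        burst_id=burst.id, epoch=burst.epoch,
        onset=float(onset), offset=float(offset),
        duration=float(offset - onset),
        t_centre=float((onset + offset) / 2),
        fmin=float(fmin), fmax=float(fmax),
        spread=float(fmax - fmin), f_centre=float((fmin + fmax) / 2),
        width_cm2=float(locations.areas[faces].sum() / 100.0),
        bbox_mm=bbox, centre_face=snap,
        centre_xyz=tuple(float(v) for v in locations.centres[snap]),
        amp_mean=float(amps.mean()), amp_p95=float(np.percentile(amps, 95)),
        phase=classify_epoch_phase(float(onset), float(offset)),
    )


def features_table(bursts, tf, locations, **kw) -> pd.DataFrame:
    rows = [compute_features(b, tf, locations, **kw) for b in bursts]
    df = pd.DataFrame([vars(r) for r in rows])
    if len(df):
        df[["bbox_x", "bbox_y", "bbox_z"]] = pd.DataFrame(
            df.pop("bbox_mm").tolist(), index=df.index)
        df[["centre_x", "centre_y", "centre_z"]] = pd.DataFrame(
            df.pop("centre_xyz").tolist(), index=df.index)
    return df


def burst_extent(features: pd.DataFrame):
    """Single cross-domain size metric per burst.

    Duration, frequency spread and spatial width are z-scored and reduced by
    PCA; the first-component score, oriented so that extent grows with
    duration, is the burst extent. Returns ``(scores, variance_fractions)``.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 bursts")
    cols = features[["duration", "spread", "width_cm2"]].to_numpy(float)
    sd = cols.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature column")
    z = (cols - cols.mean(axis=0)) / sd
    pca = PCA(n_components=3)
    scores = pca.fit_transform(z)
    if pca.components_[0, 0] < 0:        # orient: extent increases with duration
        scores[:, 0] *= -1
        pca.components_[0] *= -1
    return scores[:, 0], pca.explained_variance_ratio_


def spatial_centre_pcs(features: pd.DataFrame):
    """First two PCs of the burst spatial-centre coordinates.

    Returns ``(scores (n, 2), variance_fractions (2,))``; PC signs are fixed
    by the loading of the x coordinate.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 bursts")
    xyz = features[["centre_x", "centre_y", "centre_z"]].to_numpy(float)
    pca = PCA(n_components=min(3, len(features) - 1))
    scores = pca.fit_transform(xyz)
    var = pca.explained_variance_ratio_
    if scores.shape[1] < 2 or var[1] < 1e-12:
        warnings.warn("degenerate geometry: spatial centres have <2D spread")
        scores = np.column_stack([scores[:, 0], np.zeros(len(scores))])
        var = np.array([var[0], 0.0])
    out = scores[:, :2].copy()
    for j in range(2):
        if pca.components_[j, 0] < 0:
            out[:, j] *= -1
    return out, var[:2]


def classify_epoch_phase(onset: float, offset: float) -> str:
    """pre iff the burst ends before t=0; post iff it starts after; else spanning."""
    if offset < 0:
        return "pre"
    if onset > 0:
        return "post"
    return "spanning"
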