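"""Estimate the propagation direction and speed of planted travelling waves.

Each planted burst sweeps across the patch as a planar wave; the estimator
recovers its direction from relative latencies of oscillatory critical
points and its speed from the geodesic distance between the earliest and
latest locations.
"""

import numpy as np

from bwave import (EpochArray, SyntheticConfig, bandpass_filter,
                   simulate_dataset, summarize_propagation)
from bwave.mesh import GeodesicSolver
from bwave.propagation import circ_dist

cfg = SyntheticConfig(mesh_kind="cortical_like", mesh_area_cm2=30.0,
                      n_epochs=8, burst_amp=1.0, noise_std=0.02,
                      avoid_overlap=True, seed=12)
ds = simulate_dataset(cfg)
filt = bandpass_filter(EpochArray(ds.epochs, fs=cfg.fs, t_start=cfg.t_start),
                       13, 30)
solver = GeodesicSolver(ds.mesh)

print(f"{'true deg':>9} {'est deg':>8} {'err':>5} {'true m/s':>9} "
      f"{'est m/s':>8} {'R^2':>5} pattern")
for bt in ds.truth[:10]:
    i0 = int(round((bt.onset - cfg.t_start) * cfg.fs))
    i1 = int(round((bt.offset - cfg.t_start) * cfg.fs)) + 1
    x = filt.data[bt.epoch, bt.faces, i0:i1]
    est = summarize_propagation(x, bt.faces, ds.mesh, cfg.fs,
                                (bt.freq_lo + bt.freq_hi) / 2, solver=solver)
    err = np.rad2deg(circ_dist(est.theta, bt.theta))
    print(f"{np.rad2deg(bt.theta):9.1f} {np.rad2deg(est.theta):8.1f} "
          f"{err:5.1f} {bt.speed:9.2f} {est.speed:8.2f} {est.r2:5.2f} "
          f"{est.pattern}")
# a planar pattern with mean R^2 >= 0.2 is "retained"; direction errors of a
# few degrees and speeds within ~15% of the planted 2.8 m/s are expected at
# this signal-to-noise ratio
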