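"""Travelling-wave direction and speed estimation."""

import numpy as np
import pytest

from bwave.mesh import TriMesh
from bwave.propagation import (align_signs, circ_dist, cluster_directions,
                               estimate_speed, find_critical_points,
                               fit_direction, relative_latencies,
                               summarize_propagation, upsample)
from bwave.synth import SyntheticConfig, make_gradient_field, simulate_dataset
from bwave.preprocess import EpochArray, bandpass_filter

FS = 300.0


class TestAlignSigns:
    def test_random_flips_recovered(self):
        rng = np.random.default_rng(0)
        base = np.sin(2 * np.pi * 20 * np.arange(150) / FS)
        x = np.tile(base, (8, 1)) + rng.normal(0, 0.01, (8, 150))
        flips = rng.choice([-1.0, 1.0], 8)
        aligned, _ = align_signs(x * flips[:, None])
        c = np.corrcoef(aligned)
        assert np.all(c > 0)

    def test_already_aligned_unchanged(self):
        rng = np.random.default_rng(1)
        base = np.sin(2 * np.pi * 18 * np.arange(120) / FS)
        x = np.tile(base, (4, 1)) + rng.normal(0, 0.02, (4, 120))
        aligned, signs = align_signs(x)
        assert np.all(signs == 1)
        assert np.array_equal(aligned, x)

    def test_antiphase_pair_one_flip(self):
        base = np.sin(2 * np.pi * 15 * np.arange(200) / FS)
        x = np.vstack([base, -base * 0.9])
        _, signs = align_signs(x)
        assert sorted(signs.tolist()) == [-1.0, 1.0]


class TestUpsample:
    def test_sinusoid_matches_analytic(self):
        t = np.arange(150) / FS
        x = np.cos(2 * np.pi * 20 * t)
        up = upsample(x, 10)
        t_up = np.arange(1500) / (FS * 10)
        analytic = np.cos(2 * np.pi * 20 * t_up)
        interior = slice(100, 1400)  # resampling rings at the ends
        rms = np.sqrt(np.mean((up[interior] - analytic[interior])**2))
        assert rms < 0.01

    def test_constant_stays_constant(self):
        assert np.allclose(upsample(np.full(64, 3.3), 10), 3.3)

    def test_output_length(self):
        assert upsample(np.zeros((2, 50)), 10).shape == (2, 500)


class TestCriticalPoints:
    def test_cosine_count_and_types(self):
        fs = 3000.0
        t = np.arange(int(0.2 * fs)) / fs
        x = np.cos(2 * np.pi * 20 * t)
        cps = find_critical_points(x, fs)
        # 4 per 50 ms cycle over 200 ms, minus edge effects
        assert 12 <= len(cps) <= 16
        kinds = [k for _, k in cps]
        order = ["fall-mid", "trough", "rise-mid", "peak"]
        start = order.index(kinds[0])
        for i, k in enumerate(kinds):
            assert k == order[(start + i) % 4]

    def test_trough_first_signal(self):
        fs = 3000.0
        t = np.arange(int(0.15 * fs)) / fs
        x = -np.sin(2 * np.pi * 20 * t)   # first interior extremum: trough
        cps = find_critical_points(x, fs)
        extrema = [k for _, k in cps if k in ("peak", "trough")]
        assert extrema[0] == "trough"

    def test_noisy_peak_times_within_2ms(self):
        rng = np.random.default_rng(2)
        fs = 3000.0
        t = np.arange(int(0.3 * fs)) / fs
        clean_peaks = np.arange(0, 0.3, 1 / 20)
        hits = []
        for _ in range(20):
            x = np.cos(2 * np.pi * 20 * t) + rng.normal(0, 0.1, t.size)
            # band-limit the noise as the pipeline would
            from scipy.signal import butter, sosfiltfilt

            sos = butter(4, [13, 30], btype="bandpass", fs=fs, output="sos")
            x = sosfiltfilt(sos, x)
            cps = find_critical_points(x, fs)
            for tm, k in cps:
                if k == "peak":
                    hits.append(np.min(np.abs(clean_peaks * 1000 - tm)))
        assert np.median(hits) < 2.0

    def test_less_than_one_cycle_empty(self):
        fs = 3000.0
        x = np.linspace(0, 1, 30)  # monotone: no interior extrema
        assert find_critical_points(x, fs) == []


class TestRelativeLatencies:
    def test_identical_series_zero(self):
        t = np.arange(600) / 3000.0
        x = np.tile(np.cos(2 * np.pi * 20 * t), (5, 1))
        cps = find_critical_points(x.mean(axis=0), 3000.0)
        tm, kind = cps[len(cps) // 2]
        lat = relative_latencies(x, tm, kind, 3000.0, 50.0)
        assert np.allclose(lat, 0.0, atol=1e-6)

    def test_single_delayed_location(self):
        fs = 3000.0
        t = np.arange(900) / fs
        delay = 0.005
        x = np.vstack([np.cos(2 * np.pi * 20 * t) for _ in range(4)]
                      + [np.cos(2 * np.pi * 20 * (t - delay))])
        cps = find_critical_points(x.mean(axis=0), fs)
        tm, kind = cps[len(cps) // 2]
        lat = relative_latencies(x, tm, kind, fs, 50.0)
        assert np.allclose(lat[:4], lat[:4].mean(), atol=0.2)
        assert np.isclose(lat[4] - lat[:4].mean(), 5.0, atol=0.2)


class TestFitDirection:
    def _grid(self, n=13):
        xx, yy = np.meshgrid(np.linspace(0, 30, n), np.linspace(0, 30, n),
                             indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(),
                                np.zeros(n * n)])

    def test_pure_x_wave(self):
        coords = self._grid()
        lat = coords[:, 0] / 3.0
        theta, r2 = fit_direction(lat, coords)
        assert np.isclose(theta, 0.0, atol=1e-9)
        assert np.isclose(r2, 0.5, atol=1e-9)

    def test_diagonal_wave(self):
        coords = self._grid()
        lat = (coords[:, 0] + coords[:, 1]) / (3 * np.sqrt(2))
        theta, _ = fit_direction(lat, coords)
        assert np.isclose(np.rad2deg(theta), 45.0, atol=1e-9)

    def test_permuted_latencies_fail_gate(self):
        rng = np.random.default_rng(3)
        coords = self._grid()
        lat = coords[:, 0] / 3.0
        below = 0
        runs = 200
        for _ in range(runs):
            perm = rng.permutation(len(lat))
            _, r2 = fit_direction(lat[perm], coords)
            below += r2 < 0.2
        assert below / runs >= 0.95

    def test_collinear_coordinates_rejected(self):
        coords = np.column_stack([np.arange(5.0), np.arange(5.0),
                                  np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            fit_direction(np.arange(5.0), coords)

    def test_too_few_points_rejected(self):
        coords = self._grid()[:2]
        with pytest.raises(ValueError):
            fit_direction(np.array([0.0, 1.0]), coords)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(4)
        coords = self._grid() + rng.normal(0, 0.3, (169, 3))
        lat = (0.6 * coords[:, 0] + 0.8 * coords[:, 1]) / 3.0 \
            + rng.normal(0, 0.05, 169)
        theta0, _ = fit_direction(lat, coords)
        phi = np.deg2rad(37.0)
        rot = np.array([[np.cos(phi), -np.sin(phi), 0],
                        [np.sin(phi), np.cos(phi), 0], [0, 0, 1]])
        theta1, _ = fit_direction(lat, coords @ rot.T)
        assert circ_dist(theta1, theta0 + phi) < np.deg2rad(0.5)


class TestClusterDirections:
    def test_tight_cluster_planar(self):
        rng = np.random.default_rng(0)
        th = np.deg2rad(30) + rng.normal(0, np.deg2rad(5), 20)
        labels, pattern = cluster_directions(th)
        assert pattern == "planar"
        assert len(np.unique(labels)) == 1

    def test_opposed_bimodal_multicluster(self):
        rng = np.random.default_rng(1)
        th = np.concatenate([rng.normal(0, 0.05, 10),
                             rng.normal(np.pi, 0.05, 10)])
        labels, pattern = cluster_directions(th)
        assert pattern == "complex_multicluster"
        assert len(np.unique(labels)) >= 2

    def test_uniform_angles_not_planar(self):
        rng = np.random.default_rng(2)
        not_planar = 0
        runs = 40
        for _ in range(runs):
            th = rng.uniform(0, 2 * np.pi, 24)
            _, pattern = cluster_directions(th)
            not_planar += pattern != "planar"
        assert not_planar / runs >= 0.95


class TestSpeed:
    def _flat(self):
        verts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0],
                          [20, 0, 0], [20, 10, 0]], float)
        faces = np.array([[0, 1, 3], [0, 3, 2], [1, 4, 5], [1, 5, 3]])
        return TriMesh(verts, faces)

    def test_two_faces_closed_form(self):
        mesh = self._flat()
        centres = mesh.vertices[mesh.faces].mean(axis=1)
        d = np.linalg.norm(centres[0] - centres[2])
        lat = np.array([0.0, np.nan, d / 2.0, np.nan])
        v = estimate_speed(lat, mesh, np.arange(4))
        assert np.isclose(v, 2.0, rtol=1e-6)

    def test_latency_offset_invariance(self):
        mesh = self._flat()
        lat = np.array([0.0, 1.0, 5.0, 3.0])
        v1 = estimate_speed(lat, mesh, np.arange(4))
        v2 = estimate_speed(lat + 11.0, mesh, np.arange(4))
        assert np.isclose(v1, v2)

    def test_zero_range_rejected(self):
        mesh = self._flat()
        with pytest.raises(ValueError):
            estimate_speed(np.zeros(4), mesh, np.arange(4))


@pytest.fixture(scope="module")
def recovery_dataset():
    cfg = SyntheticConfig(mesh_kind="cortical_like", mesh_area_cm2=24.0,
                          n_epochs=4, burst_amp=1.0, noise_std=0.02,
                          avoid_overlap=True, seed=21)
    ds = simulate_dataset(cfg)
    filt = bandpass_filter(
        EpochArray(ds.epochs, fs=cfg.fs, t_start=cfg.t_start), 13, 30)
    return cfg, ds, filt


def _burst_series(cfg, filt, bt):
    i0 = int(round((bt.onset - cfg.t_start) * cfg.fs))
    i1 = int(round((bt.offset - cfg.t_start) * cfg.fs)) + 1
    return filt.data[bt.epoch, bt.faces, i0:i1]


class TestSummarize:
    def test_planted_burst_recovered(self, recovery_dataset):
        cfg, ds, filt = recovery_dataset
        bt = ds.truth[0]
        x = _burst_series(cfg, filt, bt)
        est = summarize_propagation(x, bt.faces, ds.mesh, cfg.fs,
                                    (bt.freq_lo + bt.freq_hi) / 2)
        assert est.retained
        assert np.rad2deg(circ_dist(est.theta, bt.theta)) <= 10.0
        assert abs(est.speed - bt.speed) / bt.speed <= 0.15

    def test_global_sign_flip_invariant(self, recovery_dataset):
        cfg, ds, filt = recovery_dataset
        bt = ds.truth[1]
        x = _burst_series(cfg, filt, bt)
        fc = (bt.freq_lo + bt.freq_hi) / 2
        a = summarize_propagation(x, bt.faces, ds.mesh, cfg.fs, fc)
        b = summarize_propagation(-x, bt.faces, ds.mesh, cfg.fs, fc)
        assert np.isclose(a.theta, b.theta, atol=1e-9)
        assert np.isclose(a.r2, b.r2, atol=1e-9)
        assert np.isclose(a.speed, b.speed, atol=1e-9)

    def test_opposing_half_waves_complex(self, recovery_dataset):
        cfg, ds, filt = recovery_dataset
        bt = ds.truth[2]
        x = _burst_series(cfg, filt, bt)
        # reverse the wave over the second half of the burst: directions of
        # critical points split into two opposed groups
        half = x.shape[1] // 2
        x2 = np.concatenate([x[:, :half], x[::-1, :half]], axis=1)
        est = summarize_propagation(x2, bt.faces, ds.mesh, cfg.fs,
                                    (bt.freq_lo + bt.freq_hi) / 2)
        assert est.pattern != "planar" or not est.retained

    def test_heavy_noise_discarded(self, recovery_dataset):
        cfg, ds, filt = recovery_dataset
        bt = ds.truth[0]
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1.0, _burst_series(cfg, filt, bt).shape)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [13, 30], btype="bandpass", fs=cfg.fs, output="sos")
        x = sosfiltfilt(sos, x)
        est = summarize_propagation(x, bt.faces, ds.mesh, cfg.fs, 20.0)
        assert not est.retained
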