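"""Band-pass filtering, artefact-window detection and time-frequency power.

The time-frequency decomposition is a DPSS multitaper spectrogram with a
1.6 s sliding window stepped every 200 ms at 1 Hz frequency resolution,
baseline-corrected to dB against a pre-event window. Artefact screening
uses the generalised extreme studentised deviate (GESD) test on the
across-channel standard deviation of consecutive 1 s windows, with the
outlier count capped at 20% of the windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss
from scipy.stats import t as t_dist


@dataclass
class EpochArray:
    """Epoched source time series: (epochs, locations, samples)."""

    data: np.ndarray
    fs: float
    t_start: float = -2.0       # time of the first sample relative to the event
    location_ids: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, locations, samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.location_ids is None:
            self.location_ids = np.arange(self.data.shape[1])

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.data.shape[2]) / self.fs


@dataclass
class TFPower:
    """Baseline-corrected power in dB: (epochs, freqs, timesteps, locations)."""

    power: np.ndarray
    freqs: np.ndarray           # Hz
    times: np.ndarray           # s, window centres
    baseline: tuple = (-1.8, -1.1)
    baseline_means: np.ndarray = field(default=None, repr=False)
    location_ids: np.ndarray = None

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.ndim != 4:
            raise ValueError("power must be (epochs, freqs, times, locations)")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("power contains non-finite values")
        if self.location_ids is None:
            self.location_ids = np.arange(self.power.shape[3])


def bandpass_filter(x: EpochArray, lo: float, hi: float,
                    order: int = 4) -> EpochArray:
    """Zero-phase Butterworth band-pass of every epoch and location."""
    if not (0 < lo < hi < x.fs / 2):
        raise ValueError(f"invalid band [{lo}, {hi}] Hz for fs={x.fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=x.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x.data, axis=-1)
    return EpochArray(filtered, fs=x.fs, t_start=x.t_start,
                      location_ids=x.location_ids)


# ---------------------------------------------------------------------------
# GESD artefact windows

def gesd_critical_values(n: int, max_outliers: int, alpha: float) -> np.ndarray:
    """Critical values lambda_i, i = 1..max_outliers, for a sample of size n.

    lambda_i = (n - i) * t_{p, n-i-1} / sqrt((n-i-1+t^2)(n-i+1)), with
    p = 1 - alpha / (2 (n - i + 1)).
    """
    lam = np.empty(max_outliers)
    for i in range(1, max_outliers + 1):
        df = n - i - 1
        p = 1.0 - alpha / (2.0 * (n - i + 1))
        tq = t_dist.ppf(p, df)
        lam[i - 1] = (n - i) * tq / np.sqrt((df + tq**2) * (n - i + 1))
    return lam


def generalized_esd(values: np.ndarray, max_outliers: int,
                    alpha: float = 0.05) -> np.ndarray:
    """Indices of outliers flagged by the generalised ESD test."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if max_outliers < 1 or max_outliers >= n - 1:
        raise ValueError("max_outliers must be in [1, n-2]")
    lam = gesd_critical_values(n, max_outliers, alpha)
    idx = np.arange(n)
    work = values.copy()
    removed = []
    stats = []
    for i in range(max_outliers):
        mu, sd = work.mean(), work.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(work - mu)
        j = int(np.argmax(dev))
        stats.append(dev[j] / sd)
        removed.append(idx[j])
        work = np.delete(work, j)
        idx = np.delete(idx, j)
    n_out = 0
    for i, r in enumerate(stats):
        if r > lam[i]:
            n_out = i + 1
    return np.sort(np.asarray(removed[:n_out], dtype=np.int64))


def gesd_outlier_windows(x: np.ndarray, fs: float, win: float = 1.0,
                         alpha: float = 0.05,
                         max_frac: float = 0.2) -> np.ndarray:
    """Flag artefactual 1 s windows of a (channels, samples) series.

    The per-window statistic is the standard deviation of the signal across
    all channels and samples of the window; windows whose SD is extreme
    under the generalised ESD test (outlier bound = ceil(max_frac * n))
    are returned as indices into the sequence of non-overlapping windows.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    wlen = int(round(win * fs))
    n_win = x.shape[1] // wlen
    if n_win < 5:
        raise ValueError("series must contain at least 5 full windows")
    sds = np.array([x[:, i * wlen:(i + 1) * wlen].std() for i in range(n_win)])
    max_out = int(np.ceil(max_frac * n_win))
    return generalized_esd(sds, max_out, alpha)


# ---------------------------------------------------------------------------
# Multitaper TFR

def _taper_bank(wlen: int, fs: float, window: float, fres: float):
    # half-bandwidth fres Hz -> time-bandwidth NW = window * fres;
    # keep 2*NW - 1 well-concentrated tapers (the last is discarded)
    nw = window * fres
    k = max(1, int(2 * nw) - 1)
    return dpss(wlen, nw, Kmax=k)


def multitaper_tfr(x: EpochArray, window: float = 1.6, step: float = 0.2,
                   fres: float = 1.0, fmin: float = 13.0, fmax: float = 30.0):
    """DPSS multitaper spectrogram of every epoch and location.

    Returns ``(power, freqs, times)`` with power of shape
    (epochs, freqs, timesteps, locations), non-negative raw power. Epoch
    edges are reflection-padded by half a window so the time axis covers
    the full epoch.
    """
    wlen = int(round(window * x.fs))
    n_samples = x.data.shape[2]
    if wlen > n_samples:
        raise ValueError("analysis window longer than the epoch")
    if window * fres < 1.0:
        raise ValueError(f"frequency resolution {fres} Hz incompatible with "
                         f"window {window} s (time-bandwidth < 1)")
    hop = int(round(step * x.fs))
    tapers = _taper_bank(wlen, x.fs, window, fres)

    half = wlen // 2
    padded = np.pad(x.data, ((0, 0), (0, 0), (half, half)), mode="reflect")
    # window centres on the original time axis, every `hop` samples
    starts = np.arange(0, n_samples, hop)
    times = x.t_start + starts / x.fs

    freqs = np.arange(np.ceil(fmin / fres) * fres, fmax + fres / 2, fres)
    # direct DFT at the requested frequencies (they need not be FFT bins)
    phase = np.exp(-2j * np.pi * freqs[:, None] * np.arange(wlen) / x.fs)
    kernels = tapers[None, :, :] * phase[:, None, :]          # (F, K, wlen)

    n_epochs, n_loc = x.data.shape[:2]
    power = np.empty((n_epochs, len(freqs), len(starts), n_loc))
    for ti, s in enumerate(starts):
        seg = padded[:, :, s:s + wlen]                        # (E, L, wlen)
        spec = np.tensordot(seg, kernels, axes=([2], [2]))    # (E, L, F, K)
        p = (np.abs(spec) ** 2).mean(axis=3)                  # avg over tapers
        power[:, :, ti, :] = p.transpose(0, 2, 1)             # (E, F, L)
    return power, freqs, times


def baseline_correct(power: np.ndarray, freqs: np.ndarray, times: np.ndarray,
                     baseline: tuple = (-1.8, -1.1),
                     location_ids=None) -> TFPower:
    """Convert raw power to dB relative to the per-epoch baseline mean.

    value = 10 log10(P / mean of P over baseline timesteps), computed
    separately per epoch, frequency and location.
    """
    sel = np.flatnonzero((times >= baseline[0]) & (times <= baseline[1]))
    if sel.size == 0:
        raise ValueError("baseline window contains no timesteps")
    base = power[:, :, sel, :].mean(axis=2, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("zero baseline power")
    db = 10.0 * np.log10(power / base)
    return TFPower(power=db, freqs=freqs, times=times, baseline=baseline,
                   baseline_means=base[:, :, 0, :], location_ids=location_ids)
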