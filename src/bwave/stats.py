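"""Surrogate, mixture, permutation and group statistics for burst analyses.

Covers: phase-randomised surrogates preserving the amplitude spectrum; a
per-burst planarity test against 1000 surrogates; EM fitting of a von Mises
mixture to propagation directions (raw samples or a weighted histogram)
with split-half reliability and a max-statistic permutation test on the
component weights; the group-level tests used on burst characteristics
(Wilcoxon signed-rank on medians, two-sample Kolmogorov-Smirnov, two-sample
Watson's U^2); and the two control analyses (amplitude-width correlations,
uniform spatial subsampling, beamformer-weight PC latency regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.optimize import linear_sum_assignment
from scipy.stats import chisquare, ks_2samp, norm, pearsonr, rankdata

from bwave.propagation import (align_signs, upsample, find_critical_points,
                               relative_latencies, fit_direction, circ_dist)


@dataclass
class TestResult:
    name: str                   # wilcoxon | ks | watson_u2
    statistic: float
    p: float
    n: int


@dataclass
class SurrogateResult:
    burst_id: int
    real: float
    surrogates: np.ndarray = field(repr=False, default=None)
    p: float = np.nan


@dataclass
class VonMisesMixture:
    """K-component von Mises mixture: means mu (rad), concentrations kappa,
    weights w (the "length" of each component)."""

    mu: np.ndarray
    kappa: np.ndarray
    w: np.ndarray
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self):
        self.mu = np.mod(np.asarray(self.mu, float), 2 * np.pi)
        self.kappa = np.asarray(self.kappa, float)
        self.w = np.asarray(self.w, float)

    @property
    def k(self) -> int:
        return len(self.mu)

    @property
    def length(self) -> np.ndarray:
        """Resultant mass of each component, w_k I1(kappa_k)/I0(kappa_k).

        This is the length of the component's arrow in a polar plot: it
        vanishes when a component is unconcentrated, however large its
        weight, so it discriminates genuine modes from uniform noise.
        """
        return self.w * special.i1e(self.kappa) / special.i0e(self.kappa)

    def pdf(self, theta) -> np.ndarray:
        theta = np.asarray(theta, float)
        comp = np.exp(self.kappa[:, None] * np.cos(theta[None, :] - self.mu[:, None])) \
            / (2 * np.pi * special.i0(self.kappa))[:, None]
        return (self.w[:, None] * comp).sum(axis=0)


# ---------------------------------------------------------------------------
# Surrogates

def phase_randomize(x: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """``n`` surrogates with the amplitude spectrum of ``x`` and random phases.

    Phases of the positive-frequency bins are drawn independently and
    uniformly; DC (and Nyquist for even length) keep their real values, so
    the output is real with an identical amplitude spectrum.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    nt = x.shape[-1]
    spec = np.fft.rfft(x)
    nb = spec.shape[-1]
    lo, hi = 1, nb - 1 if nt % 2 == 0 else nb
    # independent phases per surrogate AND per leading axis (channel)
    phases = rng.uniform(0, 2 * np.pi, size=(n,) + spec.shape[:-1] + (hi - lo,))
    out_spec = np.broadcast_to(spec, (n,) + spec.shape).copy()
    out_spec[..., lo:hi] = np.abs(spec[..., lo:hi]) * np.exp(1j * phases)
    return np.fft.irfft(out_spec, n=nt, axis=-1)


def _mean_r2(x: np.ndarray, coords: np.ndarray, fs: float, f_centre: float,
             factor: int = 10) -> float:
    """Planarity statistic of one burst: mean regression R^2 over critical
    points of the spatially averaged, interpolated series."""
    from bwave.propagation import _critical_times_by_kind

    up = upsample(x, factor)
    fs_up = fs * factor
    cps = find_critical_points(up.mean(axis=0), fs_up)
    period_ms = 1000.0 / f_centre
    own = _critical_times_by_kind(up, fs_up)
    r2s = []
    for t_ms, kind in cps:
        lat = relative_latencies(up, t_ms, kind, fs_up, period_ms,
                                 own_times=own)
        try:
            _, r2 = fit_direction(lat, coords)
        except ValueError:
            continue
        r2s.append(r2)
    if not r2s:
        raise ValueError("burst unestimable: no usable critical points")
    return float(np.mean(r2s))


def surrogate_planarity_test(x: np.ndarray, coords: np.ndarray, fs: float,
                             f_centre: float, n: int = 1000, seed: int = 0,
                             burst_id: int = -1,
                             factor: int = 10) -> SurrogateResult:
    """Planarity of one burst against per-location phase-randomised surrogates.

    The statistic is the burst's mean regression R^2. Sign alignment is
    applied once to the real data; each surrogate randomises the phase
    spectrum of every location independently. p = (1 + #{surr >= real}) /
    (n + 1).
    """
    x = align_signs(np.asarray(x, dtype=float))[0]
    real = _mean_r2(x, coords, fs, f_centre, factor)
    rng = np.random.default_rng(seed)
    surr_stats = np.empty(n)
    for i in range(n):
        s = phase_randomize(x, 1, seed=int(rng.integers(2**31)))[0]
        try:
            surr_stats[i] = _mean_r2(s, coords, fs, f_centre, factor)
        except ValueError:
            surr_stats[i] = np.nan
    valid = surr_stats[np.isfinite(surr_stats)]
    p = (1.0 + np.sum(valid >= real)) / (len(valid) + 1.0)
    return SurrogateResult(burst_id=burst_id, real=real,
                           surrogates=surr_stats, p=float(p))


# ---------------------------------------------------------------------------
# von Mises mixture

def _kappa_from_rbar(r: float) -> float:
    """Approximate maximum-likelihood concentration for mean resultant r."""
    if r < 1e-9:
        return 0.0
    if r > 1.0 - 1e-9:
        return 700.0
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1.0 / (r**3 - 4 * r**2 + 3 * r)
    return float(min(k, 700.0))


def _vm_logpdf(theta, mu, kappa):
    return kappa * np.cos(theta - mu) - np.log(2 * np.pi * special.i0e(kappa)) - kappa


def _em_once(theta, weights, k, rng, max_iter=200, tol=1e-8):
    n = theta.size
    mu = rng.uniform(0, 2 * np.pi, k)
    kappa = np.full(k, 2.0)
    w = np.full(k, 1.0 / k)
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        logp = _vm_logpdf(theta[None, :], mu[:, None], kappa[:, None]) \
            + np.log(w[:, None] + 1e-300)
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float((weights * lse).sum())
        gamma = np.exp(logp - lse[None, :])            # (k, n)
        gw = gamma * weights[None, :]
        mass = gw.sum(axis=1)
        w = mass / mass.sum()
        z = (gw * np.exp(1j * theta[None, :])).sum(axis=1)
        mu = np.mod(np.angle(z), 2 * np.pi)
        rbar = np.abs(z) / np.maximum(mass, 1e-300)
        kappa = np.array([_kappa_from_rbar(r) for r in rbar])
        if ll - prev < tol * max(1.0, abs(ll)) and ll >= prev:
            converged = True
            prev = ll
            break
        prev = ll
    return VonMisesMixture(mu, kappa, w, loglik=prev, converged=converged)


def fit_vonmises_mixture(theta: np.ndarray, weights: np.ndarray = None,
                         k: int = 4, seed: int = 0,
                         restarts: int = 10) -> VonMisesMixture:
    """EM fit of a K-component von Mises mixture.

    ``theta`` are direction samples in radians; optional ``weights`` turn
    them into a weighted histogram (e.g. an across-subject averaged
    probability distribution over angle bins). Multi-start EM with
    ``restarts`` random initialisations; the best local optimum is
    returned.
    """
    theta = np.mod(np.asarray(theta, dtype=float).ravel(), 2 * np.pi)
    if weights is None:
        weights = np.ones_like(theta)
    else:
        weights = np.asarray(weights, dtype=float).ravel()
        if weights.shape != theta.shape:
            raise ValueError("weights must match theta")
    if np.unique(theta).size < k:
        raise ValueError(f"need >= {k} distinct support points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        fit = _em_once(theta, weights, k, rng)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def match_components(a: VonMisesMixture, b: VonMisesMixture) -> np.ndarray:
    """Permutation of b's components minimising total circular distance to a."""
    cost = circ_dist(a.mu[:, None], b.mu[None, :])
    _, cols = linear_sum_assignment(cost)
    return cols


def split_half_reliability(theta: np.ndarray, n_splits: int = 500, k: int = 4,
                           seed: int = 0, restarts: int = 3) -> pd.DataFrame:
    """Stability of the mixture across random split halves.

    Each split fits the mixture on both halves, matches components by
    optimal circular assignment, and records the percentage difference in
    component weight ("length") and the angular difference in degrees.
    Returns ``n_splits * k`` rows.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size < 2 * k:
        raise ValueError("need at least 2K directions")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_splits):
        perm = rng.permutation(theta.size)
        half = theta.size // 2
        fa = fit_vonmises_mixture(theta[perm[:half]], k=k,
                                  seed=int(rng.integers(2**31)),
                                  restarts=restarts)
        fb = fit_vonmises_mixture(theta[perm[half:]], k=k,
                                  seed=int(rng.integers(2**31)),
                                  restarts=restarts)
        cols = match_components(fa, fb)
        la, lb = fa.length, fb.length
        for i, j in enumerate(cols):
            mean_len = (la[i] + lb[j]) / 2
            rows.append({
                "split": s, "component": i,
                "length_diff_pct": 100.0 * abs(la[i] - lb[j]) / max(mean_len, 1e-12),
                "angle_diff_deg": float(np.rad2deg(circ_dist(fa.mu[i], fb.mu[j]))),
            })
    return pd.DataFrame(rows)


def permutation_test_components(theta: np.ndarray, n_perm: int = 5000,
                                k: int = 4, seed: int = 0,
                                restarts: int = 10,
                                null_restarts: int = 2) -> np.ndarray:
    """Are the mixture component weights larger than chance?

    The null randomises every burst's direction uniformly, refits the
    mixture and records the largest component length (resultant mass,
    w I1(kappa)/I0(kappa)); the max statistic corrects for multiple
    comparisons across components:
    p_k = (1 + #{null max >= length_k}) / (n_perm + 1).
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size < 2 * k:
        raise ValueError("need at least 2K directions")
    rng = np.random.default_rng(seed)
    real = fit_vonmises_mixture(theta, k=k, seed=int(rng.integers(2**31)),
                                restarts=restarts)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        null = rng.uniform(0, 2 * np.pi, theta.size)
        fit = fit_vonmises_mixture(null, k=k, seed=int(rng.integers(2**31)),
                                   restarts=null_restarts)
        null_max[i] = fit.length.max()
    return np.array([(1.0 + np.sum(null_max >= lk)) / (n_perm + 1.0)
                     for lk in real.length])


# ---------------------------------------------------------------------------
# Group tests

def wilcoxon_signed_rank(x, y) -> TestResult:
    """Wilcoxon signed-rank test; statistic reported as the normal
    approximation z (no continuity correction), two-sided p.

    W is the sum of the ranks of the positive differences (zeros dropped);
    z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero pairs")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w - mu) / sigma
    p = 2.0 * norm.sf(abs(z))
    return TestResult(name="wilcoxon", statistic=float(z), p=float(p), n=n)


def wilcoxon_exact_p(x, y) -> float:
    """Exact two-sided p by full 2^n sign enumeration (n <= 15)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n > 15:
        raise ValueError("exact enumeration limited to n <= 15")
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    total = n * (n + 1) / 2.0
    w_hi = max(w, total - w)
    count = 0
    for bits in range(2**n):
        ws = sum(ranks[i] for i in range(n) if bits >> i & 1)
        if ws >= w_hi or ws <= total - w_hi:
            count += 1
    return min(1.0, count / 2.0**n)


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(a, b, method="asymp")
    return TestResult(name="ks", statistic=float(res.statistic),
                      p=float(res.pvalue), n=a.size + b.size)


def _watson_u2_stat(a: np.ndarray, b: np.ndarray) -> float:
    # ECDF differences evaluated at distinct pooled values (tie-safe),
    # weighted by tie multiplicity
    n, m = a.size, b.size
    pool = np.concatenate([a, b])
    order = np.argsort(pool, kind="mergesort")
    is_a = np.concatenate([np.ones(n, bool), np.zeros(m, bool)])[order]
    sorted_pool = pool[order]
    last = np.r_[np.diff(sorted_pool) != 0, True]   # end of each tie group
    fa = np.cumsum(is_a)[last] / n
    fb = np.cumsum(~is_a)[last] / m
    g = np.diff(np.r_[0, np.flatnonzero(last) + 1])  # group sizes
    d = fa - fb
    nn = n + m
    dbar = (g * d).sum() / nn
    return float(n * m / nn**2 * (g * (d - dbar)**2).sum())


def watson_u2(a, b, n_perm: int = 999, seed: int = 0) -> TestResult:
    """Two-sample Watson's U^2 for circular data, p by permutation.

    Angles are reduced mod 2pi; the statistic is computed on the pooled
    circular ranks and is invariant to a common rotation of both samples.
    """
    a = np.mod(np.asarray(a, float).ravel(), 2 * np.pi)
    b = np.mod(np.asarray(b, float).ravel(), 2 * np.pi)
    if a.size < 8 or b.size < 8:
        raise ValueError("each sample must contain at least 8 angles")
    real = _watson_u2_stat(a, b)
    rng = np.random.default_rng(seed)
    pool = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool.size)
        if _watson_u2_stat(pool[perm[:a.size]], pool[perm[a.size:]]) >= real:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return TestResult(name="watson_u2", statistic=real, p=float(p),
                      n=a.size + b.size)


# ---------------------------------------------------------------------------
# Control analyses

def amplitude_width_correlations(features: pd.DataFrame,
                                 session_col: str = "session"):
    """Pearson r between burst amplitude and apparent spatial width.

    Within each session, across its bursts; across sessions, on the session
    medians. Returns ``(per_session_table, across_r, across_p)``.
    """
    rows = []
    for sess, grp in features.groupby(session_col):
        if len(grp) < 3:
            continue
        r, p = pearsonr(grp["amp_mean"], grp["width_cm2"])
        rows.append({"session": sess, "r": float(r), "p": float(p),
                     "n": len(grp)})
    med = features.groupby(session_col)[["amp_mean", "width_cm2"]].median()
    if len(med) >= 3:
        ar, ap = pearsonr(med["amp_mean"], med["width_cm2"])
    else:
        ar, ap = np.nan, np.nan
    return pd.DataFrame(rows), float(ar), float(ap)


def uniform_spatial_subsample(features: pd.DataFrame, centres: np.ndarray,
                              face_probability: np.ndarray = None,
                              prob_floor: float = 0.44, n_bins: int = 16,
                              p_target: float = 0.2, seed: int = 0):
    """Subset of bursts whose spatial-centre distribution is uniform.

    Restricts to bursts centred on faces whose burst probability exceeds
    ``prob_floor`` (when a per-face probability is given), bins the
    remaining burst centres on a 2D grid, and iteratively removes a random
    burst from the currently most occupied bin until a chi-square
    goodness-of-fit test against uniformity is not rejected
    (p > ``p_target``). Returns the index of surviving bursts.
    """
    if len(features) < 20:
        raise ValueError("need at least 20 bursts")
    rng = np.random.default_rng(seed)
    keep = features.index.to_numpy()
    if face_probability is not None:
        ok = face_probability[features.loc[keep, "centre_face"].to_numpy(int)] \
            > prob_floor
        keep = keep[ok]

    side = max(2, int(round(np.sqrt(n_bins))))
    xy = features.loc[keep, ["centre_x", "centre_y"]].to_numpy(float)
    occupied_xy = centres[:, :2]
    gx = np.linspace(occupied_xy[:, 0].min(), occupied_xy[:, 0].max(), side + 1)
    gy = np.linspace(occupied_xy[:, 1].min(), occupied_xy[:, 1].max(), side + 1)

    def bin_of(pts):
        bx = np.clip(np.searchsorted(gx, pts[:, 0], side="right") - 1, 0, side - 1)
        by = np.clip(np.searchsorted(gy, pts[:, 1], side="right") - 1, 0, side - 1)
        return bx * side + by

    bins = bin_of(xy)
    active = np.unique(bins)            # bins the data could occupy
    keep_mask = np.ones(len(keep), dtype=bool)
    warned = False
    while True:
        counts = np.bincount(bins[keep_mask], minlength=side * side)[active]
        if chisquare(counts).pvalue > p_target:
            break
        if keep_mask.sum() <= 2 * len(active):
            warned = True
            break
        top = active[np.argmax(counts)]
        cand = np.flatnonzero(keep_mask & (bins == top))
        keep_mask[rng.choice(cand)] = False
    return keep[keep_mask], warned


def weight_pc_latency_control(latencies: list, weights: np.ndarray,
                              var_keep: float = 0.90) -> float:
    """How much latency structure survives removing beamformer-weight PCs.

    ``weights`` is (locations, n_weight_features); its principal components
    up to ``var_keep`` cumulative variance are regressed out of the
    latencies of every critical point, and the Pearson correlation between
    original latencies and regression residuals is averaged over critical
    points. r near 1 means the weight structure explains little of the
    latency field.
    """
    from sklearn.decomposition import PCA

    weights = np.asarray(weights, dtype=float)
    n_loc = weights.shape[0]
    pca = PCA()
    scores = pca.fit_transform(weights)
    ncomp = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_),
                                var_keep) + 1)
    if ncomp >= n_loc:
        raise ValueError("fewer locations than retained components")
    x = np.column_stack([np.ones(n_loc), scores[:, :ncomp]])
    rs = []
    for lat in latencies:
        lat = np.asarray(lat, dtype=float)
        ok = np.isfinite(lat)
        if ok.sum() <= ncomp + 2:
            continue
        beta, *_ = np.linalg.lstsq(x[ok], lat[ok], rcond=None)
        resid = lat[ok] - x[ok] @ beta
        if lat[ok].std() == 0:
            continue
        if resid.std() <= 1e-8 * lat[ok].std():
            rs.append(0.0)          # latency fully explained by the weights
            continue
        rs.append(pearsonr(lat[ok], resid)[0])
    if not rs:
        raise ValueError("no usable critical points")
    return float(np.mean(rs))
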