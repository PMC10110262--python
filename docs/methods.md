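# Methods

This note documents the models and procedures implemented in `bwave`, the
parameters that matter, the design choices made where the method is
genuinely underdetermined, and the limits of what the synthetic benchmarks
show.

## Surface model and geodesics

All spatial quantities live on a triangulated surface with coordinates in
millimetres. The analysis locations are the face centres (the points at
which source time series are estimated); face areas and vertex-sharing
adjacency come from the same triangulation. Latencies are in milliseconds,
so distance/latency is numerically m/s.

On-surface distances are computed on a Steiner-refined edge graph: nodes
are the mesh vertices, 12 evenly spaced points per edge and the face
centres; within each face all node pairs are joined by straight in-plane
segments, and the centres of edge-adjacent faces are additionally joined
by their exact two-face geodesic (the unfolding construction, obtained by
minimising |p−x| + |x−q| over the shared edge — a convex 1-D problem
solved by ternary search). Dijkstra on this graph over-estimates the true
geodesic by a vanishing margin as refinement grows; at the default
refinement flat-mesh distances agree with the Euclidean distance to well
under 1%. Planar meshes covering a convex region are special-cased: there
every straight segment between surface points lies on the surface, so the
geodesic *equals* the Euclidean distance and is returned in closed form.
Curved meshes (the cortical-like fixtures, folded strips) always use the
graph. An independent upper bound used in tests concatenates per-hop
on-surface paths between adjacent face centres (two-face geodesics across
shared edges, or paths through a shared vertex); the solver's distances
never exceed it. A Euclidean-weighted centre graph is *not* a sound bound:
a chord under a fold is shorter than any surface path.

The spatial clustering radius d_max is the largest Euclidean distance
between centres of adjacent (vertex-sharing) faces within the region of
interest. "Adjacent" is taken as sharing ≥ 1 vertex, the permissive
reading consistent with eight-connectivity elsewhere in the pipeline; on
a cortical-density mesh (~27 locations/cm²) d_max comes out at a few mm.
Computing a maximum over *all* pairs instead would make every location
mutually linkable and collapse spatial clustering, so the adjacent-pair
reading is the only usable one.

## Time–frequency decomposition

Per epoch and location, a DPSS multitaper spectrogram with a 1.6 s window
stepped every 200 ms. The time-bandwidth product is window × 1 Hz = 1.6
(±1 Hz half-bandwidth); ⌊2·NW⌋ − 1 = 2 well-concentrated tapers are kept.
Power is evaluated by direct DFT at integer frequencies 13–30 Hz (these
need not be FFT bins of the window length). Epoch edges are
reflection-padded by half a window so the time axis covers the full epoch;
edge estimates are therefore partially self-similar and the default
baseline window (−1.8 to −1.1 s) sits away from the very edge. Baseline
correction is 10·log10(P / P̄_baseline) per epoch, frequency and location.
Per-epoch rather than pooled baselining was chosen for robustness to slow
drifts; the baseline means are stored so the correction is invertible.

A consequence of the 1.6 s window worth stating plainly: a ~240 ms burst
produces suprathreshold power at *every* window position that overlaps
it, so the apparent duration of a detected burst is the true duration
plus up to one window length, and its apparent spectral extent includes
the leakage of a short tone (several Hz). Detection counts, spatial
footprints and all propagation quantities are unaffected (propagation is
estimated from the band-passed time series, not the spectrogram), but
apparent durations on this grid are not comparable to durations measured
with shorter windows.

Artefact screening uses the generalised extreme studentised deviate test
on the across-channel standard deviation of non-overlapping 1 s windows,
with significance 0.05 and the outlier count capped at 20% of windows.
The critical values λ_i follow the standard t-quantile formula and are
unit-tested against direct evaluation.

## Burst detection

Candidate thresholds run from the median of all in-scope baseline-corrected
power values to the median + 7 SD in steps of 0.25 SD (29 candidates; the
mean-anchored variant is available). Each candidate is scored by the
Pearson correlation, across epochs, between mean power and the number of
bursts the candidate yields after full 5D clustering and the minimum-size
filter; the best-scoring candidate wins and ties go to the lower
threshold. The burst-*count* objective is used because the cheaper
occupancy proxy (fraction of suprathreshold cells) is monotone in mean
power at every threshold, which parks the argmax at the bottom of the
grid; the count penalises both extremes — at low thresholds everything
merges into one event per epoch, at high thresholds events shrink below
the minimum size — so the correlation peaks where burst-like activity is
actually segmented (typically ~3 SD on the synthetic data).

Clustering is implemented as connected components over suprathreshold
cells with two link rules: (a) same time–frequency cell and location
centres strictly closer than d_max (single linkage), and (b) same location
and eight-adjacent time–frequency cells. This flat formulation is provably
equivalent to the staged description (2D eight-connectivity clustering,
within-cell spatial clustering, cross-cell merging of clusters sharing a
location) and is verified against a brute-force union-find oracle on
hundreds of random masks. Bursts never cross epoch boundaries. Bursts must
span ≥ 2 timesteps, ≥ 2 frequency steps and ≥ 2 locations.

## Burst characteristics

First-level features are read directly off the cell table: temporal and
spectral bounds and centres (midpoints of the bounds), apparent spatial
width (sum of face areas, reported in cm²), per-axis bounding-box extents,
amplitude (mean and 95th percentile of dB power over all burst cells), and
the spatial centre — the amplitude-weighted centre of mass of the burst's
face centres projected onto the surface by snapping to the nearest burst
face (unweighted mode available; whether the reference analysis weighted
by amplitude is not documented, so both exist). A burst is *pre* if it
ends strictly before the movement at t = 0, *post* if it starts strictly
after, otherwise *spanning* (boundary cases count as spanning and are
excluded from pre/post contrasts).

Burst extent is the first principal component of z-scored (duration,
spread, width), sign-fixed so extent grows with duration; the spatial
location PCs are the first two components of the centre coordinates,
sign-fixed on the x-loading. PCA signs are otherwise arbitrary, so fixing
them is purely a reporting convention.

## Propagation direction and speed

Given a burst's band-passed per-location series between its on- and
offset: location signs are aligned greedily (seed at the highest-variance
location, initialise signs by correlation with the seed, then flip any
location anti-correlated with the running mean until stable — the result
is defined up to one global sign, which cancels in everything downstream);
series are Fourier-interpolated ×10; the critical points of the spatially
averaged series are located (local extrema plus the zero crossings of the
mean-removed signal between opposite extrema, typed rise/fall). Critical
points where the Hilbert envelope of the averaged series is below 20% of
its maximum are dropped: a detected burst only spans suprathreshold
oscillation, and in the tapered tails "latencies" are noise.

At each critical point, every location contributes the time of its own
same-type critical point nearest the reference within ± half a period of
the burst's centre frequency (missing if none). Two simple regressions
predict these latencies from the x and y face-centre coordinates
(z ignored — on an inflated-like surface a z-gradient is expressed in x/y);
θ = atan2(b_y, b_x) points toward increasing latency, i.e. the direction
of travel, and the planarity score is the mean of the two R²s. Note the
ceiling: a perfect planar wave whose direction is not axis-aligned splits
its variance between the two simple regressions, so R̄² ≈ 0.5 is the
noise-free value, comfortably above the 0.2 retention gate.

Directions across critical points are clustered spectrally (Gaussian
affinity on circular distance, σ = π/4; cluster count in {1,2,3} by the
largest eigengap of the normalised Laplacian — the reference analysis
does not state its parameters, so these are this package's choices). One
tight cluster (circular SD < π/4) is a planar burst; one loose cluster or
several clusters are complex patterns. A burst is retained when planar
with mean R² ≥ 0.2; its direction is the circular mean over critical
points, its speed the mean over critical points of geodesic distance
between the latency extremes divided by their latency difference. Speed
is the statistic most sensitive to noise: latency errors inflate the
extremes' spread and bias speed downward, which is why the recovery
benchmark is run at high SNR.

## Synthetic data

The generator emulates the statistics of the analysed recordings, not
their biophysics: no forward model, no beamformer. Defaults are the study
conditions — a ~60 cm² cortical-like patch at ~27 locations/cm², epochs
−2..2 s at 300 Hz, burst duration 238 ± 23 ms, spectral spread 3 Hz,
nominal width 6 cm², directions drawn from four von Mises components at
66°, 248°, 142° and 324° (κ = 8), speed 2.8 m/s, and a higher post- than
pre-movement rate (0.9 vs 0.5 bursts/s, mirroring the observed ~61%/34%
split, plus ~5% spanning events). Each burst is a Hann-windowed sinusoid
whose whole waveform is delayed per face by the planar latency field
(a kinematic or "fictive" wave — the estimator measures latency structure
regardless of the generative mechanism), tapered by a raised cosine that
reaches zero at 1.5× the nominal radius so the detectable footprint at
ordinary thresholds matches the nominal width; truth faces are the
nominal-radius disc. Background is per-face independent 1/f noise (unit
exponent by default) plus a spatially common 1/f component at 30% of the
noise SD — the common term produces realistic across-epoch power
variability. `avoid_overlap=True` keeps planted bursts temporally disjoint
within an epoch, the clean design for parameter recovery (temporally
overlapping bursts contaminate each other's latency fields, as they would
in real data).

What passing the synthetic benchmarks does *not* show: robustness to
beamformer leakage and weight structure, to realistic cortical folding
(the cortical-like fixture is a gently undulating inflated-like patch),
to non-planar (circular/spiral) waves, or to the burst-shape diversity of
real recordings. The mesh-validation module quantifies sampling-induced
direction error (regular meshes near-exact, irregular ones ~1–2° median
at level N, improving with density); errors on real subject meshes are
reported in the literature at ~7° and depend on subject geometry not
reproduced here.

## Statistics

*Surrogates.* Phase randomisation keeps the amplitude spectrum exactly
(phases of positive-frequency bins drawn independently per location; DC
and Nyquist untouched) and the per-burst planarity statistic is the mean
regression R² recomputed per surrogate; p = (1 + #{surrogate ≥ real}) /
(n + 1), bounded below by 1/(n+1). The reference analysis left its
surrogate-compared "magnitude" undefined; mean R² is the planarity
strength the rest of the pipeline already gates on.

*Mixture.* Four-component von Mises mixture by EM (weighted data
supported, for fitting averaged probability histograms), concentration
updated by the standard A⁻¹(r̄) approximation, κ capped at 700, ≥ 10
seeded restarts, best local optimum kept. The "length" of a component is
its resultant mass w·I₁(κ)/I₀(κ) — the arrow length in a polar plot. The
naive alternative (length = mixture weight) is non-discriminative: EM
assigns ≈ equal weights even to uniform data, whereas the resultant mass
vanishes when a component is unconcentrated. Split-half reliability
refits on random halves and matches components by optimal circular
assignment; the permutation test refits on uniformly re-randomised
directions and corrects across components with the max-length statistic
(conservative by construction, so the family-wise false-positive rate on
uniform data sits below the nominal level).

*Group tests.* Wilcoxon signed-rank reports the normal-approximation z
(zeros dropped, average ranks, no continuity correction; exact 2ⁿ
enumeration available for n ≤ 15 — for n = 8 all-same-sign pairs,
z = 18/√51 ≈ 2.5205 and the exact two-sided p is 2/256).
Kolmogorov–Smirnov uses the asymptotic p; Watson's U² is computed on
pooled circular ranks with tie-safe ECDF evaluation and a permutation p
(≥ 999 resamples) rather than asymptotic tables, because per-subject
samples are small.

*Controls.* Amplitude–width Pearson correlations within sessions and
across session medians; uniform spatial subsampling (restrict to
high-probability faces, iteratively remove bursts from the most occupied
spatial bin until a χ² goodness-of-fit test no longer rejects uniformity
at p > 0.2); and the beamformer-weight control (regress latencies on the
weight PCs covering 90% variance, correlate latencies with residuals —
r ≈ 1 when weights explain nothing, defined as 0 when they explain
everything).

## Problem sizes and determinism

The test suite and the acceptance script run on scaled-down instances
chosen to exercise every code path with stable statistics: patches of
12–40 cm² (≈ 320–1070 faces), 4–28 epochs, 50 planted bursts for
parameter recovery, 1000 surrogates on two compact bursts, 5000-sample
mixture fits, 199/99 permutations, 200 random clustering oracles. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
identical configuration and seed reproduce byte-identical pipeline
artefacts, and completed stages are reused only when the configuration
hash matches.

## Known limitations

- The threshold-selection anchor (per-epoch mean power) is weakly
  informative when the baseline window itself contains bursts; the
  burst-count objective mitigates but does not remove this.
- Spectrogram smearing makes apparent durations window-dependent (see
  above); cross-study duration comparisons need matched windows.
- The geodesic solver is a refined-graph approximation on curved meshes
  (exact only on planar-convex ones); its error is documented by the
  flat-mesh and bound contracts, not by a formal guarantee on arbitrary
  curvature.
- Speed estimates use only the two latency extremes, inheriting the
  reference procedure's noise sensitivity.
- Complex (circular/spiral) wave parameterisation is out of scope; such
  bursts are classified complex and excluded.
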