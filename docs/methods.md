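# Methods

## Corral / hop-diffusion model

The plasma membrane is modelled as a square lattice of compartments of
side `L_comp` (nm) imposed by the cortical actin meshwork. Within a
compartment a receptor performs Brownian motion with microscopic
diffusivity `D_micro` (µm²/s): per frame interval `dt`, each axis takes a
Gaussian step of variance `2·D_micro·dt`. A step whose endpoint lies in a
different compartment is accepted with probability `p_hop` (one boundary
test per frame step, per axis); a rejected step is reflected back into the
current compartment by triangular folding, which handles steps longer than
the compartment and preserves the uniform stationary distribution.
Localization noise is added as independent Gaussian error of SD
`sigma_loc` (nm) per frame and axis.

Consequences used throughout:

* free diffusion (`L_comp = ∞` or `p_hop = 1`): ensemble MSD `= 4·D·Δt`;
* hard corral (`p_hop = 0`): long-lag MSD plateau `= L²/3` (each axis
  contributes `L²/6`, the variance of the displacement of two independent
  uniform positions on an interval of length `L`);
* static localization noise adds a constant `4·σ_loc²` to every lag.

Boundary crossings are tested once per frame; sub-frame excursions are not
resolved. This matches what a camera running at the acquisition frame rate
can observe and keeps `p_hop` interpretable as a per-observed-encounter
probability. The `p_hop = 0` and free limits use closed-form path
constructions (folded or plain cumulative sums) and are vectorized over
whole ensembles; intermediate `p_hop` iterates frame by frame.

Default acquisition settings are 20 frames/s, 1200 frames per trajectory,
107 nm camera pixels. Default `sigma_loc` is 20 nm, a typical localization
precision for 40 nm fluorescent beads in wide-field SPT; it is an assumed
instrument property, not a measured one, and is configurable everywhere.

## MSD estimation and the confined fit

Per trajectory, the time-averaged MSD with overlapping pairs is

    ρ(kΔt) = mean_i |r(i+k) − r(i)|²,  k = 1 … max_lag_frac·N

with `max_lag_frac = 0.25` by default and pair counts `N − k` retained as
weights. Tracks shorter than `min_len = 50` frames are rejected as QC
failures (counted, not fatal).

The confined model `ρ(Δt) = P·(1 − e^(−Δt/τ)) + 4·D_M·Δt + c` is fitted by
weighted least squares (weights `N − k`, all parameters bounded below by
0, `scipy.optimize.curve_fit`, at most 500 function evaluations).
Initialization: `c` from the linear extrapolation of the first two lags to
lag 0; `P` from the tail mean minus `c`; `τ` from the lag at half plateau;
`D_M` from the tail slope. `L = 1000·√(3P)` nm. When the fitted `τ`
exceeds half the lag window the plateau is not resolved within the data
and the fit is flagged unconfined (`L` unreliable); optimizer failure is
flagged unconverged and such tracks are excluded from group summaries.

The headline short-time diffusivity is deliberately not `D_M`: it is
slope/4 of a weighted linear fit (with intercept) to lags 2–5. The
intercept absorbs the `4σ²` noise offset; lag 1 is excluded because it
has the largest relative leverage from that offset. On free-diffusion
ensembles this estimator is unbiased to within Monte-Carlo resolution
(≲0.5 SEM at n = 1298); adding 20 nm localization noise moves the mean
recovered D by well under 10%.

Known bias: in the fast-relaxation regime (τ comparable to one frame,
e.g. `D_micro = 0.05 µm²/s` in a 132 nm corral) the per-track fit slightly
overestimates `c` at the expense of the plateau, and the concave map
`P → √P` adds a small Jensen term; the mean recovered `L` then runs about
4% low. Across the regimes the package targets
(D ∈ [0.005, 0.02] µm²/s, L ∈ [80, 140] nm at 1200 frames) the bias of the
mean recovered `L` stays within 5%, and of the mean recovered `D` (free
diffusion) within about 1%.

Group summaries are arithmetic mean ± SEM (`SD/√n`, `ddof = 1`; a single
fit reports SEM = 0 by convention) over converged fits, pooling
trajectories rather than averaging per cell: printed group sizes in this
assay are trajectory counts. Per-trajectory D estimates from a homogeneous
ensemble are right-skewed and closer to lognormal than normal; group
comparisons nevertheless operate on raw values (CLT at hundreds of
trajectories), with a log-scale option available.

## Trajectory reconstruction from movies

Rendering (the forward model) places each particle as an integrated 2D
Gaussian PSF (error-function differences over pixel edges) of expected
`photons_per_spot` photons on a uniform background, with optional Poisson
shot noise, writable as 16-bit multi-page TIFF.

Detection runs on the matched-filtered image (Gaussian smoothing at the
PSF width) and keeps local maxima above `median + 5·1.4826·MAD` of the
smoothed frame; each candidate is refined by a least-squares 2D Gaussian
fit on the raw image for subpixel coordinates. At 1000 photons/spot over
a 10 photon/px background the mean localization error is below 0.15 px;
rare shot-noise false positives are removed downstream by the
minimum-track-length filter.

Linking is greedy by globally smallest distance among admissible
track-head/detection pairs (mutual nearest neighbours are linked first by
construction; ties break toward the smaller distance, then the older
track). A track survives `max_gap = 2` missed frames, with the admissible
radius `max_disp = 4 px` scaled by the number of frames bridged; tracks
shorter than `min_len = 50` detections are discarded. The assay's movies
are sparse (2–4 particles per field), so global assignment would add
complexity without measurable benefit; this is a deliberate scope choice,
as are the absence of drift correction and of multiple-hypothesis
tracking.

## 3D internalization metrics

A 3D track is reduced to the inward-displacement series
`d(t) = z(t) − z_mem`, with z increasing from the coverslip into the cell
and `z_mem` defaulting to the median z over the first second. Two metrics:

* **Time-weighted inward movement** `twi = ∫d dt / T` (trapezoidal):
  dimensionally a displacement (µm), robust to uneven sampling, invariant
  to a common shift of `z` and `z_mem` and linear in `d`. For a pure ramp
  `d = v·t` over `[0, T]` it equals `v·T/2` exactly.
* **Internalization velocity** `v_in`: a directed phase is accepted when
  the best plateau-plus-line (hinge) model improves on a single line by an
  RSS ratio < 0.8. The onset is then located by a profile-likelihood
  changepoint that models pre-onset *positions* as white noise about a
  plateau and post-onset displacement *increments* as white noise about a
  constant drift; `v_in` is the mean post-onset increment per frame
  interval, clipped at 0. Working in increments is the
  generalized-least-squares treatment of Brownian fluctuations of the
  transported cargo: fitting the transport phase by ordinary least squares
  on positions lets accumulated (serially correlated) Brownian deviations
  drag the breakpoint late and bias the velocity upward — in simulation by
  over 20% at a transport-phase diffusivity of 2×10⁻³ µm²/s — whereas the
  increment-domain estimator shows ≲1% bias at velocities of
  0.005–0.021 µm/s. Without a detected directed phase, `v_in` is a robust
  (Theil–Sen) overall slope clipped at 0.

The generator draws the membrane phase as lateral diffusion at `D_mem`
with independent axial jitter, and the transport phase as drift `v_in`
plus 3D diffusion at `D_transport = 2×10⁻⁴ µm²/s` — an order of magnitude
below membrane diffusion, reflecting cargo tethered to a processive
motor rather than freely diffusing. Recovery tests use 180 s tracks
(experimental tracks run 1–10 min). Whether inward displacement should be
measured along z or along the 3D path is an open modelling question; the
z-axis convention is used and documented here.

## Cortical-actin quantification

A z-stack is reduced to xz or yz strip projections of 2 µm width
(mean intensity over the strip; a max option exists for data with hot
pixels — the mean is the default because the readout is an intensity, not
a peak). Cortical density is the mean intensity sampled along the apical
membrane path (bilinear interpolation, maximum over a 3-px axial band to
tolerate small trace errors) divided by the mean of the brightest region
of the same projection, defined as the top 1% of projection pixels. The
1% extent is a parameter: the published procedure names a "brightest
region" without giving its size, so both the extent and the reduction are
configurable. Normalization makes the readout scale-invariant and
comparable across imaging batches; values near 1 mean the cortex is as
bright as the brightest structure (typically basal stress fibers), values
near 0 mean no apical cortex.

The phantom generator builds an ellipsoidal cell (half-axes 18×18×5 µm in
a 0.1×0.25×0.25 µm voxel grid) with a 0.3 µm apical shell at
`cortical_intensity` and a 0.2 µm basal layer at `basal_intensity`.
Ground-truth apical paths are taken over the central 60% of the footprint,
where the shell's height varies by less than a voxel across the strip
width. On real data the path comes from a user-supplied trace; automatic
membrane segmentation is out of scope.

## Wound-healing metrics

Relative wound density `RWD(t) = 100·(w(t) − w(0)) / (c(t) − w(0))`,
where `w` and `c` are the occupied-area fractions inside and outside the
fixed wound region; clipped below at 0, undefined points reported as NaN.
Confluence is the covered-pixel percentage. The generator fills the wound
with Bernoulli occupancy at density `outside_density·(1 − e^(−r·t))`
against a static outside monolayer, so the analytic closure curve is
`RWD(t) = 100·(1 − e^(−r·t))` up to binomial noise. RWD is a ratio of
area fractions and therefore resolution-invariant.

## Statistical scheme

For two groups, a two-sided F-test on the sample variances at α = 0.05
selects the pooled Student *t*-test (equality not rejected) or the Welch
*t*-test; more than two groups go to one-way ANOVA. Stars: `*` p < 0.05,
`**` p < 0.01, `***` p < 0.001; p-values are unadjusted (a Holm option
exists but is off by default). A vectorized Monte-Carlo replica of this
decision rule (`type1_error_rate`) verifies calibration: under the null
the rejection rate at α = 0.05 stays within [0.04, 0.06] both when the
pooled branch dominates (equal variances) and when a 16-fold variance
ratio routes >99% of repetitions to Welch. Gene-set overlap significance
is the exact hypergeometric upper tail `P[X ≥ k]`, cross-checked against
full enumeration for every universe size ≤ 12.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the estimators assume:
Markovian corral diffusion, Gaussian localization noise, a single sharp
membrane-to-transport switch, an ideal ellipsoidal cell, Bernoulli cell
masks. They deliberately omit photophysics (blinking, bleaching),
anomalous diffusion, exposure-time motion blur, 3D PSF sectioning,
cell-to-cell parameter heterogeneity, and segmentation errors in real
masks. Passing recovery tests therefore demonstrates estimator
correctness and calibration under the stated model — not robustness to
every artefact of real microscopy data. Published per-cell-line values
are measurements on live cells whose raw movies are not available; the
package anchors its simulations at those printed parameters and verifies
recovery, which is the strongest check possible without the original
data.

## Problem sizes and determinism

Recovery runs use 1298 trajectories of 1200 frames (the published
trajectory count for the reference cell line) for headline checks, and
50–300 trajectories for property tests; ensemble closed-form checks use
10⁴ short trajectories. All generators take explicit seeds and are
bit-reproducible; the pipeline runner derives per-group seeds from the
config seed and serializes reports with sorted keys, so a fixed
configuration yields byte-identical reports.
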