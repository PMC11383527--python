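# Methods

## Generative model (what the simulator emulates)

A field of view of `fov_px × fov_px` pixels (default 0.1 μm/px) is imaged
for `frame_count` frames (default 500) at `frame_interval_s` (default
0.1 s, i.e. 10 Hz).  Each particle is a cluster of `k` receptors drawn from
`stoichiometry_pmf` (counts 1..k_max, k_max = 10); particle density
defaults to 1 particle/μm², well below the 4.5/μm² sparsity bound the
single-particle analysis assumes.

**Photophysics.**  Each fluorophore's brightness is drawn once from
`N(monomer_mean_au, monomer_sd_au)` (defaults 980, 89 a.u.; truncated
positive) and is constant until the fluorophore bleaches in a single step
at an `Exponential(bleach_lifetime_s)` time (default 5 s; `inf` disables
bleaching).  A fluorophore emits in frame `f` iff it survives the whole
frame, so the first dark frame is `floor(t/Δt) + 1`.  Brightness is
defined as the signal deposited in a 3×3 pixel window centred on the
particle — the same statistic the analysis measures — and the rendered PSF
(isotropic pixel-integrated Gaussian, σ = 1 px) is scaled so a
pixel-centred source's 3×3 sum equals its amplitude.

**Motion.**  A fraction `mobile_fraction` (default 0.85) of particles
performs 2-D Brownian motion with per-axis step variance `2·D·Δt`
(default D = 0.02 μm²/s) and reflecting boundaries; the rest are static.
Observed fast-path positions add Gaussian localization noise
(`loc_noise_sd_um`, default 0.03 μm).  The simulation is in-plane only; the
evanescent-field axial dimension is not modelled because the analysis uses
only in-plane quantities.

**Noise.**  Rendering adds Poisson shot noise on signal + background
(treating a.u. as counts) and Gaussian read noise (default sd 10 a.u.),
both switchable off for exact tests.  The background is a uniform level
(default 100 a.u.) plus, optionally, a brighter disc emulating the cell
footprint (default radius 0.45·fov, +100 a.u.); particles are placed inside
the disc when present.  The image-free fast path
(`simulate_trajectories`) draws the same intensities without rendering,
approximating window shot noise as Gaussian with variance
`signal + 9·background`.

**Cell tracks.**  Chemotaxis fixtures are biased persistent random walks
with fixed step length: the direction is a persistence-weighted update of
the previous direction blended toward +x with weight `bias`; bias 0 is an
isotropic persistent walk, bias 1 straight-line +x motion.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: camera gain/EMCCD statistics, fluorophore blinking
and maturation fractions, anomalous or confined diffusion, axial drift,
non-uniform illumination, and cell-shape heterogeneity.

## Measurement chain

* **Segmentation.**  Otsu threshold of the temporal-median image, largest
  connected component, holes filled.  A uniform image (no contrast) is an
  explicit failure.
* **Background `K0`.**  Per frame, the `q = 0.80` quantile (numpy linear
  interpolation convention) of in-mask pixel gray values after excluding a
  5×5 block around every detection in that frame.  Because a quantile of a
  noisy distribution exceeds its mean, `K0` is a deliberately conservative
  background; calibrant and sample are measured identically, so the
  stoichiometry ratio is convention-free.
* **Particle intensity.**  For each of the first `window_frames = 20`
  frames of a track: 3×3 window sum at the rounded particle position minus
  `9·K0`, divided by the sub-pixel aperture fraction
  `F(dx)·F(dy)/F(0)²` of the window (with `F` the 1-D pixel-integrated
  Gaussian mass in a 3-pixel aperture).  Without this correction a
  half-pixel offset reads only ~89% of the amplitude, which breaks integer
  count recovery at k ≥ 4.  The average is truncated at the first detected
  photobleaching step (below); otherwise bleaching at τ0 = 50 frames
  deflates a 20-frame mean to ~82% of the amplitude on average.  Tracks
  shorter than the window, or whose window crosses the image border, are
  excluded and logged.  Negative averages are floored at 0.
* **Step detection.**  Recursive two-segment change-point: the split
  minimising the two-constant-segment SSE is accepted when the mean drop
  exceeds both 15% of the pre-mean (50% for the single-step calibrant
  criterion) and 4 robust noise units; the search recurses into the
  pre-segment so the *earliest* significant step is returned.  The noise
  scale (MAD of first differences / √2) is estimated once on the whole
  trace — short staircase segments would otherwise inflate it.
* **Monomer calibration.**  Per calibrant trace the single step is
  located; pre-step frames (≥ 5, ≤ 20) give the intensity sample and the
  step time enters the bleach fit.  Traces that are dark from the start
  (fluorophore bleached before acquisition; ~2% at the defaults) are pure
  noise and are rejected by a 5-noise-sd emission floor — in imaged data
  such particles are simply never detected.  The Gaussian fit is the
  maximum-likelihood mean/sd by default (a histogram least-squares variant
  is provided); zero variance is flagged degenerate.
* **Photobleach fit.**  The exponential MLE (sample mean) of the step
  times.  A step at first dark frame `d` is interval-censored in
  `[(d−1)Δt, dΔt)` and left-truncated (dark-from-start traces are
  unobservable), so the extracted time is `(d − 1.5)·Δt` for `d ≥ 2`,
  making the mean unbiased to O(Δt²/τ0).  Distributions with a
  coefficient of variation far from 1 are flagged non-exponential.  The
  pipeline warns when `window_frames ≥ τ0` in frames.  Note that movies
  much shorter than ~10·τ0 right-censor the distribution and bias the fit
  low (censored traces are excluded, not modelled).
* **Stoichiometry.**  `ratio = intensity / I_mono`; the receptor count is
  the ratio rounded half-to-even, floored at 1.  Counts ≤ 2 are
  monomers-plus-dimers, ≥ 3 nanoclusters; MSI is the unweighted mean of
  per-particle intensities.
* **Diffusion.**  Time-averaged MSD with gap-aware pair counting;
  `D1-4 = slope/4` from an OLS fit with intercept over lags 1–4.  The
  intercept absorbs static localization error (`b = 4σ²`); the raw,
  possibly negative slope is kept for diagnostics.  Minimum track length
  for diffusion analysis is 20 frames, aligned with the intensity window.
* **Mobility threshold.**  The 99th percentile of `D1-4` over ≥ 1000
  simulated pure-localization-noise tracks at the stated noise and track
  length.  The pipeline default noise is a conservative 0.03 μm — chosen
  to cover the dimmest particles, whose centroid noise is largest; a
  data-driven estimate from MSD intercepts (`estimate_loc_noise`) is
  available but not the default, because per-track noise heterogeneity
  makes the median intercept too permissive.  A fixed user threshold can
  override.  The group median D is reported over mobile tracks only.
* **Chemotaxis.**  Per-cell metrics, then unweighted averaging across
  cells (one cell, one vote).  The gradient axis is fixed as +x in data
  files; importers must rotate coordinates.  Zero-length paths are
  excluded with a warning.
* **Statistics.**  Mann-Whitney: exact full enumeration of
  `C(n_a+n_b, n_a)` midrank assignments for combined n ≤ 12, two-tailed
  p = 2·min(tail) capped at 1 (identical samples give p = 1); otherwise the
  normal approximation with tie and continuity correction.  Chi-square:
  Pearson, no continuity correction, zero expected counts rejected.
  One-way ANOVA + Tukey HSD is a convenience wrapper only.

## Detection and linking choices

The tracker is a deliberate simplification of full SPT machinery (no
motion models, merges/splits, or Kalman filtering): LoG response
(median-subtracted — the truncated kernel has a DC bias), robust-MAD
threshold with a floor at 0.2% of the peak response (so noise-free images
admit no ripple maxima), 3×3 local maxima, non-maximum suppression at
2σ, and sub-pixel refinement by the centroid of the clipped-positive LoG
response in a ±max(2, ⌈2σ⌉) window (compact, hence robust to neighbours at
2–4 px, with < 0.01 px bias for isolated noise-free spots).  Linking is an
optimal bipartite assignment per frame (squared displacement, gate
`max_disp_px`, default `3·sqrt(4·D_max·Δt)/pixel_size` with D_max =
0.2 μm²/s) with miss/birth alternatives priced at the gate cost, and gap
closing up to `max_gap = 2` frames against the last known position.
Detections are canonically ordered by (y, x) within each frame, so output
is deterministic and invariant to input permutation.  Two emitters within
one PSF width are a single diffraction-limited spot; ground-truth scoring
utilities therefore provide an isolation filter
(`GroundTruth.isolated_particles`) and an effective-count helper
(`counts_alive_at`, since a fluorophore dark before a track starts is
unobservable by any intensity method).

## Problem sizes used in the validation suite

Calibration recovery uses 5000 fast-path monomer traces of 500 frames;
diffusion recovery 500 mobile tracks of 500 frames; the end-to-end movie
checks use a 320-px (32 μm) field at 0.15/μm² (noise-free exactness, 60
frames) and 0.5/μm² (~520 particles, 80 frames, full default noise);
statistical calibration uses 2000 null replicates at n = 20 per group.
These sizes give sampling errors comfortably inside the asserted
tolerances while keeping the whole suite in the minutes range.

## Known limitations

* Stoichiometry by intensity ratio cannot distinguish co-diffusing
  particles closer than the PSF; crowded fields bias nanocluster fractions
  upward (merged windows) and purity downward.
* Step-counting photobleaching analysis (an alternative stoichiometry
  route) is out of scope, as are anomalous-diffusion exponents, HMM state
  segmentation and confinement analysis.
* The Mann-Whitney exact branch is O(C(n, n_a)) and intentionally capped
  at combined n = 12.
* TIFF I/O is a single-channel, 2-D, time-ordered dialect with a JSON
  sidecar; proprietary formats (ND2/CZI) are not read.
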