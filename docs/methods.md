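# Methods

`hemcyto` quantifies fluorescently labeled cells in very low magnification
("cell astronomy") images: roughly 3 µm per pixel, so a 7–20 µm cell spans
only 3–7 pixels. At that scale a cell is well approximated by a small
bivariate Gaussian blob sitting on a locally flat background, and the
analysis problem becomes astronomical photometry with one extra twist —
the object is *barely* resolved, so its width carries real information
(physical diameter) instead of being a fixed point-spread constant.

## Model

Each detected event (an image patch around a bright spot) is modeled as a
mixture of N Gaussian components, one per cell, plus one uniform
component for the background:

    f_c(x) = N(x | μ_c, Σ_c)          c = 1..N
    f_{N+1}(x) = 1 / (width · height)

with mixing weights π_c summing to one. Pixel intensities are treated as
photon counts: the likelihood is intensity-weighted,
L = Σ_x I(x) · ln Σ_c π_c f_c(x), which is exactly the likelihood of
treating every photon as an i.i.d. draw from the mixture, computed once
per pixel instead of once per photon. EM alternates

  - E-step: z_c(x) = π_c f_c(x) / Σ_n π_n f_n(x)
  - M-step: π_c = Σ_x z_c I / Σ_x I;  μ_c = Σ z_c I x / Σ z_c I;
    Σ_c = Σ z_c I (x−μ_c)(x−μ_c)′ / Σ z_c I

and L is non-decreasing across iterations. Outputs per cell:

  - fluorescence F_c = Σ_x z_c(x) I(x) (responsibility-weighted intensity
    sum; the background keeps its own share, so Σ_c F_c = Σ_x I(x)
    exactly);
  - diameter = pixel_size · 2√(2 ln 2) · σ_eff with σ_eff = |Σ_c|^(1/4),
    the geometric mean of the principal standard deviations. This is the
    FWHM of the fitted Gaussian, made rotation-invariant for elliptical
    fits; it reduces to the scalar FWHM for isotropic Σ.

Densities are evaluated in log space; pixels where every weighted
component density underflows float64 are assigned wholly to the
background. The Eq-style normalizer is the standard bivariate constant
2π√|Σ|.

### Numerical choices

- Convergence: relative change of L below 1e-8 or 200 iterations.
  Patches are tiny (≤ ~40×40), so the cost is negligible.
- Covariance floor: eigenvalues clamped at 0.04 px² during the M-step,
  preventing collapse onto a single bright pixel before the QC rules
  can judge the component.
- Initialization: μ at the detection centroid; Σ isotropic with σ sized
  to a 10 µm expected cell diameter at the configured pixel size;
  Gaussians share weight 0.5 equally, background starts at 0.5. The
  scale-matched Σ keeps the Gaussian from capturing the background.
- No automatic camera-offset subtraction; a config `offset` is
  subtracted and clamped at zero before fitting when set.
- Background scope: the uniform component's domain is the local patch by
  default (its density is then 1/patch-area), which tolerates background
  heterogeneity across the frame. A global mode fits the whole frame as
  one mixture — a single frame-wide uniform plus one Gaussian per
  detected event — for truly uniform backgrounds; cluster splitting is
  a local-mode feature.

## Spot detection

A two-class linear discriminant with shared pooled covariance scores
every window (stride 1, default size 15×15). Windows are min–max
normalized to [0, 1], which makes detection invariant to positive affine
rescaling of intensities — a dim and a bright cell present the same
descriptor. Constant windows map to the all-zero descriptor (background
by construction). The pooled covariance gets a ridge of
1e-3 · trace/dim; because the covariance is shared, the spot posterior
is a logistic function of one linear functional of the descriptor, so
the scan reduces to a single correlation with the weight kernel plus
running min/max filters. The margin of ⌊w/2⌋ pixels is left unscored
rather than padded with fabricated intensities.

The detection threshold is cross-validated (default 5 folds): the
largest posterior cut whose mean held-out true-positive rate stays at or
above 0.99, stepped down to the midpoint of the score gap just below it
so the operating point does not sit on the saturated score boundary.
Training/scanning use a single window size (default 15 px ≈ 45 µm,
a 7.5 µm spot plus generous margin at 3 µm/px): descriptor and
classifier dimensions must match, so a separate scan size would be
inconsistent. Thresholded maps are segmented with 8-connected
components (spots span few pixels; 4-connectivity fragments diagonal
blobs), one event per component, bounding boxes padded by ⌊w/2⌋ so the
Gaussian tail stays inside the fitted patch.

## Quality control

A fitted component is vetted purely from its covariance:

- too_small — 3√λ_min < 1 px: the Gaussian cannot cover one pixel;
- too_large — the 3σ ellipse area π(3σ₁)(3σ₂) exceeds the footprint a
  compact cluster of more than three maximal (20 µm) cells could occupy
  (four-cell area, ≈140 px² at 3 µm/px): the fitter latched onto
  background;
- degenerate — eigenvalue ratio above 100 or λ_min below the covariance
  floor: a correlated pixel set, not a cell.

Rejected components are flagged in the event table, never silently
dropped.

## Cluster splitting

Sliding-window detection returns one event per connected blob, so
doublets and triplets arrive as single events. Refinement is recursive
and fully deterministic (image information only). Each round the
component with the largest covariance eigenvalue is a split candidate,
and two deterministic proposals compete:

1. Eigenvector split — children at μ ± √λ_max · v along the leading
   unit eigenvector v. This is exact when one Gaussian has absorbed two
   equal round spots: the between-centers spread adds λ = d² along the
   axis through the centers. Each child starts with the parent scatter
   minus that between-centers spread, i.e. eigenvalues floored at the
   parent's *minor* eigenvalue. (Flooring at the global 0.04 px² floor
   instead produces a degenerate needle-shaped child in which EM gets
   stuck; the minor-eigenvalue floor is the decomposition the two-spot
   argument actually implies.)
2. Residual-guided reseed — when cells differ strongly in brightness
   (ratios ≳ 2), the single-Gaussian optimum locks onto the brightest
   cell and the *uniform component* absorbs its dim neighbours, so the
   parent covariance carries no trace of them and proposal 1 cannot
   reach them. The reseed keeps one child at the parent location and
   places the other at the peak of the smoothed background-attributed
   intensity z_bg(x)·I(x), skipped when that peak lies on an existing
   component.

Each proposal is refit with the full EM; the better refit (by BIC) is
accepted only if the BIC drops by more than a threshold (default 10, a
conventional strong-evidence gap; configurable), else the pre-split fit
is kept and refinement stops. BIC = k·ln(n_eff) − 2L with k = 6 free
parameters per Gaussian (2 mean, 3 covariance, 1 weight; the uniform
component is parameter-free and the sum-to-one constraint absorbs its
weight) and n_eff = Σ_x I(x), the photon-count reading of the data size
(pixel count available as config). Isotropic covariances break the
eigenvector tie along the row axis with non-negative first component,
keeping reruns bit-identical. Only splits exist — no merge moves; the
spurious-split direction is instead controlled by the BIC penalty
(measured 0/50 on isolated spots).

On the synthetic doublet/triplet battery (separations 4–8 px,
brightness ratios 1–3, SNR 10–30) the two-proposal refinement resolves
the correct component count in ≈99% of cases; with the eigenvector
proposal alone the rate is ≈78%, the deficit concentrated exactly in
the high-brightness-contrast regime described above.

## Synthetic data

No public micrographs exist for this imaging regime, so the simulator
is the test bed and defines the study conditions. It renders fields at
3 µm/pixel with spots integrated over pixel footprints
(error-function differences; bivariate-normal rectangle CDF for rotated
anisotropic spots) — point-sampling a 3–4 px spot visibly biases the
totals — and applies Poisson noise to background + signal, matching the
photon-count reading of intensities. Same spec and seed give
bit-identical images.

The bead series emulates a three-tier calibration-bead experiment:
all beads have true diameter 7.5 µm (σ ≈ 1.06 px), per-tier photon
totals proportional to the manufacturer-reference intensities
18,882 : 138,201 : 624,803 (default 0.02 photons per reference unit),
and per-tier background levels calibrated so the expected
peak-over-background SNR hits 7.8 / 23.5 / 102. A single background
cannot satisfy both constraints (the SNR ratios are not the photon
ratios); per-tier backgrounds mirror the fact that each bead level is a
separately imaged sample. SNR here is (peak intensity above background
mean)/(background standard deviation); the calibration averages the
central-pixel Gaussian mass over uniform sub-pixel placements, and the
measurement samples the pixel nearest the true center to avoid the
upward bias of a noisy local maximum.

What the simulator does not emulate: optical PSF physics, camera gain
and read noise, vignetting, debris and unbound-fluorophore
heterogeneity, or cell-shape deviations from a Gaussian. Passing the
synthetic batteries therefore demonstrates the estimator's correctness
under the model's own assumptions and the stated SNR regime — not
robustness to the full messiness of real slides.

## Benchmark problem sizes

The packaged batteries use 20 detection fields of 192² px at SNR 20,
300 beads per tier, a 200-case split battery and 50 isolated spots —
large enough that the binomial error on the reported rates is a few
percent, small enough to run on one CPU in a few minutes.

## Known limitations

- Fluorescence is reported in intensity-sum units; absolute calibration
  (e.g. to reference-bead units) is the user's regression.
- Events touching the image border are flagged `edge` and excluded from
  default plots; their truncated tails bias fluorescence low.
- The uniform-background assumption fails under structured background
  (dark-field debris); the QC rules reject such fits rather than
  repairing them.
- Diameter recovery carries a small positive bias (~4% at 7.5 µm beads)
  from pixel-footprint integration: the fitted Gaussian sees the spot
  convolved with the pixel box.
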