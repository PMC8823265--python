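# Methods

This note documents the models, numerical choices and limitations behind
`eprredox`, in the spirit of a package's own methods appendix.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model

A continuous-wave EPR spectral projection along gradient direction **d** is
modelled as

    y_d(B) = ( ell * R_d x )(B) + n(B),

where `R_d x(B)` is the plane integral of the spin density `x` over
`{ r : G (r·d) = B }` (G the gradient in mT/mm), `ell` the first derivative
of a unit-area absorption line, and `n` i.i.d. zero-mean Gaussian noise.
The probe is treated as a single line of peak-to-peak width 0.073 mT: the
¹⁵N-labelled nitroxyl has a two-line hyperfine spectrum but only one
absorption peak is scanned, and field-modulation broadening is absorbed
into the effective linewidth rather than modelled as a separate
convolution.  Additive white Gaussian noise on the first-derivative spectra
is the standard assumption for lock-in-detected CW EPR; noise levels are
parameterized as peak-amplitude SNR (`noise_sd_for_snr`).

Geometry conventions: the field axis spans the sweep width symmetrically
about the scanned line center; the reconstructable field of view is
`sweep_width / gradient` (1.5 mT at 40 mT/m → 37.5 mm); volumes are
isotropic grids whose voxel centers are symmetric about the origin.

### Discretization

`R_d` deposits each voxel's mass onto the two nearest field bins by linear
interpolation, which conserves total mass exactly
(`sum(p)·Δb = sum(x)·voxel_volume·G`) and makes the forward map smooth in
sub-voxel shifts.  Mass projecting outside the sweep is dropped with a
warning — wrap-around would alias mass to the opposite side of the volume.
The adjoint reads a profile back with the same interpolation weights, so
the operator pair passes the adjoint dot-product test at machine precision
(asserted at 1e-8 in the suite).  The convolution with the lineshape is a
zero-padded linear convolution aligned on the kernel center tap; its exact
transpose (embed, correlate) is used in the adjoint.  The inner
scatter/gather loops are numba-compiled; everything else is numpy/scipy.

## Golden-mean direction schedule

Directions are generated from the two golden means φ₁ = 1/λ² ≈ 0.46557 and
φ₂ = 1/λ ≈ 0.68233, λ the real root of λ³ = λ² + 1: index i (1-based, which
avoids the degenerate pole at i = 0) maps to z = 2 frac(i φ₁) − 1 over the
full sphere and azimuth 2π frac(i φ₂).  The schedule is deterministic and
nested — any prefix equals the shorter schedule exactly — which is what
makes retrospective sub-sampling of one measured projection set
meaningful.  `uniformity_score` (coefficient of variation of
nearest-neighbour angular distances) quantifies angular uniformity; the
suite checks the golden-mean sets beat seeded uniform-random sets of equal
size.

## Filtered back-projection

For plane integrals the inversion formula is
`f(r) = −1/(8π²) ∮ p''_ξ(ξ·r) dΩ`, implemented as: Wiener deconvolution of
the lineshape with Tikhonov floor `|L|² + reg·max|L|²` (default
`reg = 1e-3`, exposed), a −(2πν)² second-derivative filter under a cosine
apodization window, and back-projection with weight 4π/n per direction.

Two details matter numerically:

* the first-derivative lineshape has no DC component, so the standalone
  profile estimator (`deconvolve_lineshape`) first integrates the spectrum
  to absorption form, linearly detrends the small edge residual left by
  truncated absorption tails, and divides by the absorption transfer
  function, which is nonzero at DC; the filtered path inside the
  reconstructor divides directly by the derivative transfer function
  because its filter removes DC anyway (and an integration step would leak
  the edge residual through the |k|² filter);
* the absolute scale of a discrete FBP depends on grid and filter
  conventions, so the output is calibrated by reconstructing a unit
  impulse at the grid-center voxel through the same 1D pipeline (cheap:
  one filtered profile per direction, no volumetric back-projection) and
  dividing by its peak.  Image-quality metrics normalize residual scale
  anyway.

A measured zero-gradient spectrum can replace the analytic kernel; it is
resampled onto the kernel tap axis (the sweep axis of an even-length scan
has no bin at exactly zero offset) and normalized by its windowed double
integral, which undercounts Lorentzian tail area — a physical limitation of
any windowed measurement, visible as a few-percent global scale offset.

## Compressed-sensing reconstruction

The objective `½‖CRx − y‖² + λ₁‖x‖₁ + λ₂ TV(x)` is minimized with a
monotone (restarting) FISTA: gradient step with step size 0.95/L (L from
10 power iterations on AᵀA, seeded; the safety factor guards against
under-estimation by a finite power iteration), then the approximate prox of
the compound penalty — TV denoising followed by soft-thresholding (both
orders exposed; the composition is the standard approximation to the prox
of the sum) — an optional non-negativity clamp (on by default: the
reconstructed map is a signal intensity), and Nesterov momentum.  The
monotone variant keeps the best iterate, so the objective history is
non-increasing by construction even over the very short default schedule of
**four outer iterations**; plain FISTA is not monotone and four iterations
would otherwise be untestable.  λ defaults are (0.1, 0.01) for the
high-SNR, sharp-edged phantom preset and (0.01, 0.01) for the in-vivo-like
preset, applied to max-normalized observations.

The TV prox is Chambolle's dual fixed-point projection (isotropic 3D TV,
forward differences, reflective boundaries, dual step 1/6, default 10 inner
iterations).  It is hand-written so the inner iteration count is an exact,
fixed parameter inside FISTA; the test suite cross-checks it against an
independent converged TV solver.

Observations and iterates are max-normalized internally for stability, so a
reconstructed time series loses inter-frame amplitude ratios;
`renormalize_series` multiplies each frame by the mean double-integrated
amplitude of its raw spectra (proportional to the spin count during that
frame), restoring the decay profile.  This exactly undoes the normalization
when the spatial distribution is static and is accurate to first order when
the distribution changes slowly, as with two compartments whose rates
differ by ~30% over a few frames; the residual is a small common-mode rate
offset (the tumor compartment is kept a small fraction of the phantom
volume partly for this reason).

## Kinetic mapping

Decay maps fit `S(t) = A₀e^(−kt)` per voxel on the frames above an
intensity threshold (25% of the first frame's maximum by default; 15% is
the display threshold).  The fit is a damped, vectorized Gauss–Newton on
(A₀, k) initialized from the log-linear OLS solution with non-positive
samples clipped; voxels that fail to converge within 200 iterations are
removed from the mask and counted.  A pure log-linear mode exists for
comparison.  Rates carry the reciprocal of the series' time unit, and the
suite asserts exact scale- and time-unit-invariance.  Frame timestamps are
mid-acquisition times of each 16.8 s scan (128 projections + zero-gradient
at 130 ms each), the least-biased single timestamp for an exponential
sampled by a finite scan; by default only the first 5 of 12 frames enter
the fit, because later frames of a decaying series have proportionally
lower SNR.

## Image-quality assessment

NRMSE (RMS error over the reference's range), MAE (mean absolute difference
of per-image max-normalized volumes) and SSIM.  SSIM defaults to the
windowed mean-local form (3D Gaussian weights, σ = 1.5, 11-voxel support,
c₁ = (0.01 L)², c₂ = (0.03 L)² with L the dynamic range of the pair),
delegated to scikit-image; the single-window global-statistics formula is
available as a variant, and metrics accept full volumes or slices.  Two
reference conventions are named: phantom comparisons score each method
against its own densest (2048-projection) reconstruction; in-vivo-style
comparisons score both methods against the CS reconstruction, since no
low-noise reference exists there.  `psf_fwhm_estimate` fits a 1D profile as
a known-width rod convolved with a Gaussian and reports the Gaussian FWHM —
the operational spatial resolution.

## Synthetic data: what it does and does not emulate

`pillar_phantom` reproduces the printed geometry of the solution phantom —
ten 3.0 mm × 15.0 mm pillars on a 5.0 mm pitch inside a 21.8 mm bore,
1.06 mL in total — with a separable anti-aliased construction (8×
supersampled cross-section × exact axial partial volume) whose total mass
is grid-independent to a fraction of a percent.  The in-plane hole layout
is a 4–3–3 row pattern; only pitch, diameter, length and count are
documented for the physical object, so the layout is approximate.

`two_compartment_leg_phantom` is a *synthetic stand-in* for a tumor-bearing
leg: an ellipsoidal leg (semi-axes 7 × 7 × 12 mm) of uniform initial
amplitude with an embedded 3.5 mm-radius spherical tumor, rate map exactly
two-valued (defaults 1.00 and 1.36 min⁻¹, the group-mean rates of normal
and tumor tissue).  It emulates the two-rate geometry and the acquisition
timing only — not vasculature, probe uptake, perfusion heterogeneity,
resonator sensitivity inhomogeneity, or anatomy.  Passing tests on it
demonstrate that the pipeline recovers known kinetics through
reconstruction and renormalization at realistic SNR; they do not certify
accuracy on animal data.

Noise levels are fixed once per experiment type: peak-amplitude SNR 50 for
the phantom acceleration experiment (solution-phantom data are
high-quality) and SNR 20 for the in-vivo-like recovery experiment.

## Experiment runners and problem sizes

`run_acceleration_experiment` simulates one dense 2048-direction noisy
projection set of the pillar phantom at 64³, reconstructs nested prefixes
{64 … 2048} with both methods, scores them against each method's own 2048
reconstruction, and reports the acceleration factor — the largest m/n such
that CS from n projections matches or beats FBP from m on all three
indicators.  `run_decay_recovery` runs 20 seeded replicates of the
five-frame two-compartment pipeline at 48³ with 128 directions.  These
sizes (64³/48³ rather than the 96³ display grids of practice) keep the
full validation suite and the acceptance script at a few minutes on one
CPU while leaving every algorithmic ingredient in place; the matrix size
is a parameter everywhere.

## Known limitations

* The forward model omits resonator B₁ inhomogeneity, saturation, rapid-
  scan distortion and baseline drift; decay-rate maps are insensitive to a
  static sensitivity profile, but absolute A₀ maps are not.
* FBP noise amplification depends strongly on the deconvolution
  regularizer; the default (1e-3) favours resolution over noise, matching
  its role here as the conventional baseline rather than a tuned method.
* The measured-kernel deconvolution inherits the windowed double-integral
  scale deficit for heavy-tailed (Lorentzian) lines.
* The renormalization step assumes the double integral of noisy spectra is
  unbiased; at very low SNR its variance propagates into fitted rates.
* `DecayPhantomSpec.frame_times` are seconds while rates are min⁻¹; the
  conversion lives in `decay_series` and `ImageSeries.times_in`, and mixing
  units elsewhere is the caller's responsibility.
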