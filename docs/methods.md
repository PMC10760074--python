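# Methods

This note documents the models implemented in `conedrive`, the choices made
where the design was open, and what the synthetic-data generator does and
does not emulate.

## Photoreceptor model

Canine spectral sensitivities are generated from the A1 visual-pigment
template: an alpha band `1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D)`
in the normalized frequency `x = λmax/λ`, with `a` a weak Gaussian function
of λmax, plus a Gaussian beta band whose center (`189 + 0.315 λmax` nm) and
width (`-40.5 + 0.195 λmax` nm) are linear in λmax. The canonical canine
set is L 555 nm, S 429 nm, rhodopsin 506 nm, melanopsin 480 nm. Template
constants are stored as data on the `Photopigment` so alternative fits can
be swapped in through configuration. Curves are peak-normalized to 1
before pre-receptoral filtering and deliberately *not* re-normalized after
it, since filtering genuinely lowers and shifts the effective peak.

Lens filtering uses a parametric canine lens transmittance — unit
transmittance in the long-wave range with a logistic short-wave cutoff,
half-height 400 nm and slope 10 nm by default — because no tabulated canine
curve ships with the package. A user-supplied `wavelength_nm,value` CSV
can replace it; all shipped results use the parametric default so they
are self-contained.

Excitations are rectangular-rule inner products `e_p = Σ S_p(λ) Φ(λ) Δλ`
on a 380–780 nm, 2 nm grid (grid-refinement invariance is tested at the
0.1% level). Contrast is bipolar Weber contrast
`C_p = (e_p(arm+) − e_p(arm−)) / (2 e_p(background))`; because the printed
convention of the source experiments is not recoverable, every
`ContrastReport` also carries the unipolar contrast of each arm against
the background.

Melanopsin is treated as a pigment like any other; no intrinsic-response
kinetics are modeled.

## Stimulus design

The synthetic light engine has 56 Gaussian primaries (centers 400–700 nm,
16 nm FWHM, equal peak power) with settings bounded in [0,1], an optional
neutral-density scalar, and an optional dark light. Output is linear in
settings. Modulations are symmetric about the half-on background:
`pos = bg + d`, `neg = bg − d`.

With the background fixed, bipolar contrast is linear in `d`, so the
design problem — maximize the minimum targeted contrast subject to
|contrast| ≤ tolerance (default 1e-3) on every silenced pigment and the
gamut box — is solved as an epigraph program by SLSQP with 20 seeded
starts (the first start is the zero perturbation projected onto the
silencing null space). The multi-start search reproduces the exact
linear-program optimum on the default device and dominates 10,000 random
feasible modulations in the test suite; it remains correct if a nonzero
dark light or a nonlinear extension makes the problem genuinely nonlinear.
Targeted pigments may carry a sign (`("L", "-S")`) for opponent-channel
designs. Identical configuration and seed give bit-identical modulations.

Temporal profiles: a 1/6 Hz sinusoid (360 s) for pupillometry, and
12 s on / 12 s off blocked flicker (432 s, 1.5 s half-cosine onset/offset
ramps; 32/4/16 Hz carrier for L+S, L−S and light flux) for fMRI.
Luminance/irradiance metadata is device-specific and not a tested surface.

## Pupillometry

Border points are fitted with a direct least-squares conic ellipse
(scikit-image `EllipseModel`), iterated with gentle trimming: at each pass
points whose residual exceeds `max(threshold, 90th-percentile residual)`
are dropped and the ellipse refitted, until stable. Trimming at most the
worst decile per pass matters because a contaminated first fit inflates
the residuals of sound border points. A frame is "poor" when fewer than 5
points survive or the final RMSE exceeds 2 px (the source analysis never
quantified "poor"; this is our operational definition). An acquisition is
excluded only when *strictly more than* 50% of frames are poor.

Pupil area is expressed as percent change about the valid-frame mean and
fitted by OLS with regressors {1, sin 2πft, cos 2πft} at f = 1/6 Hz;
amplitude = √(β_sin² + β_cos²), phase = atan2(β_cos, β_sin) ∈ (−π, π]
(the polar convention is ours and fixed here). Session error is the
exhaustive bootstrap: all C(2n−1, n) multisets of the n acquisitions
(35 for n = 4) are averaged frame-wise, refitted, and the SD of the
resulting amplitudes (circular SD for phase, after rotation to the
circular mean) is the SEM. Average-then-fit is the default reading of the
ambiguous "repeat the fit across resamplings" recipe; fit-then-average
gives indistinguishable point estimates on the synthetic data. Video
segmentation itself (pupil/iris contrast detection, Purkinje masking,
motion correction) is out of scope: the package consumes border points or
area series and ships a border-point renderer for testing.

## BOLD preprocessing

Stages run in the narrated order: per-voxel mean-preserving linear
detrend → spike detection → confound regression → (for maps)
mirror-averaging.

Spike detection is two-stage MAD, with the raw MAD (no 1.4826 consistency
constant) and one-sided "above the median" rules taken literally (a
`two_sided` switch exists). A voxel sample is an outlier if it lies
≥ 6 MAD above that voxel's temporal median; a TR is flagged if its
outlier-voxel count lies ≥ 25 MAD above the median count. Two degenerate
rules: a voxel with zero temporal MAD contributes nothing, and a uniform
count vector flags nothing. Because most TRs in clean data have zero
noisy voxels, the count-MAD itself collapses to 0; it is floored at one
count, so the effective minimal threshold is 25 noisy voxels in a TR —
about 0.3% of the default volume. Measured on null Gaussian volumes the
false-flag rate is < 1% of TRs; single-TR offsets of ≥ 8 voxel-MADs on
≥ 2% of voxels are caught essentially always.

Motion confounds: 24 regressors (6 parameters, backward-difference
derivatives with first row zero, and squares of both), centered, reduced
by PCA to the smallest leading set reaching 95% cumulative variance.
Spike indicators are appended and the stacked matrix is regressed from
each voxel by QR projection (rank-deficient columns are dropped with a
warning), restoring the voxel mean.

Mirror-averaging is `(v + flip_x(v))/2` about the array center of the
sagittal axis, assuming template-space input; the registration between
original and flipped volumes is the identity in this synthetic template
space, a documented simplification of the full procedure. The operation
is exactly symmetric and idempotent.

## Forward model

The neural regressor is the unit square wave of the 12 s blocks (the
1.5 s stimulus ramps are intentionally not modeled; their effect is
absorbed by the HRF). It is convolved, per acquisition and at 10×
sub-TR resolution, with an HRF expressed as a weighted sum of three
unit-norm components: a canonical double-gamma kernel (peak 6 s,
undershoot 16 s, ratio 1:6), its temporal derivative, and its dispersion
derivative. A CSV-supplied basis can replace this set.

Per voxel, the model jointly estimates 3 kernel weights shared across the
6 concatenated acquisitions and one beta per acquisition, minimizing the
L2 residual. The problem is bilinear, so it is solved by alternating
exact OLS steps (betas given kernel; weights given betas), vectorized
across voxels, iterated to a 1e-8 weight tolerance with seeded restarts
of the weights; the per-voxel minimum-residual solution is kept. The
kernel is peak-normalized to 1 at every step, resolving the beta–kernel
scale degeneracy; betas are in percent signal change about the
acquisition mean (`100 (raw − mean)/mean`, computed before fitting) and
may be negative (thalamic responses are simulated and recovered with
negative sign). Noiseless recovery is exact to ≤ 1e-3.

R² maps are computed on the across-acquisition average series with a
single shared beta; zero-variance voxels get R² = 0 with no special flag
value. ROIs binarize the map (default threshold: top 0.5% of in-mask R²),
take 26-connected components, drop those under 10 voxels, and label the
survivors by size ("cortex", then "lgn" — the real study's 143/27-voxel
ROIs are reference metadata only). ROI response is the mean of
ROI-averaged betas across acquisitions, with SEM = SD/√n over
acquisitions; an acquisition subset selects a single stimulated eye.

## Synthetic data

The generator produces every input the pipeline consumes, deterministic
under its seed. Disease presets are multiplicative mechanism gains —
WT 1/1/1/1, RCD1 1/1/0.05/1, XLPRA2 0.4/0.4/0.3/1, CRD2 0/0/0.05/1
(L/S/rod/mel), and CRD2_treated restores the treated (left) eye with the
fellow eye at 0.1 — nominal values, since the source disease descriptions
are qualitative.

Pupil sessions: 12 acquisitions (4 per condition: L+S, Rod+Mel, light
flux), 360 s at 60 Hz. Each series is a 1/6 Hz sinusoid whose amplitude
is the light-flux anchor (10% area change in WT) scaled by the
mechanism-weighted, gain-weighted contrast of the condition; pupil drive
weights (L 1.0, S 0.25, rod 0.08, mel 0.02) encode cone dominance at this
frequency and background. An explicit `ls_lf_ratio` can pin the
L+S : light-flux amplitude ratio. Noise is 1/f with 2% SD; Poisson blink
events (0.1 Hz) mask 0.3 s windows.

BOLD sessions: 6 acquisitions per stimulus (3 left-eye then 3 right-eye),
24×24×16 voxels × 144 TRs at TR 3 s. Mirror-symmetric cortical (positive)
and LGN (negative) blob pairs respond with the boxcar convolved against
the canonical kernel; the evoked component is centered so the amplitude
parameter is defined about the acquisition mean, the same anchor the
analysis uses. Noise is AR(1) (ρ 0.3), plus per-voxel random linear
drift (≤0.5%), optional scheduled single-TR global spikes (5%), and
motion-coupled nuisance in 10% of voxels driven by a pseudo-physiological
6-parameter motion table.

What the generator does not emulate: spatially correlated noise and
physiological noise spectra, anatomically realistic geometry,
registration/distortion errors (volumes are born in template space),
partial-volume effects, habituation or nonlinear neural adaptation, and
session-to-session animal variability. Passing recovery tests therefore
demonstrate correctness of the estimation chain under the stated noise
model, not performance on real scanner data.

## Problem sizes and known limitations

Recovery studies use 100 pupil sessions and 50 BOLD sessions at the
volume sizes above — small enough to run comfortably on a single CPU
while leaving Monte-Carlo error well below the tolerances of interest.

Known limitations:

- Estimating the 3 HRF weights per voxel against noise inflates recovered
  response amplitudes slightly (≈ +0.35% relative at per-voxel SNR 1,
  measured against a fixed-true-kernel OLS control, which is unbiased).
  This is intrinsic to per-voxel kernel estimation, not to the alternating
  solver; it is far smaller than the acquisition-level SEM any single
  session reports.
- The ratio of two fitted amplitudes (pupil L+S : light flux) is a ratio
  estimator and carries O(SE²) bias; at the simulated noise level it is
  negligible relative to Monte-Carlo error.
- The spike detector's floored count threshold (25 voxels) makes its
  sensitivity depend on volume size for very small volumes.
- `mirror_average` assumes the sagittal midline sits at the array center
  of the x axis; off-center subjects must be resampled upstream.
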