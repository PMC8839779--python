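# Methods

This note documents the models, the numerical choices and the limits of
what the test suite demonstrates. Units are °C for temperatures, µS for
skin conductance, ms for beat intervals, Hz for rates.

## Study design emulated by the generator

Each synthetic subject contributes two 180 s sessions — *Rest* and
*Stroop* (stress) — with facial thermal video at 5 Hz (64×64 px frames by
default; the face occupies the central 60 % of the frame) and physiological
channels at 500 Hz. Class coding is 1 = Stroop, 2 = Rest throughout.

All randomness descends from a single root seed via
`numpy.random.SeedSequence` spawning: root → subject → session → signal
family (ROI trajectories; motion and pixel noise; EDA; RR; respiration).
Identical seeds therefore reproduce cohorts bit-for-bit, and adding a new
signal family cannot perturb existing streams.

### Planted stress effects (defaults)

The default preset reproduces the directional pattern expected for this
protocol; magnitudes are free parameters chosen once at realistic scales:

| effect | Rest | Stroop |
|---|---|---|
| nose/septum/periorbital mean shift | 0 | −0.3 °C |
| left-cheek mean shift | 0 | +0.2 °C |
| Std multiplier (forehead, cheeks, periorbital, maxillary) | 1.0 | 1.5 |
| tonic skin conductance | 2.0 µS | +1.0 µS |
| SCR rate | 2/min | 8/min |
| mean RR | 850 ms | 750 ms |
| LF / HF modulation amplitude | 25 / 40 ms | 40 / 15 ms |
| respiratory frequency | 0.25 Hz | 0.35 Hz |

The mean-temperature shift is realised as a linear ramp from
`shift − δ` to `shift + δ` (δ = min(0.15 °C, |shift|)) across the session:
its time average is the shift and its slope gives a DMean of
`2δ/duration` with the sign of the shift, so regions that cool also show a
negative temperature derivative, as observed under sympathetic
vasoconstriction. Side effect worth knowing: the ramp adds `2δ/√12` to the
session Std of shifted ROIs, so their Std also carries some effect even
though it is not in the informative-feature registry. Likewise the HF
modulation change propagates into RMSSD, pNN50, SD1, SD2 and std HRV,
which the registry includes.

ROI trajectories are Gaussian-smoothed white noise (≈2 s correlation
length) normalised to an exact session SD of 0.10 °C × the session's Std
multiplier, on a per-subject baseline drawn from 32.8–34.2 °C. Faces are
rendered as a 35.5 °C rectangle (inside the 30–38 °C skin band) on a 25 °C
background; the 2 °C-order contrast between ROI patches and the
surrounding face is what gives the block-matching tracker texture to lock
onto. Painted ROI patches (side ≈ 0.17 × face height) are strictly larger
than the extraction ROIs (2 % of face pixels), so integer tracking plus
median extraction recovers planted trajectories exactly at zero noise.
Head motion is a clipped ±1 px random walk (max ±3 px).

What the generator does **not** emulate: real facial geometry and
non-rigid deformation, emissivity and reflected-radiation artifacts,
camera NUC discontinuities, ECG waveform morphology (R-peak times are
emitted directly), EDA electrode artifacts, and any correlation structure
between modalities beyond the shared session label. Passing tests
therefore demonstrate the correctness of the *analysis machinery* under
the stated statistical structure, not performance on human recordings.

## Thermal processing

* Affine registration is the least-squares 2×3 solve from ≥3 non-collinear
  fiducial pairs; collinearity is checked at rank tolerance 1e−9.
* Stream pairing accepts the nearest RGB timestamp within half an RGB
  frame period; IR frames outside coverage are flagged, never dropped.
* Segmentation keeps pixels strictly inside (30, 38) °C and inside the
  face-contour polygon. ROI pixel count is `round(0.02 × face pixels)`
  laid out as a near-square rectangle centred on the landmark (the
  per-ROI proportionality constant is configurable; published sources
  specify proportionality but not the constant).
* Tracking is integer-displacement block matching: 11×11 template around
  the previous centre, ±5 px search, SSD objective, ties broken by
  smallest displacement. A track whose window would leave the image is
  flagged lost and frozen. This satisfies the same contract as pyramidal
  KLT on the rendered data without implementing optical flow.
* Cleaning: a centred, edge-truncated moving median (window 5 = 1 s at
  5 Hz) iterated to its fixed point — repeated median smoothing reaches a
  root signal, making cleaning idempotent — followed by outlier
  replacement: session mean/SD computed once on the smoothed signal,
  samples beyond 3 SD replaced by the nearest-in-time non-outlier value.

## Electrodermal decomposition

Skin conductance is modelled as y = h∗p + Bℓ + Cd + ε with h the Bateman
biexponential (rise 0.7 s, decay 2.0 s, unit peak), p ≥ 0 the sparse
sudomotor driver at the working rate, B a clamped cubic B-spline basis
with knots every 10 s (coefficients ℓ², weight γ = 1e−3), and C an
unpenalized offset + linear drift. The driver carries an ℓ1 weight
α = 0.05 µS⁻¹·sample. Because p is nonnegative, ‖p‖₁ is a linear term and
the program is smooth over the feasible set; it is solved with L-BFGS-B
using exact gradients, with all convolution operator products done by FFT
(no dense system matrix). The recording is polyphase-decimated to 25 Hz
first — both EDA components live far below that bandwidth and the problem
shrinks 20-fold. The residual is reported as the model's noise term, so
tonic + phasic + noise reconstructs the input exactly by construction.
α was fixed during solver bring-up by requiring clean recovery of planted
0.5 µS responses over 0.01–0.02 µS measurement noise; at these settings
planted events are localised to well under 1 s.

SCR peaks are local maxima of the phasic component with **prominence**
≥ 0.01 µS. Prominence (trough-to-peak rise) rather than absolute height is
the standard SCR amplitude convention and matters at stress event rates:
overlapping responses keep the phasic baseline elevated, where an absolute
height criterion both overstates amplitudes and counts micro-fluctuations
on decay tails as events.

Feature windows follow the session protocol: tonic statistics in
non-overlapping 20 s windows, phasic statistics in 5 s windows (a 180 s
session gives 9 and 36 windows; trailing remainders are discarded;
windows without a peak contribute 0 to peak-derived features), and
EDAsymp as Welch power (60 s mean-detrended segments, 50 % overlap) of the
raw conductance in 0.04–0.25 Hz.

## HRV and respiration

Beats whose interval deviates from the centred 11-beat local median by
more than 30 % are flagged and replaced by cubic-spline interpolation over
valid beats (an error above 50 % flagged). The tachogram is cubic-spline
resampled at exactly 4 Hz over the session; the working unit is
instantaneous heart rate (bpm), with RR (ms) available behind a flag —
chosen because mean HRV is expected to *rise* under stress, which holds
for heart rate, not for RR. Frequency features use a Welch spectrum (64 s
linearly detrended segments, 50 % overlap); LF = [0.04, 0.15) Hz,
HF = [0.15, 0.40) Hz, expressed as percentages of their sum (the VLF band
is excluded from the denominator, which published descriptions leave
unspecified), so LF% + HF% = 100 by construction. Poincaré axes use the
population-SD convention, which preserves SD1 ≡ SD(ΔRR)/√2 exactly;
sample entropy uses m = 2, r = 0.2 × SD, Chebyshev distance, self-matches
excluded, with degenerate cases (constant series, no matches) returning 0.
The respiratory rate is the dominant Welch peak in 0.05–1 Hz, required to
exceed 5× the median in-band power.

## Statistics

The paired Wilcoxon signed-rank test discards zero differences (classic
treatment) and requires ≥5 nonzero pairs. For n ≤ 25 the two-sided p-value
is exact: the null distribution of the positive rank sum is built by
integer convolution over doubled midranks, which remains exact under tied
ranks; above 25 the tie-corrected normal approximation is used. BH-FDR is
applied across all features of an analysis run as one family.

## Feature selection and classification

Stage 1 keeps features whose Pearson (point-biserial) correlation with the
class coding has p ≤ 0.05, in original column order; zero-variance
features are excluded with a warning.

Stage 2 is ν-SVM RBF recursive feature elimination (ν = 0.5, γ = 1/p with
p the surviving feature count — the LIBSVM defaults; features z-scored).
At each step the fitted dual coefficients are held fixed and each
feature's criterion is c_f = |W²(α) − W²₋f(α)| where
W²(α) = ΣᵢⱼαᵢαⱼyᵢyⱼK(xᵢ,xⱼ) and K₋f is recomputed (multiplicatively, via
exp(γ d_f²)) without feature f. The least-influential feature is removed;
ties break by column order; the last survivor has rank 1.

**Correlation-bias reduction.** Highly correlated features share their
influence, so their individual criteria are mutually suppressed and whole
informative clusters can be eliminated early. Before each elimination,
features are clustered by single linkage on |Pearson r| > 0.7, and every
member whose criterion falls below the cluster's *joint* removal criterion
|W² − W²₋cluster| is raised to it. Simply averaging member criteria — a
plausible reading of the cited correction — is a no-op for exact
duplicates (their criteria are equal) and empirically fails to prevent
the bias; the joint-removal form corrects it (duplicated-informative
experiment: both copies in the top ranks in 25/30 seeds with the
correction versus 1/30 without).

Known limitation: the kernel-space criterion saturates for a very strongly
separating feature (its between-class kernel entries are ≈0 with or
without it), so in the final two-feature duel such a feature occasionally
loses to noise and ends ranked 2nd. This is a property of the nonlinear
RFE criterion itself, visible only when a single feature is already nearly
perfectly separating.

LOSO cross-validation always keeps both of a subject's sessions in the
same fold. Two ranking protocols are provided: `pooled` (filter and rank
once on the pooled table, then cross-validate each top-k subset — matching
the construction of a single global ranked axis and accuracy curve) and
`strict` (filter + rank refit inside each training fold; leakage-free and
methodologically preferred, provided for comparison). Default `pooled`.
Degenerate training folds where the ν-SVM dual is numerically infeasible
(e.g. a two-valued quantized feature with conflicting labels) fall back to
majority-class prediction for that fold.

## Problem sizes and calibration checks

The suite and the acceptance script use: the full 19-subject cohort at
default settings for classifier-level checks; 5-subject cohorts at 48×48
px and 100 Hz physiology for structural and end-to-end tests; and
generator-level nulls (50 seeded replicates) for exchangeability. The
null-label calibration permutes session labels within subjects of the
19-subject cohort (20 permutations) and compares the LOSO accuracy —
averaged over rank depths, to avoid the selection bias of the max — with
the 95 % binomial band around 0.5 for 38 observations. Under the default
preset the planted effects are strong relative to the generator's noise,
so all three feature sets saturate near 100 % LOSO accuracy; the
acceptance bounds (Full ≥ 90 %, Thermo ≥ 75 %) are met with margin.
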