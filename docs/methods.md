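# Methods

## Transit model and estimator

The package treats the pulmonary circulation as a linear transport system
for an intravascular indicator. The RV first-pass bolus is modeled as a
gamma-variate `A (t - t0)^alpha exp(-(t - t0)/beta)`, the standard
parametric form for indicator-dilution curves; the LV first pass is the RV
curve convolved with a transport kernel. Because convolution with a
normalized kernel adds the kernel mean to the first moment, the LV/RV
centroid difference equals the mean transit time regardless of the kernel's
shape — this is what makes the centroid (rather than peak-to-peak) estimator
unbiased under dispersion, and it is the invariant the test suite checks
numerically.

Estimation excludes recirculation before computing centroids:

* **centroid-of-fit (default).** A gamma-variate is fitted by bounded
  nonlinear least squares (amplitude, alpha and beta in log space;
  `scipy.optimize.least_squares`, trf, ftol = xtol = gtol = 1e-12, at most
  2000 function evaluations) over the window from the curve foot to the
  first post-peak sample below 40% of peak. The centroid is the closed form
  `t0 + beta (alpha + 1)`, so the late tail never needs to be observed.
  Initialization: t0 at the foot, alpha = 3, beta from the time to peak,
  amplitude from the peak value. A fit is accepted when the optimizer
  reports convergence and the residual RMS is below 25% of peak; otherwise
  the truncation method is used and flagged.
* **centroid-of-truncated-curve (fallback).** The measured curve is cut at
  the post-peak running minimum preceding any secondary rise (hysteresis 2%
  of peak) and the discrete trapezoidal first moment is taken. Truncation
  biases each cavity's centroid early because the gamma tail is cut, but the
  bias is nearly equal in the two cavities and cancels in the difference;
  on noiseless phantoms the two methods agree within ~0.2 s.

Curves are used at their native one-sample-per-heartbeat resolution; no
interpolation is applied before moment computation. Arrival detection uses
the earliest frame exceeding baseline + max(5 SD, 5% of peak enhancement)
(earliest qualifying frame on plateaus).

Quality control mirrors clinical exclusion practice: poor AIF signal (peak
below 0.5 mmol/l, a repository convention), incorrect contrast timing
(enhancement already present at the first frame, i.e. no baseline),
blood-pool identification failure, non-positive PTT (swapped labels), and a
physiological plausibility window of 2–30 s (convention, motivated by the
range seen clinically; flagged, not excluded).

## Image-based AIF extraction

Blood pools are segmented classically: per-pixel peak enhancement (peak
minus the mean of the first 3 frames) is thresholded at its 0.90 quantile,
8-connected components above 20 pixels are kept, each is morphologically
closed and hole-filled, and the two largest are labeled RV/LV by
time-to-peak order (the bolus reaches the RV first). The quantile default
assumes the two cavities occupy roughly the top decile of enhancing pixels
on a basal short-axis view; it is configurable for other fields of view.

Signal is converted to concentration through a monotone forward map from
concentration to normalized enhancement `(S - S0)/S0`. The default is a
one-parameter hyperbolic saturation `f(c) = gain * c / (1 + c/c_sat)` with
`c_sat` = 8 mmol/l and gain 1, closed-form invertible; user-supplied
monotone look-up tables are supported through the same interface.
Enhancement beyond the invertible range raises an error rather than
silently clipping. The baseline is the mean of the pre-arrival frames
(all frames before RV arrival minus 1); fewer than 3 baseline frames raises
a timing QC flag.

## Hemodynamics and units

`CO = SV x HR`, `PBV = PTT x CO`, `PBVi = PBV / BSA`. Canonical internal
units are s, ml, ml/s and m^2; a light unit layer rejects quantities
carrying other units (notably cardiac output in l/min) unless converted
explicitly, because the indicator-dilution product requires CO in volume
per second to match PTT's seconds. BSA defaults to Mosteller
(`sqrt(height x weight / 3600)`), with Du Bois selectable; the choice is
recorded in output metadata. The formula choice matters at the ~1% level
for typical adults.

## Synthetic data: what it emulates and what it does not

**Curve phantoms.** Gamma-variate first pass (default alpha = 3, beta = 2 s,
onset 4 s, peak 5 mmol/l — a typical first-pass peak for a compact bolus),
truncated-Gaussian transport kernel (mean = true PTT, default SD 1 s),
recirculation as each cavity's own first pass delayed 15 s and scaled by
0.3, additive Gaussian concentration noise, one sample per R-R interval
(default 0.9 s) over 90 heartbeats. Ground-truth centroids are computed by
trapezoidal quadrature of the noiseless, recirculation-free components on a
0.01-s grid extended until the gamma tail mass is below 1e-13, so the
oracle's own discretization error is orders of magnitude below the
tolerances tested. Not emulated: MR physics (Rician noise, saturation of
the measured signal is only applied in the image phantom), breathing motion,
arrhythmia (sampling jitter), and contrast-dose nonlinearities.

**Image phantoms.** 64 x 64 grids with disk cavities, a myocardial annulus
following a delayed 15%-amplitude copy of the LV curve, static background
at 60% of baseline signal, cavity signal generated through the forward
saturation model, optional Gaussian pixel noise parameterized by SNR =
(peak cavity enhancement)/(pixel SD). Not emulated: partial-volume edges,
coil shading, motion. Passing segmentation tests therefore demonstrates
the contract (masks + arrival-order labels), not robustness to real-scan
artifacts.

**Cohorts.** Covariates are drawn from independent marginals with clinically
typical means/SDs and prevalences, clipped to physiological ranges before
the generating model is evaluated so the linear model holds exactly on the
delivered table. log_e PTT is linear in the covariates with the clinically
reported coefficient signs and magnitudes (LA area +0.019 per cm^2/m^2,
heart rate -0.008 per beat/min, age +0.003 per year, AF +0.118, LVEF -0.007
per %, diabetes -0.060, hypertension -0.038, rest MBF -0.098 per ml/g/min,
male +0.052), intercept 2.686 and noise SD 0.26, chosen so the generated
PTT distribution has median ~7.7 s and SD ~2.4 s. Because the marginals are
independent, the explained variance (r^2 ~ 0.2) is necessarily lower than
in clinical data where these covariates are strongly inter-correlated; the
generator prioritizes the PTT scale and SD, which the power and per-SD
calculations depend on. Events follow a Weibull proportional-hazards model
`H(t) = (scale * t)^shape * exp(beta_SD (PTT - 8)/2.4)` with scale
0.0024/month and shape 1 (about 8% events over a 20–40 month administrative
follow-up), so `scale` acts as a hazard-rate multiplier and more scale means
more events. `censor_rate` selects a Bernoulli fraction of subjects whose
independent censoring time is Uniform(0, (1 - rate) x follow-up max); the
shrinking window is a convention that makes rate = 1 censor everyone at
time zero. Early revascularization, when enabled, is assigned to a random
hazard-independent subset with days Uniform(1, 90).

## Cohort statistics

Group comparisons screen normality per group with a Lilliefors
Kolmogorov-Smirnov test and fall back to Mann-Whitney (the conservative
default); binaries use chi-square. The log-PTT model is OLS with
unstandardized betas, 95% CIs, standardized betas and r^2; rank-deficient
designs are rejected naming the collinear columns via pivoted QR. Cox
models scale the predictor by its cohort SD (or a supplied SD) before
fitting — equivalent, to machine precision, to multiplying the raw
coefficient by the SD — and report the HR per 1 SD, its Wald 95% CI, the
likelihood-ratio model chi-square, and scaled Schoenfeld-residual p-values
per covariate. Ties use the Efron approximation. The optional sensitivity
refit adds an L2 penalty (default 0.1) on the partial likelihood, shrinking
estimates toward the null as a guard against low-event-count bias; it is a
penalized refit, not an exact Firth correction, and is labeled as such in
the output. p-values are unadjusted. Death is censoring for the MACE
analysis; competing-risks models are out of scope. The early-
revascularization sensitivity censors affected subjects at the
revascularization date (days/30.4375 months) and refits the identical
specification, so an empty affected set reproduces the base fit exactly.

## Problem sizes and numerical conventions

Simulation-based tests use 50–200 phantom replicates and 100-replicate
coverage/power studies at n = 1000–2000 subjects — sizes at which the
Monte-Carlo error of the checked quantities is comfortably below the
asserted bounds. Coverage assertions (>= 93/100) sit about one binomial SD
below the nominal 95%, so occasional seeds can land at 91–92 without
indicating a defect; the acceptance script reports the measured value for
the seed it is given. All generators accept explicit integer seeds and are
bitwise reproducible; numeric file output is written at 9 significant
digits; JSON keys are sorted so output hashes are stable.

## Known limitations

* The segmenter's quantile threshold presumes the cavities dominate the
  top-decile enhancement; very small cavities or strongly enhancing
  extra-cardiac structures would require retuning.
* The gamma-variate fit's centroid inherits a small (~0.1 s) systematic
  error when the true LV curve is a dispersed gamma rather than an exact
  one; this is visible in the noiseless phantom bias and is well below the
  one-heartbeat sampling resolution.
* Stress curves are processed identically to rest curves; no
  stress-specific physiology is modeled.
* The unit layer is advisory at the float level: a bare float in the wrong
  unit cannot be detected, only labeled quantities are checked.
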