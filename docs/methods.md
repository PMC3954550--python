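# Methods

`tfdyn` quantifies the nuclear mobility of ligand-activated transcription
factors (the glucocorticoid and mineralocorticoid receptors, GR and MR) with
two complementary analyses — single-molecule displacement analysis by
Particle Image Correlation Spectroscopy (PICS) and Monte Carlo fitting of
strip-FRAP recovery curves — and with a synthetic-data generator that stands
in for the microscope so that every stage can be validated by parameter
recovery against known ground truth.

## The mobility model

A receptor molecule is in one of three states:

* **free** — 3D diffusion with coefficient `D_free` (order 1–3 µm²/s);
* **short bound** — immobilized on chromatin with mean residence time
  `tau_short` (0.4–1 s);
* **long bound** — immobilized with mean residence time `tau_long` (1–4 s).

Residence times are exponential, so the state process is a continuous-time
Markov chain shaped like a star (free ↔ short, free ↔ long).  Only mean
immobilization times are identified by either technique, which an
exponential dwell reproduces with the fewest assumptions.  Given equilibrium
fraction sizes `(f_free, f_short, f_long)` the unbinding rates are `1/tau`
and the binding rates follow from detailed balance,
`k_free→s = (f_short/f_free)/tau_short` (and the long-state analogue), so the
chain's stationary distribution equals the fractions exactly
(`kinetics.rates_from_fractions`; a Gillespie occupancy oracle cross-checks
this in the tests).  `f_free = 0` is allowed only with infinite residence
times (the fixed-cell control).

In the single-molecule simulator bound molecules creep with an apparent
`D_bound = 0.03 µm²/s`, matching the slow constrained motion of chromatin
itself; in the FRAP simulator bound molecules are strictly immobile, because
chromatin drift over a 1 µm strip during 55 s is negligible.

## Single-molecule simulator (`tfdyn.motion`)

The imaging protocol is stroboscopic wide-field microscopy: series of 8
frames at a 6.25 ms or 12.5 ms lag, 180 series per cell, 20 cells, a 50×50
pixel region of interest (220 nm pixels), ~1.5 detected molecules per frame,
~40 nm localization error per axis.  Series are statistically independent
(the instrument bleaches through many molecules between series), so
correlations exist only within a series — exactly the structure PICS
assumes.

Numerical choices:

* State evolution uses the exact per-lag transition matrix `exp(Q·dt)`;
  the displacement over a lag uses the diffusion coefficient of the state
  occupied at the start of the step (state dwell ≫ frame lag, so mid-step
  switches are a sub-percent effect).
* Molecules are seeded uniformly in a volume extending 1 µm laterally
  beyond the ROI; the Poisson molecule count per series is calibrated so the
  *visible* mean matches 1.5 peaks/frame.
* Axial detection is unbounded by default.  At lags ≤ 37.5 ms the axial
  diffusion length (≈0.3 µm) is far below a wide-field depth of detection,
  and a hard 1 µm slab would deflate the apparent diffusing fraction by
  ~5 percentage points through displacement-dependent partner loss — an
  artifact of the hard cut-off, not of the experiment, which restricts
  itself to short lags precisely so that 3D escape is second order.  A
  finite `detection_slab` remains available as a stress test of that bias.
* Blinking and photobleaching default to off; PICS is robust to them, and
  they are exposed as opt-in stress parameters.

## PICS (`tfdyn.pics`)

For each frame pair `(t, t+lag)` within a series, `correlate` counts, per
frame-`t` localization, the frame-`(t+lag)` localizations within distance
`l`, producing a cumulative correlation `C(l²)`.  Uncorrelated molecules
contribute `ρ·A(l)`, where `A(l)` is the expected disc∩ROI search area
(`πl² − (8/3)l³/L`, the first-order edge correction for a square field of
side `L`); the correlated contribution plateaus at the redetection
probability.  `C(l²) = c₀ + ρ·A(l)` is fitted over a background window
(default `l² ∈ [1, 4] µm²`, ≥5× the largest correlated MSD yet ≤2 µm ≪ L,
configurable), and `P_cum(l²) = (C − ρA)/c₀`, clipped to [0,1] and
monotonized.  Curves with fewer than `min_pairs` references are flagged and
excluded.

Each per-lag `P_cum` is fitted with the two-population model

    P_cum(l²) = 1 − [α·exp(−l²/MSD₁) + (1−α)·exp(−l²/MSD₂)]

by bounded least squares with eight deterministic multistarts (ties broken
by residual, then smaller α); `MSD₁ ≥ MSD₂` is enforced by swapping.  A
three-population variant exists behind a flag but is not used by default —
it is not consistently identifiable across lags.  The default model
additionally multiplies the mixture density by the exact square-field
pair-survival probability `1 − 4r/(πL) + r²/(πL²)` (set covariogram):
without it, pairs whose second localization left the field compress the
observed displacement distribution and deflate the fitted MSDs by 4–6%,
which propagates into `D_fast`.  The plain closed form is used when no
field size is supplied.

`MSD₁` and `MSD₂` are regressed on the lag (all lags from 6.25 to 37.5 ms;
the 12.5/25/37.5 ms lags pool both acquisition series) with a free
intercept, which absorbs the localization-error offset `4σ_loc²` so that
`D = slope/4` is not contaminated by it.  The regression is unweighted by
default: the per-lag standard errors come from only 3 cell groups (2
degrees of freedom), and inverse-variance weighting with variance estimates
that noisy is anti-conservative.  `weighted_msd_fit=True` restores 1/SE²
weighting.  α is reported as the mean over lags.  Uncertainties follow the
experimental scheme: cells are partitioned into 3 near-equal groups (7/7/6
for 20), the entire analysis is re-run per group, and SEM =
SD(group estimates)/√3.

## Synthetic camera frames (`tfdyn.imaging`)

To validate the localization step itself, `render_frames` draws each
molecule as a pixel-integrated 2D Gaussian (PSF SD 0.17 µm ≈ 400 nm FWHM,
100 photons by default) on a background with Poisson shot noise plus
Gaussian read noise; `fit_peaks` detects local maxima above 4 background
SDs and fits an offset integrated Gaussian (two components jointly when
candidates are closer than twice the FWHM; widths outside 0.45–2.5× the
expected PSF width are rejected as noise spikes).  The quoted per-axis
accuracy is `FWHM/√N`; at the reference condition (SNR ≈ 8) the empirical
refit scatter is ~34 nm, consistent with the quoted ~40 nm within 25%.
This module is optional in the pipeline — PICS normally consumes
localization tables directly from the motion simulator.

## Strip-FRAP Monte Carlo (`tfdyn.frap`)

The nucleus is an ellipsoid with semi-axes 6×4×2.5 µm; the bleach/detection
region is a 1 µm-wide slab through the center, normal to the long axis,
spanning the full cross-section.  Neither dimension is known from the
experiments; recovery-curve shape is insensitive to them to first order
because all quantities are normalized to the pre-bleach baseline.
Particles (default 20 000 per cell × 30 replicate cells, pooled into one
ensemble — replicates are i.i.d., so pooled counting equals curve
averaging) start uniform in the ellipsoid with stationary state labels.

Free particles take Gaussian steps (variance `2·D_free·dt` per axis,
default `dt = 50 ms`, exact for free diffusion at any `dt`); steps that
would leave the nucleus are rejected, which — the proposal being symmetric
and the target uniform — preserves the uniform equilibrium density exactly
(a zero-flux boundary without reflection geometry).  State switches use
exact exponential probabilities `1 − exp(−k·dt)`.  The protocol is 40
pre-bleach scans at 100 ms, a 100 ms bleach, and 55 s of recovery at 100 ms
intervals.  During the bleach the survival probability is applied per
sub-step (5 sub-steps), so molecules transiting the strip receive a dose
proportional to their residence.  The full-residence survival (0.16) was
calibrated once so that the first recovery sample of the reference
agonist-bound GR condition lands at ~30% of baseline — the observed bleach
depth — and then frozen; it is deliberately lower than 0.30 because free
molecules exchange with the strip during the bleach window.  Observation
does not bleach (fixed-cell controls show no loss during recovery), so the
fluorescent count is conserved outside the bleach window, which the tests
assert exactly.

## FRAP grid-search fit (`tfdyn.frapfit`)

A target curve is fitted by simulating candidate three-population models
and ranking them by ordinary least squares over the recovery phase
(pre-bleach samples are used for normalization, not fitting).  `D_free` is
fixed at the single-molecule estimate; the four free parameters are sampled
on the stated bounds — short and long bound fraction 0–90% (sum ≤ 90%),
`tau_short` 0.1–1 s linear, `tau_long` 1–300 s logarithmic (its range spans
2.5 decades).  The top-10 candidates are averaged (± SEM = SD/√10) and the
mean of their curves is the fitted curve.

Candidate curves are simulated with common random numbers (CRN): one
shared stream of initial positions, step proposals and switching uniforms
drives every candidate (consumption is parameter-independent), so curve
differences between candidates are parameter-driven rather than
noise-driven.  Candidates skip the pre-bleach phase, are normalized by the
exact expected baseline (particle count × strip volume fraction, which for
the slab |x| ≤ h·a is `(3h − h³)/2`), and their bleaching is
Rao-Blackwellized — particles carry survival probabilities instead of
sampled bleached/fluorescent flags, which has the same expectation and
strictly less variance.

Two statistical pitfalls shape the search design.  First, the raw SSE of a
Monte Carlo candidate contains the candidate's own sampling variance, and
that variance depends on its parameters: deeply bleached (high-bound)
candidates produce lower-intensity, intrinsically less noisy curves, so
noise-limited ranking by raw SSE systematically drifts toward too-large
bound fractions.  Candidates are therefore compared by a variance-corrected
SSE — `Σ_t (Ī_t − target_t)² − Var̂(Ī_t)`, with the variance estimated
unbiasedly from the between-subgroup scatter of 8 particle subgroups
(algebraically the cross-product U-statistic over subgroup pairs); it can
dip slightly below zero at the noise floor.  Second, the model family has
a soft, nearly degenerate direction: a larger short-bound fraction with a
residence time near the scan interval mimics free diffusion, so
coarse-fidelity comparisons cannot order candidates across different total
bound fractions.  The search therefore keeps bound-fraction diversity
alive until the final, high-fidelity comparison: (1) every grid candidate
is screened at a few thousand particles; (2) a pool — the best
`stage2_pool` overall, the best `band_pool` of every total-bound band, and
a "band centre" (even split, mid residence times) per band — is
re-simulated at `final_particles` (default 120 000), where parameter
differences dominate; (3) CRN pattern descents polish the best
band-distinct incumbents (local comparisons are reliable at intermediate
particle counts because neighbouring candidates share their noise), and
each descent's leaders are promoted to final fidelity.  Ranking, top-10
averages and the fitted curve use final-fidelity scores only; ties break
toward the smaller total bound fraction.  Setting `refine_passes=0`
recovers a pure pre-simulated-library search over the grid.  The
`sensitivity_dfast` helper re-runs the full fit at
`D_free − SEM, D_free, D_free + SEM` and reports the spread of every
averaged parameter.

## Pipeline and scales

`run_experiment` chains the stages as the combined experimental design
does: simulate localizations → PICS → simulate the FRAP target from the
condition's FRAP parameters → grid-search fit with `D_free` fixed at the
*PICS estimate* → a per-condition report including the SMM-vs-FRAP
bound-fraction cross-check.  Twenty condition parameter sets (GR and MR
under their ligand panels, three GR domain-deletion mutants, a no-hormone
control and a fixed-cell control) ship as YAML fixtures; the two controls
contain synthetic stand-in values where no measured numbers exist and are
marked as such.  The `reduced` profile (5 cells, 2 000 FRAP particles,
coarse grid) exists for quick structural runs.  Headline recoveries use
the full protocol sizes for the simulated single-molecule data (20 cells
of 180×2 series) and, on the FRAP side, a 50 ms simulation step, a target
curve averaged over 30 cells × 35 000 particles (particles per replicate
is a Monte Carlo fidelity knob; real nuclei carry ≥10⁵ fluorophores, so
even this understates experimental curve SNR), candidates fitted over the
first 20 s of recovery (the reference condition is fully recovered by
then; the remaining tail contributes noise-dominated samples at Monte
Carlo SNR), the full stated 10×10×5×8 grid for screening, and staged
fidelities of 2 000 / 120 000 / 400 000 particles for screening, pool
re-scoring and the final re-ranking — sizes chosen so a complete recovery
runs on a desktop core in minutes.

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the analyses rely on:
state mixing at equilibrium, 2D projection of 3D motion, localization
noise, finite fields of view, uncorrelated background molecules, strip
bleaching with partial dose for transiting molecules, replicate averaging.
It does not emulate depth-dependent PSF blur, detector pixelation effects
on localization (except in `tfdyn.imaging`), chromatin micro-domains,
anomalous diffusion, reversible photobleaching, or cell-to-cell parameter
variability — every synthetic cell shares one parameter set.  Passing
recovery tests therefore demonstrates that the estimators are consistent
for the stated model at realistic data volumes, not that the model captures
every feature of receptor motion in living nuclei.

## Cross-validating the two techniques

The design's central consistency check is that the bound fraction measured
by PICS on single-molecule data agrees with the combined bound fraction
fitted from FRAP data generated by the *same* three-state model.  The
tests run this round trip for five conditions at a reduced scale: one
shared generating model per condition, a 12 s recovery window (all sampled
conditions recover by then), a 50 ms simulation step (at a 0.1 s step the
`tau_short = 0.1 s` mimic of free diffusion becomes a discretization
artifact), and a synthetic target averaged over 30 cells × 35 000
particles — still far below the fluorophore numbers behind a real
recovery curve, so the synthetic targets are, if anything, noisier than
experiment.  Four of the five conditions agree to well within 8 percentage
points.  The corticosterone-bound GR does not (≈10 points): with
`D_free = 2.49 µm²/s` and weak binding, the best-fitting mimic (39% bound,
`tau_short` at the 0.1 s bound) and the near-truth candidate (26% bound)
produce curves differing by less than one part in 10⁴ of the least-squares
norm — below any affordable Monte Carlo resolution, and consistent with
this condition showing the largest technique discrepancy in real
measurements as well.

## Known limitations

* The diffusing-fraction and MSD estimates retain a small (≈1–4%)
  downward bias from state switching within a lag and residual edge
  effects; it is well inside the study's standard errors.
* `tau_short` and `tau_long` are resolved only to a few tenths of a second
  at the simulated data volumes; the SSE ridge between "more short-bound,
  shorter dwell" and "fewer bound, longer dwell" is genuinely shallow, and
  for fast-diffusing, weakly bound conditions the total bound fraction
  itself inherits that softness (see above).
* The FRAP simulator's time step under-resolves residence times near the
  0.1 s lower search bound; target and candidates share the same step, so
  round-trip comparisons remain fair.
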