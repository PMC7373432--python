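# Methods

This note documents the models, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Psychometric model and fitting

2AFC performance is modeled as `Psi(x) = gamma + (1 - gamma - lambda) *
Phi(beta (x - alpha))` with `gamma = 0.5` and `lambda = 0` fixed, `alpha`
in mA and slope `beta = 1/sigma` in mA⁻¹ (reported per µA where JND-scale
slopes are quoted). The likelihood is binomial over levels; repeated
amplitudes are merged into one level before fitting. Optimization is over
`(alpha, log beta)`: a 13 × 4 coarse grid seeds three Nelder-Mead refinements
(xatol 1e-7, fatol 1e-10) and the best is kept. A grid-oracle test checks
that the optimum dominates a 201 × 201 search to 1e-4 in log-likelihood.
Data with all accuracies at the guess floor or at ceiling are not
identifiable; the fit is returned with `converged=False` rather than raising.

Thresholds and JNDs are `Psi^{-1}(0.75)`, which with the fixed rates equals
`alpha` identically. Task-level exclusion follows the accuracy band rule:
exclude when every level is below 0.6 or every level is above 0.9. When an
electrode is measured on several days, per-electrode threshold averaging
precedes the subject mean; exclusion is applied per task before averaging
(the alternative ordering is not distinguishable from the available
descriptions, so the simpler one is used).

JND trials are pooled over whether the test fell above or below the
standard and fit on `|test − standard|`; the signed-Δ alternative was left
aside because the comparison-list composition is not constrained by
anything we implement against.

**pTLR.** Goodness of fit simulates `n_sim` datasets (default 1000; 200 in
the pipeline for speed) from the fitted curve at the observed levels and
trial counts, refits each starting from the generating parameters
(single-start: the generating values are near-optimal for their own data),
and reports the fraction of simulated deviances ≥ the observed deviance.
Deviance is `2(LL_saturated − LL_model)`, so larger pTLR means better fit
and the statistic is exactly the transformed likelihood ratio. Refit
failures are counted; more than 10% flags the result. A calibration test
(200 outer × 250 inner) verifies the rejection rate at 0.05 stays within
5% ± 2% and the pTLR distribution is near-uniform under the true model.

## Staircase

One-up three-down with multiplicative 2 dB amplitude steps
(`10^(±2/20)`), amplitude decibels because amplitude is the controlled
variable. The consecutive-correct counter resets after every amplitude
change and after any incorrect response. A reversal is a sign change
between consecutive *realized* amplitude movements; a step clipped into a
no-op at the 0/6 mA bounds creates neither movement nor reversal. The run
ends at the fifth reversal (trial cap 200 guards non-termination). The
threshold estimate is the mean of the last 10 trial amplitudes up to and
including the trial whose response triggered the fifth reversal; with fewer
than 10 available, all are used and the run flagged. The estimator is
scale-equivariant (scaling observer and bounds by c scales the estimate by
c), which the suite checks by replaying identical random streams.

## Magnitude estimation and binning

Block 1 is a familiarization pass and is dropped; remaining ratings are
divided by their mean with zero ("nothing felt") ratings included, so the
normalized mean is 1. Zeros also participate in binning (they fall in the
lowest bin); leaving them out would bias low-amplitude accuracy upward.
Model comparison fits a line (OLS; slope F-test gives `p_int`), a
logarithm `a + b ln x`, and a 3-parameter logistic `L / (1 + e^{−k(x−x₀)})`
(nonlinear least squares; non-convergence recorded, comparison proceeds),
each scored by adjusted R² with its own parameter count; the linear model
wins ties. For discriminability, each electrode's amplitudes and ratings
are normalized by their own maxima over all its sessions, partitioned into
k equal-width bins on [0, 1] (half-open, last bin closed so the maximum is
in the top bin), and accuracy is the fraction of matching bin indices,
pooled per trial across electrodes and subjects (per-electrode averaging is
available as an option).

## Percept maps

The calibrated template is a stylized upper limb rasterized at 0.5 mm/px
with eight labeled segments. Two independent calibrations are kept:
distances use the 189 mm hand length, areas use the 75 cm² palm area
(applying one constant to both quantities would make them mutually
inconsistent; each is applied only to its own quantity). Area is pixel
count × per-pixel area; centroid is the unweighted mean of member-pixel
centers; overlap is `|a ∩ b| / min(|a|, |b|)` so containment scores 1 and
the >70% display rule keeps the more focal mask. Stability uses the
reference amplitude covering the most distinct weeks (≥ 2, minimum
amplitude on ties), weekly means over repetitions, Euclidean migration of
consecutive weekly mean centroids, and consecutive area differences
reported both signed and absolute — the headline medians are quoted on
absolute values, since a signed median conflates direction with magnitude.

## Stability statistics

Threshold charge is first-phase amplitude × pulse width (mA·µs = nC).
Week effects use `scipy.stats.f_oneway` and `scipy.stats.tukey_hsd`
(Tukey-Kramer for unbalanced weeks). The trend model is linear regression
with AR(1) errors by iterated feasible GLS (statsmodels `GLSAR`,
Cochrane-Orcutt style updates to convergence); it reports the trend
coefficient and p-value, the estimated error autocorrelation ρ (|ρ| ≥ 1
flagged non-stationary), and the Durbin-Watson statistic of the OLS
residuals. Exact parity with any particular commercial AUTOREG
implementation is not attempted. Affine alignment from landmark pairs is
the least-squares solution of the linear system (rank-deficiency on
collinear landmarks raises); image scale comes from a 3 mm contact's pixel
length; rostro-caudal migration is the tip displacement projected on the
caudal-positive axis.

## Synthetic data generator

Defaults are the study conditions: 4 subjects with (2, 5, 14, 14)
electrodes, subject-level mean thresholds (3.75, 1.25, 1.58, 1.94) mA,
4 weekly sessions (2 for subject 2), 6 mA amplitude ceiling, 200 µs pulse
width. Per-electrode observers draw `mu` lognormally around the subject
mean (15% scatter) with `sigma = 0.2 mu`; JND observers are Weber-like
(location 4% of the standard, spread 1.5%); raters are linear with additive
Gaussian noise truncated at 0 (a lognormal option exists; no particular
noise model is implied by the rating procedure itself) and a perception
floor at 0.8 `mu`. Percepts are filled ellipses on the template drifting
10 mm/week proximally with 2 mm repetition jitter and −5%/week area change;
descriptor mixtures make subject 3 naturalistic-dominant and the others
paresthetic/mixed-dominant. Trial counts per staircase are not externally
constrained; staircases simply run to their fifth reversal. All randomness
derives from one study seed with fixed per-electrode offsets, so identical
(config, seed) pairs are byte-identical on disk.

What the generator does *not* emulate: neural recruitment or electric
fields, referred residual-limb co-sensations (only labelled extra masks
could represent them), session-to-session criterion drift in ratings,
non-stationary observers, or hand-drawn mask irregularity (ellipses only).
Passing tests therefore validate the analysis arithmetic and its
statistical calibration, not robustness to the messiness of real drawings
or real observers.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen to
exercise each estimator's asymptotics without waste: 500 staircases for
convergence, 100 seeds × (6 levels × 60 trials) for recovery, 200 × 250
for pTLR calibration, 2000 simulations for ANOVA type-I error, n = 200
series for AR(1) recovery. The full default-size pipeline runs in well
under a minute on one core.

## Known limitations

- The percept-drawing stage models drift with a constant per-electrode
  velocity; real series show the largest shift in week 1.
- The dermatome matrix treats the electrode-to-level assignment as given
  metadata; no imaging arithmetic beyond the affine/scale helpers is done.
- `itch` is counted non-paresthetic by default (a switch moves it): the
  classification vocabulary places it with the tingle descriptors but the
  classification rule does not list it, and the rule wins here.
- AR(1) results on very short weekly series (n = 4) are reported but weakly
  identified; the recovery guarantees are stated at n = 200.
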