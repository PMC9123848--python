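# Methods

## Problem setting

`rnsfc` implements a resting-state connectomics pipeline for predicting
clinical response to responsive neurostimulation (RNS) in focal epilepsy
from pre-implant parcel-level brain signals (as obtained from
source-reconstructed MEG). The pipeline has five stages: band-specific
imaginary-coherence estimation between regions of interest (ROIs),
reduction to a coarse module-level connectome, z-normalization against a
healthy-control reference, multiscale feature summarization, and outcome
modeling (classification of responders vs non-responders and rank
correlation with percent seizure-frequency reduction). Because no real
recordings ship with the package, a synthetic cohort generator with
planted, calibrated couplings provides ground truth for validation.

## Connectivity estimator

For two signals the coherency is the cross-spectral density normalized by
the geometric mean of the auto-spectra, `C(f) = Sxy / sqrt(Sxx Syy)`. The
band imaginary coherence is the mean of `|Im C(f)|` over the frequency
bins inside the band. Any purely instantaneous (zero-lag) linear mixing
of sources yields a real coherency, so this statistic is insensitive to
volume conduction / field spread — the reason it is preferred for
source-space electrophysiology.

Choices that the statistic's definition leaves open:

* **Spectra.** Welch estimates with 1 s Hann windows at 50% overlap,
  mean-detrended per segment, computed on the concatenated 90 s resting
  segment treated as continuous. One-second windows give 1 Hz resolution,
  enough to resolve the 1 Hz lower delta edge. A per-epoch mode
  (estimate per 15 s epoch, then average) is available
  (`PipelineConfig.per_epoch`); concatenation seams are not tapered.
* **Band summary.** `abs_per_bin` (default): average of `|Im C|` per bin.
  The signed alternative `abs_of_mean` (`|mean Im C|`) is a config
  switch. The per-bin absolute value matches nonnegative connectivity
  maps; the sign of the lag is not interpreted.
* **Band edges are closed intervals**, so a bin at a shared edge (e.g.
  4 Hz) contributes to both adjacent bands.
* **Filtering.** Where explicit band-limited time series are needed, a
  zero-phase (forward–backward) Butterworth of order 4 per pass is used;
  zero-phase filtering is essential because phase distortion would
  corrupt the imaginary part of the coherency.

The all-pairs estimator is a windowed-FFT cross-spectral matrix
(`einsum` over segments) that follows exactly the same segmentation and
windowing conventions as the pairwise Welch path; the two are asserted
equal to 1e-10, and both are checked against a brute-force per-window DFT
oracle in the tests.

Epoch handling: recordings are parsed into consecutive non-overlapping
15 s epochs (trailing remainder discarded), each flagged clean or
contaminated; the first six clean epochs are concatenated to the 90 s
analysis segment. Fewer than six clean epochs is an error stating the
shortfall.

## Connectome features

The ROI-level matrix (218 ROIs by default) is reduced to module level
(44 modules) by block averaging; the diagonal holds the mean over
unordered within-module ROI pairs (singleton modules have no such pair —
their diagonal is dropped from the connection vector with a warning).
With M modules the connection vector has length M(M+1)/2 (990 for
M = 44), ordered by (i, j), i ≤ j, ascending module id.

The control reference stores, per band and connection, the sample mean
and SD (n−1 denominator, chosen for the small cohorts involved) across
control subjects; a zero SD anywhere is a degenerate-reference error.
Subjects are z-scored connection-wise against it. Summary features:

* **global** — mean and sample SD over all connections;
* **hemispheric** — mean z over connections with *both* endpoints in a
  lead-bearing hemisphere, averaged over hemispheres when leads are
  bilateral ("within" is read as both-endpoint; an `any_endpoint` switch
  is provided);
* **lobar** — mean z within each lead-bearing lobe, where a lobe region
  is hemisphere-specific (left frontal, not frontal-anywhere), averaged
  over regions.

Within-module diagonal entries count toward all three scales, as they are
part of the 990 connections.

## Outcome modeling

Percent reduction is `100 (baseline − current) / baseline` with `current`
the arithmetic mean of the two follow-up samplings; responders are
defined by reduction ≥ 50% (boundary inclusive). Classifiers are
unpenalized maximum-likelihood logistic regressions (binomial GLM — the
same model family as R's `glm`), over feature sets of 1, 2 or 4 of
{alpha mean, beta mean, alpha SD, beta SD}. Perfect separation is flagged
with a warning, and the saturated fitted probabilities are still
returned.

The primary AUC is computed from in-sample fitted scores via the
trapezoidal rule over the full threshold sweep (equal to the Mann–Whitney
pair statistic with ties counted ½; asserted against an exhaustive
pair-counting oracle). Confidence intervals are percentile bootstrap
(2.5/97.5) over 1000 subject-level resamples, unstratified, with
single-class replicates redrawn (≤100 retries). Leave-one-out
cross-validation fits n models on n−1 subjects; a training fold that
degenerates to a single class is scored by the training prevalence and
flagged. The operating threshold maximizes the geometric mean of
sensitivity and specificity over midpoints of adjacent distinct LOOCV
scores plus the two trivial classifications, ties broken toward higher
specificity; predictions use `score ≥ threshold`. Undefined confusion
ratios (zero denominators) are NaN with a warning. Reported percentages
are rounded to one decimal at the reporting layer only.

Group comparison fits, per band, a linear mixed-effects model on the
per-lobar-region mean z (one observation per subject × region, 8 regions
under the default parcellation) with group as fixed effect and a
per-subject random intercept; the group Wald p-value is reported with
LS-means and 95% limits. A random slope by region is a config switch. A
singular fit falls back (flagged) to a Welch t-test on subject-level
means. P-values are adjusted across the five bands with
Benjamini–Hochberg (5% FDR family = the bands within one spatial scale).
Dose–response uses the Spearman rank correlation (average ranks on ties,
t-approximation p; exact permutation p available for n ≤ 10).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not MEG biophysics (no sensor space, forward model, head geometry or
epileptiform transients):

* **Background**: independent 1/f-shaped Gaussian noise per ROI (white
  noise shaped in the frequency domain, flat below 1 Hz), matching the
  gross spectral shape of resting MEG, plus a zero-lag common "leakage"
  source (amplitude 0.4) shared by all ROIs — the volume-conduction
  confound the estimator is supposed to ignore.
* **Coupling**: a coupled module pair shares a band-limited Gaussian
  source mixed equally into all member ROIs of both modules, the second
  module delayed by a quarter cycle of the band's center frequency
  (maximizing `|Im C|`, which keeps the strength calibration
  well-conditioned). Member ROIs additionally receive the source with a
  small per-ROI conduction delay (5% of the quarter-cycle per member
  index). This delay matters: a strictly zero-lag within-module source
  *suppresses* the `|Im C|` estimation floor, which would make
  within-module z-scores move opposite to the planted coupling; the small
  delay removes that estimator artifact and makes within-module
  connectivity grow with coupling strength, as observed in epileptogenic
  tissue.
* **Calibration**: the mixing amplitude for a target imaginary coherence
  is solved numerically against the analytic coherency of the
  lagged-common-source model *as seen by the default Welch estimator* —
  the true source/background spectra are convolved with the Hann window's
  power kernel and evaluated on the discrete analysis bins. Without the
  kernel the band-edge smearing biases delivered strengths low by ~0.05.
  Modules participating in two couplings of one band carry extra unshared
  source power; a fixed-point refinement feeds that power back into each
  pair's calibration. Solutions are cached.
* **Topology**: default coupled pairs are within-hemisphere chains
  (m0,m1), (m1,m2), …, so most of the network is informative — matching
  the globally elevated/reduced connectivity phenotype of the clinical
  cohorts. Planted single-pair strengths are recovered to ±0.1 at 120 s
  in the tests; chain pairs land within ~±0.05 of target.
* **Cohort structure** (defaults = the emulated study conditions):
  15 controls, 22 responders, 9 non-responders; 200 Hz sampling, 120 s
  recordings (≥ 6 clean 15 s epochs survive flagging at clean-epoch
  probability 0.9); baseline coupling strength 0.30 in alpha and beta;
  responders +0.15 alpha; non-responders −0.15 alpha and −0.15 beta
  (beta's magnitude mirrors its near-parity with alpha in the clinical
  effect sizes); between-subject strength SD 0.10, which places the
  single-feature classification regime near the clinically observed one.
* **Outcomes**: percent reduction is an affine function of the subject's
  planted alpha strength (slope 150 per unit strength, centered so
  baseline coupling maps to 50%), clipped to [−100, 100], plus Gaussian
  noise (default SD 10 percentage points, under which labels almost
  always match the designed groups). Responder labels are then assigned
  by the ≥50% rule, so with large outcome noise designed responders can
  be labeled non-responders — deliberately, since the label is the noisy
  clinical endpoint. `calibrate_outcome_noise` solves (at plan level, by
  bisection with common random numbers) for the noise SD under which the
  planted alpha→reduction Spearman rho averages a requested value; the
  dose–response validation uses the SD giving rho ≈ 0.45.
  Baseline seizure frequencies are log-normal (median 3.5/week); the two
  follow-up samplings are symmetric around the implied current frequency
  so their mean reproduces the drawn reduction exactly.
* **Determinism**: all randomness flows from one root seed through named
  substreams (strengths / outcomes / metadata / per-subject simulation),
  so identical seeds give bit-identical cohorts and each subject can be
  re-simulated in isolation.

What passing tests on this generator do **not** show about real data:
the generator's group differences are homogeneous across the planted
network, its noise is Gaussian and stationary, leads are assigned at
random rather than at the seizure-onset zone, and label noise is
independent of connectivity given the alpha strength. Effect sizes on
real cohorts can differ substantially.

## Validation problem sizes

The Monte-Carlo validations run on a scaled-down parcellation (32 ROIs /
16 modules) with the full cohort structure (22/9/15), durations and
shifts — the global-feature signal-to-noise ratio is nearly
scale-invariant (coupled fraction × per-connection z-shift vs the
√connections noise floor), so the small parcellation probes the same
regime at a fraction of the cost. Type-I calibration of the
mixed-effects comparison uses 200 null simulations at the study's 22/9
subject split across 8 lobar regions (rejection rate asserted within
[0.02, 0.10] at α = 0.05). The full 218/44 parcellation is exercised
end-to-end by `scripts/acceptance.py` and in the connection-count tests.

## Numerical notes and limitations

* Estimated ImCoh of truly uncoupled pairs has a positive bias
  (~`1/sqrt(2 n_segments)`, the |Im| rectification floor); the control
  z-normalization removes it, which is one reason the pipeline normalizes
  at all.
* The percentile bootstrap interval is not guaranteed to contain the
  point estimate and no BCa correction is applied.
* Mixed-model p-values are Wald; with 31 subjects they are mildly
  anticonservative, which the calibration test bounds.
* The LOOCV of an unpenalized 4-feature logistic at n = 31 overfits:
  its held-out AUC is typically at or below the single-feature LOOCV AUC
  even when the in-sample (primary) AUC ordering favors the richer
  model. The package reports both.
* `max_strength` gives the estimator-visible ceiling of plantable
  coherence per band (≈0.97 at the quarter-cycle lag); targets above
  ~0.98 of it are rejected as infeasible.
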