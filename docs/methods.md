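# Methods

This note documents the models, parameter choices and numerical
conventions behind `neuroinertia`, and what the synthetic cohorts do and do
not establish about real recordings.

## The latent state model

Anesthetic state is modelled as overdamped Langevin dynamics in a
double-well potential

    V(x) = (a/4) x^4 - (b/2) x^2 + c x,

integrated by Euler–Maruyama, `x <- x - V'(x) dt + sqrt(2 D dt) N(0,1)`,
with `x < 0` awake and `x > 0` anesthetized (exact zeros keep the previous
state).  Defaults `a = b = 1` give well minima at ±1 and a barrier
`ΔV = b²/(4a) = 0.25`.  The tilt is linear in concentration,
`c(t) = -k (conc(t) - c_ref)` with `c_ref = 0.6%`, so the final 0.6% step of
both exposure arms is the symmetric condition and higher concentrations
deepen the anesthetized well.  The integration step is `dt = 10 ms`
(stability is checked against `dt · max|V''|`; behavioural dwell times are
minutes, four orders above `dt`), and the binary state series is
sample-and-held onto the 250 Hz signal clock.

In the small-noise limit the escape rate over the barrier is the Kramers
closed form `r = sqrt(V''(min)·|V''(0)|)/(2π) · exp(-ΔV/D)`; the simulator
is validated against it by repeated first-passage simulation (agreement
within a factor of 1.5; in practice within a few percent at `D = 0.05`).

### Two timescales: switching vs. memory

A *symmetric* double well has a single timescale: the memory of the initial
condition decays at exactly the barrier-hopping rate (`τ = 1/(2r)`).  If the
40-minute inertia relaxation were implemented purely through the barrier,
dwell times would also be ~40 min, and every 20-minute training or test
window of a single recording would be one frozen Bernoulli draw of the
state — per-individual occupancies would randomly invert between arms, and
no classifier protocol could see the (real, but only in expectation)
hysteresis.  Steady-state EEG in this preparation is conspicuously dynamic,
with discrete spectral fluctuations on the scale of minutes, so the
generator separates the two timescales:

* **Switching**: `D = 0.0676` by default, giving ~3-minute dwell times at
  the symmetric step — windows sample the state distribution densely.
* **Memory**: the tilt follows an *adapted* concentration — a first-order
  lag of the delivered concentration with time constant
  `relaxation_target` (default 40 min), solved exactly per constant
  segment.  At the final 0.6% step the adapted drive still remembers the
  1.2% step (emergence) or the oxygen baseline (induction), and the
  residual tilt decays exponentially with the chosen relaxation time.

With tilt gain `k = 0.45`, the anesthetized-state occupancy gap between
arms is ≈ 0.6 during test minutes 30–50 and ≈ 0 by minutes 110–130, which
yields classifier accuracies in the 0.7–0.9 range early and chance late —
the collapsing-inertia condition.  `simulate_two_well` without an
adaptation constant remains the textbook instantaneous-tilt model (and is
what the Kramers and symmetric-occupancy validations exercise);
`noise_for_relaxation` inverts the Kramers formula for users who want the
single-timescale variant.  Arm-exchangeable null cohorts set `k = 0` and
randomize the initial well; for "zero-memory" null calibrations the noise
is raised (`D = 0.15–0.2`, dwell well under a minute) so that chance
occupancy structure in finite recordings averages out.

Interindividual variability: ±20% uniform jitter on `D`, and log-normal
(σ = 0.2) per-band gains on the spectral templates, independently per
channel.

## Signal synthesis

**EEG.**  Each 4-s block of each channel is colored noise built in the
frequency domain: random phases with amplitude ∝ sqrt(power), where the
block's power template is the geometric blend of the awake and anesthetized
templates at the block's latent-state fraction.  Blocks overlap by 0.256 s
with power-complementary (sin/cos) raised-cosine cross-fades, so state
bouts shorter than a block are blended, never dropped.  The awake template
is a 1/f background with a theta (7.5 Hz) peak and elevated 30–80 Hz power;
the anesthetized template boosts 0.5–4 Hz delta and attenuates high
frequencies; both are scaled to ~60–75 µV RMS.  On top, every block carries
a smooth spectral modulation shared across channels: 8 log-spaced Gaussian
bumps in log-frequency with i.i.d. N(0, σ²) amplitudes, σ = 2 dB.  This σ
is the generator's explained-variance calibration: it balances low-rank
structured variance against multitaper estimator noise so that the first
50 PCs of a default individual's feature matrix capture 70–78% of the
variance (measured ≈ 75%).

**EMG.**  White baseline noise (3 µV RMS) plus Poisson movement bursts
(2/min, only while awake, exponential durations of mean 2 s clipped to
0.5–8 s, 8× baseline RMS with 0.1-s ramps).  The log of the 1-s RMS series
of a mixed recording is therefore bimodal with tight modes.

**Artifacts.**  Optional Poisson transients (damped 8 Hz bursts, default
peak 1500 µV) added to random EEG channels, with ground-truth times kept
for round-trip testing of the artifact detector.

**Channels.**  Besides M2 and V1 the generator adds two "context" EEG
channels by default.  They exist because mean re-referencing across *only*
two channels would leave two equal-and-opposite copies of one difference
signal; the montage this emulates retained ~25 leads, so a four-channel
reference keeps M2 and V1 distinct while still removing common mode.
Analysis uses M2 and V1 only.

**Spans.**  By default recordings are synthesized only where the analysis
reads them: the oxygen baseline, the 10–30 min training window of every
0.6% step, and test minutes 30–130 of the final step (~320 of 630 paired
minutes per individual).  The latent trajectory is always integrated over
the full exposure, so state memory crosses span gaps intact.  Pass
`spans="full"` for complete recordings.

## Preprocessing conventions

* Decimation 1 kHz → 250 Hz: zero-phase 8th-order Butterworth at 0.8× the
  new Nyquist, then subsampling.  (A maximally flat design is used so a
  constant passes exactly; an equiripple anti-aliasing filter would ring
  the passband by its ripple.)
* EEG band-pass 1–120 Hz: 6th-order Butterworth applied
  forward-and-backward (`sosfiltfilt`), giving zero phase lag by
  construction.
* Channel exclusion: impedance strictly greater than 30 kΩ, or a manual
  flag; exactly 30 kΩ is kept.  Losing M2 or V1 aborts the analysis.
* Artifact rule: per channel, a single σ over the whole recording computed
  after dropping samples beyond ±700 µV and samples inside high-EMG
  seconds; any 4-s window containing a sample strictly beyond 6σ or
  ±700 µV is masked.  "Period" means the 4-s spectral window, because the
  window grid is the mask's only consumer.  A window masked on either
  analysis channel is dropped for both.
* Mean re-referencing subtracts the across-retained-channel mean per
  sample; channel-periods flagged as artifactual are excluded from the
  reference (the reference falls back to all channels where nothing is
  valid).

## EMG tone threshold

The 15 Hz 6th-order zero-phase high-passed EMG is reduced to non-overlapping
1-s RMS values.  The empirical CDF of the *centered* natural-log RMS is
kernel-smoothed (Gaussian kernel, Silverman bandwidth with the IQR guard,
512-point grid); its slope is the KDE.  Scanning upward from the
distribution's main mode, the threshold is the first grid point where the
slope drops below 1; seconds with log RMS strictly above it are "high
tone".  Centering (a shift in log space) makes the rule invariant to
rescaling the raw signal by any positive constant.  The spread is *not*
normalized to unit variance: 1-s RMS estimates cluster so tightly in log
units (relative SD of a few percent) that the quiet-mode density is well
above 1, which is what makes "slope drops below 1" a meaningful landmark —
z-scoring would cap the density of any unimodal sample near 0.4 and turn
the rule degenerate.  Degenerate inputs (constant RMS, or densities that
never reach 1) produce an all-false mask with a warning.

## Spectral features

Power is estimated per non-overlapping 4-s window with Thomson multitapers:
time–bandwidth NW = 2 (half-bandwidth 0.5 Hz) and 3 tapers, evaluated at
0.25 Hz resolution and subsampled to the fixed 241-bin grid, 0–120 Hz at
0.5 Hz — the unique grid consistent with 241 estimates per channel and a
Bonferroni level of `1 − 0.05/241 = 99.979%` for per-frequency CIs of mean
spectra.  Features are `10·log10(power)` deviations from the mean log
spectrum over the union of the three sources (induction recording,
emergence arm, induction arm of the emergence recording), M2 then V1,
482 dims.  dB differencing reflects the multiplicative nature of EEG
spectral contrasts.  PCA keeps 50 components (sign convention:
largest-magnitude loading positive; effective-rank truncation with a
warning), and held-out windows are projected with the training centering.

## Classifiers and statistics

Training sets: 260 windows per class, sampled without replacement from
minutes 10–30 of the relevant 0.6% steps; the induction class takes
130 + 130 from its two sources, so recording-day idiosyncrasies cannot
masquerade as path dependence.  Ensembles of 250 classifiers differ by
independent resampling of the training set (member i uses seed
`base_seed + i`); null ensembles additionally shuffle each member's labels.
LDA is classical Fisher/Gaussian LDA with Ledoit-Wolf shrinkage of the
pooled covariance; SVM defaults to an RBF kernel with
`gamma = 1/(50 · Var)` and `C = 1`.  Population-level (leave-one-out)
training draws 260 windows per class from each of the other individuals
(1300 per class for a six-mouse cohort) in a shared feature space.

Balanced accuracy `½(I_C/I_T + E_C/E_T)` is computed from pooled window
counts per classifier per period — one summary per classifier, not an
average of sub-period accuracies.  Inference: Kruskal–Wallis for real vs
null (inertia call = higher real median and p < 0.05, two-sided, α = 0.05
throughout); Friedman (tie-corrected, implemented directly so the
two-treatment LDA-vs-SVM case is admissible) for method comparison;
Wilcoxon matched-pairs over pooled classifiers plus a two-way ANOVA
(period × individual) with Šídák-corrected per-individual contrasts for
the early (minutes 30–50) vs late (110–130) collapse test.  All-tied pairs
take the documented p = 1 branch.  Bootstrap CIs of medians use 10,000
percentile resamples.

## Problem sizes and determinism

Headline runs use the study-scale sizes: 250 classifiers per ensemble,
six-individual cohorts, 10,000-resample bootstraps.  Property simulations
use deliberately smaller configurations (e.g. 100 replicates of a complete
but miniaturized pipeline with a shortened test period and 25-member
ensembles for the null-cohort type-I check; 5 replicates for the
static-inertia specificity check), chosen to keep the suite fast while
leaving the tested mechanism intact.  Every stochastic stage draws its
seed deterministically from the run seed via `SeedSequence`, so identical
configurations give bit-identical cohorts, ensembles and reports.

## Limitations

* The synthetic EEG is stationary colored noise per state with smooth
  multiplicative modulation: no burst suppression, no more than two latent
  states, no cross-channel coherence structure, no line noise.  Passing
  tests show the *pipeline* behaves correctly on data whose ground truth is
  known, not that real recordings satisfy the two-well model.
* Concentration steps act instantaneously on the drive apart from the
  modelled slow adaptation; there is no pharmacokinetic compartment model
  (gas-phase equilibration in this preparation is ≤ 12 min, inside the
  30-min analysis guard).
* Treating ensemble members as independent samples (the Kruskal–Wallis and
  Wilcoxon units) is anticonservative, since members share training pools
  and test sets.  With the large real-vs-null effects this procedure
  targets, the miscalibration is immaterial, and the type-I property is
  verified on zero-memory cohorts; but marginal inertia calls near the
  significance boundary should not be over-read.
* The manual channel-inspection step of real workflows is replaced by a
  config-listed exclusion flag; EMG lead choice is fixed to the single
  synthesized lead.
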