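# Methods

This note records the statistical models desyncflow implements, the
assumptions behind them, the defaults of the synthetic study generator, and
the numerical and design choices that were genuinely open.

## Study design being modelled

A forced-desynchrony protocol schedules sleep onto a 28-h day so that after
a few cycles sleep occurs 12 h out of phase with the central circadian
clock. Each participant contributes two sampling windows: *in-phase*
(sleep aligned with the melatonin rhythm) and *out-of-phase* (sleep 12 h
against it). Per window the design assumes 7 blood draws at 4-h spacing for
transcriptomics — the 7th draw falls at the same clock time as the 1st,
24 h later, and is treated as a distinct observation with independent
measurement error — and 2-hourly plasma samples over 24 h for hormones.

## Cosinor model

Hormone series are fitted with `X(t) = a + c·sin(ωt + b)`, `ω = 2π/24`,
by OLS on the linearised regressors `[1, cos ωt, sin ωt]`; the coefficients
map back through `c = √(β_cos² + β_sin²)`, `b = atan2(β_cos, β_sin)`. The
period is fixed at exactly 24 h. This is a deliberate simplification: under
forced desynchrony the melatonin rhythm free-runs near 24.2 h, but a
single-window fit over one cycle absorbs that discrepancy into the phase
estimate, and fixing the period keeps the model linear and the two
conditions directly comparable.

Rhythm presence is the joint F-test of the two trigonometric terms.
Standard errors for amplitude and peak time come from the delta method on
(β_cos, β_sin); they are reported per fit but the between-condition
comparison uses the paired t-test on per-participant differences, with peak
differences wrapped to (−12, 12] h *before* the test. The wrapping
convention matters only for shifts approaching ±12 h, where the unwrapped
difference is ambiguous; it is fixed, tested, and configurable in
`wrap_hours`. Fits require ≥ 4 points spanning ≥ 8 h (3 coefficients plus
at least one residual degree of freedom, and a non-degenerate design). A
fitted amplitude below 1e-9 leaves the peak time undefined; such pairs are
excluded from the peak-time test and counted.

## Phase alignment and the disruption screen

Sampling times are re-expressed relative to each participant's fitted
in-phase cortisol peak: `aligned = (clock − peak) mod 24`. The in-phase
peak is used for both conditions because the cortisol rhythm is, by design
and by observation, essentially unchanged under misalignment; a
per-condition alignment would leak condition differences into the design.
Pooled aligned times are discretised into 8 equal-frequency bins
(rank-based, occupancy differs by at most one; equal-width binning is
available as an option). Equal-frequency was chosen because it guarantees a
balanced categorical factor regardless of the cortisol-peak distribution.

Each probe is then modelled as

    y ~ condition + time_bin + condition:time_bin + (1 | participant)

with Gaussian errors. The main effect of condition (1 df) and the
condition × bin interaction (7 df) are tested by likelihood-ratio tests of
nested maximum-likelihood fits against a χ² reference. The random
intercept is fitted by profiling: for a fixed variance ratio
λ = σ_u²/σ_e² the marginal covariance is block-diagonal with a rank-one
update per participant, so GLS estimates, the profiled σ_e², and the
log-likelihood are closed-form given per-group column sums; λ is then
optimised on log scale over a bounded interval, with the boundary λ = 0
(no participant variance) checked explicitly. This makes the per-probe fit
a few milliseconds, numerically exact at the boundary (all-null probes
reduce smoothly to OLS rather than failing on a singular random-effects
covariance), and reproducible. The statsmodels `MixedLM` ML fit is used in
the test suite as an independent cross-check of the likelihood (agreement
to ~1e-6 on well-conditioned data).

LRT p-values are χ²-asymptotic; with 19 participants and ~266 observations
the interaction test is measurably but mildly liberal (empirical type-I
error ≈ 0.06–0.07 at nominal 0.05 in the null calibration the acceptance
script runs). Benjamini–Hochberg correction is applied across probes
separately within the main-effect family and within the interaction
family; *affected* means either adjusted p < 0.05. Missing cells are
dropped pairwise per probe (the n used is recorded); probes missing > 20%
of observations are excluded with a warning. No rhythmicity test is ever
applied: the screen asks whether level or shape changed, not whether
profiles are sinusoidal.

## Enrichment

Gene-level by default: a gene counts as affected if any of its probes is
affected, because target lists are gene-level and collapsing avoids
counting a gene twice. The test is the upper-tail hypergeometric
probability including the observed count, with the platform's gene universe
as background; target sets must be platform-restricted first (enforced).
Probe-level counting is exposed for parity with probe-indexed binding-site
annotations. No cross-set multiple-testing correction is applied by default
(few sets are tested); a BH option exists.

## Temporal coherence

Mean profiles average expression across participants per time point
(missing dropped per point). Pearson correlation with the regulator uses
all 7 points; the circular cross-correlation uses points 1–6 only, because
point 7 duplicates point 1's clock position and cannot participate in
cyclic shifting. Both 6-vectors are z-scored (sample SD, n−1) and
correlated under all 6 cyclic shifts; the lag is `4·s*` hours wrapped to
(−12, 12], where `s*` maximises the correlation. Sign convention: positive
lag means the probe peaks later than the regulator. Ties across shifts
(possible with 6 points, e.g. period-3 patterns) are broken toward the
smallest |lag|, then toward the negative lag; both the orientation and the
tie-break are regression-tested. Lag distributions are summarised by the
circular mean and resultant length R ∈ [0, 1] (1 = all probes share a
lag), grouped by affected status.

## Synthetic study generator

The generator is first-class, tested code: it provides the ground truth
every downstream recovery test measures against.

Hormones: per participant, mesor/amplitude/peak are drawn around population
means; the out-of-phase parameters add a (mean, SD) condition effect.
Defaults encode a 19-participant cohort with melatonin amplitude
33.9 pg/ml, peak 3.47 h and a +0.92 h out-of-phase peak delay, and cortisol
amplitude 195.9 nmol/L, peak 11.04 h with no condition effect (the rhythm
persists). Between-participant SDs are back-computed from cohort standard
errors (SE·√19 ≈ 13 pg/ml and 1.35 h for melatonin); the paired-difference
SD of 1.0 h reproduces a cohort-level paired-t p of order 1e-3 for the
melatonin shift. Residual SDs (5 pg/ml, 30 nmol/L) are set at roughly 15%
of amplitude, typical of duplicate immunoassay series. Amplitudes are
truncated at zero.

Transcripts: `X = μ_g + u_i + A_gk·sin(ω t + φ_gk) + Δ_gk + ε` with five
classes — circadian-locked (identical both conditions), sleep–wake driven
(phase shifted 12 h out-of-phase), amplitude-disrupted (A × 0.25
out-of-phase), mean-shifted (+0.5 log2 out-of-phase), flat — plus one
SP1-like regulator peaking at 12 h whose amplitude is multiplied by 0.25
out-of-phase. Defaults: amplitude 0.5 log2 units, residual SD 0.25 (signal
to noise 2), participant-intercept SD 0.5, 200 probes (40/30/30/20/79 + the
regulator). Half of the changed-class probes are generated as lagged copies
of the regulator's sinusoid, lags on the 4-h grid and recorded in the
ground truth; target-set membership is drawn at P = 0.6 for changed classes
and P = 0.1 otherwise. Out-of-phase samples are taken at the same clock
times as in-phase samples — the misalignment lives in the transcript model,
matching the aligned-time analysis frame. All noise is Gaussian on the log2
scale; one probe per gene by default, with a multi-probe mode that
duplicates each gene's signal with independent noise.

What the generator does *not* emulate: raw microarray intensities and
normalisation, dye/batch effects, heavy-tailed noise, blood cell-type
composition and its own diurnal rhythm, and the ~24.2 h free-running
melatonin period. Tests passing on this generator therefore demonstrate
correctness of the estimators and the pipeline's logic under the stated
sampling design — not robustness to array artefacts or compositional
confounding in real blood transcriptomes.

## Problem sizes used in the automated checks

The test suite and acceptance script size their simulations for a desk-scale
run: 1000 replicate cohorts for shift recovery, 2000 probes for null
calibration of the screen, 150 amplitude-disrupted probes for power,
exhaustive hypergeometric enumeration to N = 25, 500 draws for lag
recovery, and full duplicate pipeline runs for determinism. Each block
completes in seconds to tens of seconds.

## Known limitations

* The cohort mean of wrapped peak-time differences is slightly attenuated
  toward zero when some participants are nearly arrhythmic: a fitted
  amplitude near the noise floor makes the peak estimate, and hence the
  wrapped difference, close to uniform with mean 0. With the default
  melatonin parameters ~10% of simulated pairs fall in this regime and the
  expected recovered shift is ≈ 0.87 h for an implanted 0.92 h. Real
  studies screen participants for clear melatonin rhythms; an amplitude
  filter before the paired test would remove the attenuation and is left to
  the caller.
* The interaction LRT is mildly liberal at n = 19 participants (see above);
  a Kenward–Roger or Satterthwaite small-sample correction is not
  implemented.
* Circular lags are resolved only to the 4-h sampling grid; sub-grid lag
  estimation is out of scope.
* The screen assumes homoscedastic Gaussian errors per probe; no
  empirical-Bayes variance moderation across probes is applied.
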