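# Methods

`abrkit` implements two automated hearing-threshold detectors for averaged
auditory brainstem response (ABR) audiograms, a ground-truth-free statistic
for comparing threshold-finding methods, and a downstream mutant-vs-control
candidate-gene scan. This note describes the models, their assumptions, the
synthetic data the test suite runs on, and the numerical choices that were
genuinely open.

## Data model

An ABR measurement session yields, per mouse and stimulus (broadband click
or a 6/12/18/24/30 kHz tone pip), a stack of averaged evoked-response curves
at ascending sound pressure levels (SPL) on a 5 dB grid (click and
12–24 kHz: 0–85 dB; 6 and 30 kHz: 20–85 dB). Each curve has 1000 samples
spanning 10 ms. The hearing threshold of a mouse × stimulus is the lowest
recorded SPL with a detectable evoked response; the sentinel 999 means no
response at any tested level ("non-hearing"). Everything is carried in one
CSV dialect (`mouse_id, stimulus, sound_level, threshold, t0..t999`, plus
optional per-mouse metadata columns); a schema mapping accommodates foreign
header spellings, and grid checking is lenient by default (off-grid SPLs
warn rather than fail) because legacy recordings contain odd levels.
An empty threshold field means "unlabelled", which is distinct from 999
("assessed, no response"). Amplitudes are carried opaquely — no rescaling on
input or output. Mice lacking any of the six stimuli are dropped by
`filter_complete_mice` before analysis.

## Sound Level Regression (SLR)

SLR is self-supervised: the only regression target is the stimulus SPL,
which the recording itself provides, so no human labels enter the pipeline
(the API does not even accept them). The premise is informational: a
sub-threshold curve contains no information about the stimulus level, so SPL
can only be predicted from a curve recorded above the animal's threshold.

**Step A — sound-level estimation.** Each curve is mean-centred and mapped
to the squared magnitudes of its 50 lowest non-DC Fourier components.
(The count of retained components is configurable; DC is excluded because
mean-centring removes electrode-offset artefacts, and a flag restores it
for sensitivity analysis.) A random forest (100 trees, fixed seed,
unlimited depth — the regressor's hyperparameters are not critical and are
exposed in `SLRConfig`) regresses SPL on these features inside a five-fold
*grouped* cross-validation with mice as groups: a curve is always predicted
by a forest that never saw any curve of the same animal. Fold assignment is
canonical-sort → seeded shuffle → round-robin, so it is reproducible and
independent of input row order.

**Step B — breakpoint search.** Per mouse × stimulus, predicted SPL is
plotted against actual SPL. Below threshold the prediction fluctuates
around a constant; above it tracks the actual level. The model is

    f(x) = c                         for x ≤ b
    f(x) = c + Σ_{k=1..4} a_k (x−b)^k  for x > b,

continuous at the breakpoint b by construction. For each candidate b the
basis h_k(x) = max(x−b, 0)^k is standardized and an elastic net
(l1 ratios 0.5 and 0.99, regularisation strength chosen by internal 5-fold
CV) is fitted with an unpenalised intercept, which is the constant c. The
candidate grid is restricted to 5 dB steps between two bounds:

* *Lower bound*: predictions are mean-aggregated per actual level and
  fitted with a non-decreasing (isotonic) step function; the bound is one
  grid step below the first level whose fitted value exceeds the fitted
  minimum (tolerance 1e-9 — the "first increase" needs a tie tolerance and
  we fix it at numerical noise level), floored at the lowest measured level.
* *Upper bound*: the largest level L such that actual and predicted SPL,
  restricted to levels strictly above L, show a significantly positive
  Spearman rank correlation (one-sided), Bonferroni-corrected over the
  candidate levels actually tested (those with at least three distinct
  levels above them). If no candidate is significant the animal is called
  non-hearing. Rank correlation is used because the forest's response is
  monotone but not linear. For at most eight pairs without ties the exact
  permutation distribution of the rank correlation replaces the
  t-approximation: the approximation assigns p ≈ 0 to a perfect ordering of
  three points, whose true null probability is 1/6, which would make the
  smallest candidates fire spuriously on pure noise.

The CV-error-minimising candidate wins (ties go to the larger breakpoint),
then b ± 0.5 dB are refitted and whichever of the three has the least CV
error is adopted. The threshold is *not* the breakpoint: a quartic can
leave the constant arbitrarily slowly, so the threshold is the first point
(scanned at 0.1 dB resolution) where the polynomial part exceeds the
constant by more than 4 dB, snapped *up* to the recording grid — a
deviation point of 44.0 dB reports 45 dB, because the threshold is by
definition the lowest *recorded* level with stimulus-induced activity. If
the 4 dB deviation never occurs within the measured range, the result is
999. Monotonicity of the polynomial part is not enforced; the first
crossing of the 4 dB line is well defined regardless.

The upper-bound rule admits a second reading (take the largest level whose
corrected p-value *exceeds* the significance level); `SLRConfig.
upper_bound_rule = "nonsignificant"` selects it, the default is the
significant-correlation reading, which matches the bound's purpose of
narrowing the search space from above.

## Two-stage neural network (NN)

The supervised path mimics the human reading process. **Model I** scores a
single 1000-sample curve (per-curve standardized — inputs of very different
amplitude otherwise destabilise training) for response presence. Its labels
derive from the manual threshold: curves at or above threshold are
"response", below are "no response", and a 999 threshold labels the whole
stack "no response". Measurements whose label was re-validated with an
"agree" verdict get weight 2.0 (a deliberate default; the requirement is
only "higher"), realised by row replication because the MLP trainer has no
per-sample weights. **Model II** is a per-stimulus classifier from the
stack of Model I scores, placed on the full 0–85 dB grid (18 slots;
unmeasured slots carry fill value −1 plus an explicit mask channel rather
than imputed scores), to a threshold class on the grid ∪ {999}. 999 is an
ordinary class; it never matches a numeric class at any accuracy tolerance.

Both models are small multilayer perceptrons (Model I: 32–16 hidden units,
Model II: 32) with all architecture hyperparameters in `NNConfig`, so a
published architecture can be dropped in. Training follows a grouped
five-fold cross-validation with mice as groups: mice split 4:1 into
training and test, training mice again 4:1 into training and validation.
Model I trains on the training mice only. Model II trains on *out-of-fold*
Model I scores — inner 3-way grouped split for the training mice, plus the
validation mice scored by the (for them out-of-sample) Model I — so that
its input distribution matches what it sees at test time; training it on
in-sample scores (configurable) would leak Model I's training fit. Each
mouse is predicted by the fold in which it is a test mouse; no curve of a
test mouse ever enters the training of the fold that scores it.

## Evaluation curves

To compare threshold-finding methods without trusting any labels, all
curves of one stimulus are sorted by the threshold-normalised level
l(i) = SPL(i)/threshold(i) and the temporal variance S²(n) of the
cumulative mean of the first n curves is tracked. Under a good assignment
the accumulating curves are genuinely sub-threshold (incoherent) for as
long as possible, so S²(n)/S²(N) stays near zero longer; the normalised
curve is plotted against n/N and its area is a relative quality score
(lower = better). The statistic is qualitative — no significance test
between curves is attempted. The cumulative mean is defined over exactly
the first n curves, so S²(1) is the single-curve statistic. Division
sentinels: threshold 999 gives l = SPL/999 (tiny — such curves sort first,
consistent with "no response anywhere"); threshold 0 sorts after all
finite keys, internally by SPL; remaining ties break on (SPL, mouse_id)
for determinism. Curves are evaluated per stimulus. The "always 50 dB"
constant assignment serves as a worst-reasonable-method control.

## Phenotyping scan

Accuracies against manual labels are reported at exact, ±5 dB and ±10 dB
match levels (the grid is 5 dB and human reading itself varies by about
that much). For each mutant line × stimulus, thresholds are compared
against controls (all controls, or same-measurement-date controls when
dates exist; without dates the same-day policy falls back with a warning)
using Cliff's delta d = P(m>c) − P(m<c) — computed by direct pair
enumeration up to 10⁶ pairs, rank-equivalently above — and a two-sided
Wilcoxon rank-sum p-value, tie-corrected, computed by exact enumeration of
group assignments for pooled samples of at most 12 and by the normal
approximation otherwise. The test's sidedness is a documented choice
(two-sided). 999 enters all rank statistics as the largest ordinal;
medians and percentiles use linear interpolation between order statistics,
and a group whose median lands on 999 reports non-hearing. Candidates must
pass p < 0.05 *and* |d| > 0.474 (strict, the conventional "large effect"
margin; 0.147 and 0.33 mark small and medium); the sign of d gives the
direction. No across-line multiplicity correction is applied in the scan
(an optional Benjamini–Hochberg step would be a caller-side addition);
the type-I behaviour of the uncorrected scan is itself verified on null
simulations.

## Synthetic data

The generator emulates exactly the statistical structure the methods
exploit, not cochlear biophysics. Per mouse × stimulus a true threshold θ
is drawn from a normal distribution around a stimulus-specific mean
(defaults trace a typical U-shaped hearing curve: click 30, 6 kHz 45,
12 kHz 25, 18 kHz 30, 24 kHz 40, 30 kHz 55 dB; SD 7.5 dB), rounded and
clipped to the recording grid, with a stimulus-specific non-hearing
probability (5% at 24 kHz, 10% at 30 kHz — high-frequency non-hearing is
common in real screens, elsewhere 0). Curves below θ are i.i.d. Gaussian
noise (SD 0.5 in arbitrary voltage units; optionally AR(1)-coloured —
real noise spectra are uncharacterised, so white is the default). Curves
at and above θ add a template of five alternating-sign Gaussian peaks
between 1 and 7 ms (a stylised waves I–V morphology) scaled by
0.2·(SPL − θ + 5) per dB — the +5 dB offset makes the threshold-level
curve itself carry signal, matching the labelling convention that the
threshold SPL counts as hearing — with peak latencies shrinking by
0.01 ms/dB above θ. Mutant lines can shift the per-stimulus threshold
mean; the manual label column equals θ, optionally displaced by one grid
step with a configurable probability to emulate reader variability
(default 0: clean labels; tests corrupt explicitly).

What passing tests on this generator do **not** show: robustness to real
electrode artefacts, drifting baselines, stimulus-specific waveform
morphology changes, or inconsistent human labelling styles across readers
— the properties the real-data studies address. They do show that each
algorithm recovers the structure it is designed to exploit, and that the
pipeline's statistics behave nominally under the null.

## Benchmark scenarios and problem sizes

Four frozen scenarios (constructors in `abrkit.simulate`) drive the tests
and `scripts/acceptance.py`:

* `high_snr_screen` — 100 mice (5 lines × 4 + 80 controls), click +
  18 kHz, noise SD 0.1 (waveform at θ+30 dB ≈ 70× noise floor). SLR
  recovers ≥ 90% of thresholds within ±5 dB here; the NN variant (click
  only, clean labels) reaches ≥ 90% within ±5 dB end-to-end and ≥ 95%
  per-curve Model I accuracy.
* `null_screen` — the same cohort with evoked amplitude 0: every curve is
  pure noise, the correct call is always 999; SLR must say so ≥ 95% of the
  time.
* `mutant_screen` — click-only screen of 16 lines × 8 mice vs 40 controls,
  6 lines carrying a +30 dB shift; generator → SLR → effect scan →
  candidate filter must recover ≥ 90% of shifted lines and flag ≤ 10% of
  null lines.
* `dominance_screen` — 40 mice per replicate with one +30 dB line and 10%
  non-hearing: a screening-like population with a wide threshold spread,
  which is the regime the evaluation-curve statistic is built for (in a
  homogeneous colony the SPL ordering nearly coincides with the
  ratio ordering and the comparison carries little information). Over 100
  replicates the truth assignment's curve area must be dominated by a
  ±5 dB-corrupted assignment (30% of mice) and by the constant-50 control
  in ≥ 95 each.

The type-I check runs 20 replicates of a 200-line × 6-stimulus null screen
(thresholds sampled directly — waveforms are irrelevant to the scan) and
expects 5% ± 2 percentage points of tests at p < 0.05.

These sizes are the package's benchmark definitions; they were chosen once
as the smallest cohorts at which the respective statistics have adequate
power, and the full suite runs in minutes on one CPU.

## Known limitations

* The MLP stand-ins for the two classifiers are deliberately small; real
  screens would tune architecture and training length per dataset.
* The SLR per-mouse fit sees at most 18 points; its CV error estimate is
  noisy, which the ±0.5 dB refinement partially absorbs.
* The exact rank-correlation null is only applied to tie-free samples of
  ≤ 8 points; larger perfect correlations still receive approximate
  p-values (their null mass is negligible).
* `same_day` control matching requires a measurement-date column; absent
  dates silently widen to all controls (with a warning).
* The generator's amplitude law is linear in dB; real growth functions
  saturate.
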