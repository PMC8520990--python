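# Methods

This package models and analyses a psychoacoustic estimate of cochlear gain
reduction: the elevation of a brief 4-kHz signal's detection threshold caused
by a preceding sound (a *precursor*) that activates the medial olivocochlear
reflex (MOCR), measured with forward masking and an adaptive 2-down/1-up
procedure.

## Listener model

**Input–output function.** The basilar-membrane response at the signal place
is a two-segment broken-stick curve: output = input + `G` below a breakpoint
`BP`, and output = `BP + G + c·(input − BP)` above it, with low-level gain
`G` (default range 35–50 dB across synthetic listeners), compression exponent
`0 < c ≤ 1` (default range 0.2–0.5) and `BP` in dB SPL (30–45). The
broken-stick form was chosen over smooth sigmoids because it makes the
gain-reduction shift identities exact and testable: reducing gain by
`ΔG` pivots the breakpoint to `BP + ΔG/(1−c)`, leaving the compressive
segment unchanged, so outputs below the original breakpoint drop by exactly
`ΔG` and high-level responses converge. The alternative — shifting the whole
curve down — was rejected because it would move high-level thresholds, which
is not what converging input–output schematics imply. For `c = 1` the pivot
is undefined and the curve simply loses `ΔG` of gain below `BP`.

**Place excitation.** A tone within one equivalent rectangular bandwidth
(ERB) of the signal frequency is *on-frequency* and passes through the I/O
function; the one-ERB rule generalises the two frequencies actually used
(4 kHz vs 2.4 kHz, nearly an octave apart). An off-frequency tone is
processed linearly at the signal place: place level = tone level − `A`, with
`A` a free per-listener attenuation (no filter model is assumed; `A` is
calibrated from matched-masker pairs). A broadband noise contributes the
level falling in one ERB at the signal place: spectrum level
`SL = overall − 10·log10(bandwidth)` and `dB/ERB = SL + 10·log10(ERB(F))`,
with `ERB(F) = 24.7(4.37F + 1)` Hz (456.46 Hz at 4 kHz). Tail contributions
of the noise outside the ERB are ignored, consistent with the rationale for
the dB/ERB conversion. All logs are base 10; all levels are dB SPL unless
labelled spectrum level or dB/ERB.

**Gain-reduction rule.** In mechanistic mode, elicited gain reduction is
`ΔG = clamp(s·(E − E0), 0, cap)`, where `E` is the precursor's place
excitation through the full-gain curve, `s` an elicitation slope
(0.7–0.9 per dB), `E0` an elicitation floor and `cap ≤ G` a ceiling
(default 30 dB, within the 25–40 dB range behavioural estimates span). The
chain rule then gives level slopes `s` for an off-frequency precursor
(linear path) and `s·c` for an on-frequency precursor above the breakpoint —
the asymmetry the mixed-model analysis quantifies. An empirical mode maps
precursor level directly through per-class linear coefficients. The observed
noise-precursor slope (0.41) being slightly steeper than the on-frequency
tone slope (0.29) is not forced: the mechanistic rule predicts equality, and
both parameterisations are supported.

## Detection stage

Detection follows the power spectrum model: the signal is detected when its
place output reaches a criterion signal-to-masker ratio `K` (default 0 dB,
configurable) above the intensity sum of the effective masker excitation and
an internal noise floor `N0`. `N0` is calibrated per listener so the model's
quiet threshold equals the listener's nominal quiet threshold
(`N0 = io(quiet) − K`). Two hypotheses are implemented for what a precursor
does:

* **gain reduction** — `ΔG` from the precursor is applied to the signal-place
  curve; an on-frequency masker rides the same reduced curve (hence little or
  no shift unless the signal approaches the noise floor), while an
  off-frequency masker is linear and keeps its effectiveness, producing a
  large shift;
* **additivity of masking** — the curve is static and the compressed
  intensities of masker and precursor add, predicting identical shifts for
  equally effective maskers of either frequency.

Thresholds are found by bisection on the strictly increasing I/O curve over
[−20, 120] dB SPL to 0.01 dB, saturating at the bounds if the criterion is
unreachable. Intensity-domain summation of compressed components was chosen
because the additivity account is defined by summation after compression;
no particular formula being mandated, the standard power sum is used.

The psychometric function for the 3-interval forced-choice task is a
Gaussian CDF with guessing rate 1/3 and spread σ (default 4 dB, a typical
forward-masking slope), anchored with a fixed offset `z0 = Φ⁻¹(0.5605)` so
that the probability correct at the model-true threshold is exactly 0.707 —
the point the 2-down/1-up rule tracks. The anchoring makes "true threshold"
and "70.7% point" synonymous, which the convergence analysis requires.

## Staircase simulation

Trial responses are Bernoulli draws from the psychometric function centred
on the model-true threshold plus a single per-run Gaussian offset
(SD `run_noise_sd`, 0.8–2 dB), which reproduces between-run SDs without
trial-level nonstationarity. Signal tracking: two consecutive correct
responses move the level down one step, any incorrect response moves it up;
masker tracking inverts the polarity so the track converges on the lowest
masker level at which the fixed signal is just detectable. Step size is
5 dB until the second reversal (fourth, in the fixed-reversal regime), then
2 dB. Stopping is either at exactly 50 trials (even mid-descent) with
threshold = mean of the final even number of 2-dB reversals, or at 12
reversals with threshold = mean of the final eight. Runs are excluded when
the reversal SD exceeds 5 dB strictly (the within-run reversal SD; the rule
could also be read as an across-run SD, which is not implemented) or fewer
than six reversals occurred. Starting level defaults to the true threshold
+10 dB; level bounds are [−20, 120] dB SPL.

`staircase_asymptote` is an independent oracle: the 2-down/1-up rule on a
fixed 2-dB grid is a Markov chain over (level, consecutive-correct) states;
its stationary mean is computed by eigen-decomposition and compared with the
simulator's mean estimate (agreement within 0.5 dB over ≥200 runs, checked
for several psychometric spreads).

## Estimation pipeline

Gain reduction is estimated as threshold-with-precursor minus quiet
threshold (masker absent), unclamped; points are floor-filtered at
strictly >4 dB before slope fitting to avoid floor compression of the
slopes. Equally-effective-masker comparisons use one-tailed pooled-variance
Student t-tests from summary statistics (`df = n1 + n2 − 2`); the pooled
rather than Welch form matches the degrees of freedom that the worked
examples imply, verified against the packaged summary table. The Holm
correction family is the set of per-participant matched-level tests
(configurable; the family is a convention, not a derived quantity).

The mixed models fit estimated gain reduction on uncentred level (dB SPL
for tones, dB/ERB for noise), precursor-class and their interaction, with
the on-frequency tone as reference class, by REML via statsmodels MixedLM.
Two random-effect structures are exposed: by-participant intercepts plus
by-participant class offsets with correlation (the two-class tonal model),
and intercepts only (the three-class model including broadband noise). The
backend does not provide Satterthwaite degrees of freedom, so p-values use
a residual-df approximation and the result is flagged accordingly
(`df_method="residual"`); estimates and SEs, the quantities of interest,
are unaffected. Model-structure selection (backward elimination) is not
reimplemented; the final structures are fitted directly as explicit
configuration. Fits are cross-checked against lme4 (REML) in the test
suite, agreeing to better than 1e-3 on fixed effects.

## Synthetic data

Two generator tiers separate failure diagnosis. The *direct* tier draws
gain-reduction estimates straight from the hierarchical model: fixed
effects default to the fitted tonal-model values (intercept −4.32, level
slope 0.33, off-frequency offset −49.47, interaction 0.47) with variance
components 31.23 (participant intercepts), 16.18 (participant class
offsets, correlation −0.02) and 11.98 (residual); the three-class variant
uses intercept −3.40, slope 0.29, offsets −47.50/+1.52, interactions
0.46/0.11, intercept variance 48.90 and residual 15.62, with 4
participants. The *full* tier chains mechanistic listeners through the
detection model and staircase for every condition of the three designs.

Study conditions: 7 participants (tonal) and 2 runs per condition;
precursor level grids 20–90 dB SPL on-frequency (10-dB steps), 60–95 dB
SPL off-frequency (5-dB steps) and 24–64 dB overall for the noise (10-dB
steps, converted to 10.6–50.6 dB/ERB; the 64-dB cap avoids the
middle-ear-muscle reflex, which is represented only as this level guard).
The ranges are the experimental ones; the spacings are a package choice of
realistic psychoacoustic grids. Quiet thresholds are drawn from 5–20 dB
SPL and are unanchored (no numeric per-participant values exist to match).
Negative generated estimates are kept — floor filtering is an
analysis-stage concern.

What the generator does *not* emulate: listener lapses and attention
drift, the high-pass background noise (a metadata flag only),
off-frequency listening, MOCR onset-delay dynamics (the paradigm's timing
is assumed fully effective), and idiosyncratic participants (one highly
variable listener, one affected by a frozen-noise artefact). Passing
recovery tests therefore show that the pipeline is unbiased under its own
assumptions, not that those assumptions hold for any given listener.

## Numerical and degenerate cases

Bisection tolerance 0.01 dB everywhere; thresholds saturate at
[−20, 120] dB SPL with the boundary value rather than failing. With an odd
count of final-step reversals the earliest is dropped. A reversal SD of
exactly 5 dB passes QC (the exclusion is strict). Zero pooled variance
with equal means raises rather than returning 0/0. The Markov-chain oracle
refuses degenerate psychometric functions at the grid edge (reducible
chain). Mixed-model non-convergence and singular fits are flagged on the
result, never silently replaced.

## Known limitations

The floor filter truncates the response distribution, which biases
recovered level slopes slightly downward (about 0.03 on the tonal level
slope, 0.06 on the interaction, at the study's sample sizes); this is a
property of the published estimation procedure itself, reproduced rather
than corrected here. Recovery studies use 50 replicate cohorts; residual
Monte-Carlo error on mean coefficients is ~0.01. The model has no temporal
window, so masker–signal delay effects outside the fixed paradigm are out
of scope, as are otoacoustic-emission measures and contralateral
elicitation.
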