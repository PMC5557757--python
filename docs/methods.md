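# Methods

This note documents the models, estimators and numerical choices behind
`psytact`, and what its synthetic-data generator does and does not emulate.

## Event-related SCR extraction (`psytact.scr_events`)

The statistic is deliberately literal: the *pre-stimulus value* is the
conductance at the last sample strictly before stimulus onset (a point
value, not a pre-window mean), the *peak* is the global maximum over the
half-open window (offset, offset + 10 s], and the response delta is their
difference. No tonic/phasic decomposition, deconvolution or artifact
rejection is attempted. Two consequences worth knowing:

* The window is anchored at stimulus **offset**; latency is reported
  relative to offset. When the 10-s window would overlap the next trial
  the window is kept untruncated and the overlap logged.
* The minimum response amplitude that counts as an event-related response
  defaults to 0.05 μS — the conventional electrodermal minimum. It is a
  config parameter (`amplitude_criterion_uS`), and downstream results are
  always reported alongside the criterion used, because the inclusion
  rule (≥ 1 responding trial per intensity) depends on it.
* Whether the published mean peak latency of such analyses is computed
  per trial or per participant mean is generally ambiguous; the pipeline
  reports both (they coincide when every participant contributes the same
  number of trials).

Negative deltas are retained in trial records; they can never satisfy the
response criterion.

## Synthetic cohort and traces (`psytact.synthetic_data`)

The generator's defaults are the study conditions all validation runs
under; they are calibrated, not tuned:

* **SCR amplitudes.** Per (group × intensity) cell the participant-level
  mean amplitude is Normal with the cell mean/SD (ASD weak 1.025 ± 0.559,
  TD weak 0.489 ± 0.336, ASD strong 2.165 ± 1.040, TD strong 1.332 ±
  0.581 μS), clipped at 0 μS. Clipping biases the recovered cell means
  upward by < 0.01 μS at these mean/SD ratios — the calibration-recovery
  test tolerances account for it. Trial-to-trial amplitude noise is
  0.15 μS (SD).
* **Latent structure.** A standard-normal autonomic reactivity trait z
  correlates ρ = 0.6 with the amplitude deviations and, with loading
  λ = 0.7 (sign per subscale; Sensation Seeking loads negatively), with
  every questionnaire subscore. Within a group this gives the closed-form
  correlation corr(amplitude, subscore) = ρ·λ, which the tests verify by
  Monte-Carlo. Weak and strong amplitudes share a common component so
  their within-participant correlation is a parameter (default 0.5 — no
  published value exists, so it is exposed rather than asserted).
* **Traces.** tonic level (≈ 5–6 μS, SD 2.4) + optional linear drift +
  slow tonic wander (0.3 μS SD, ≈ 30 s correlation scale, generated on a
  coarse grid and interpolated) + one unit-normalized bi-exponential
  (Bateman) phasic response per stimulation + smoothed Gaussian sensor
  noise (0.02 μS SD, 0.5 s smoothing) at 20 Hz. 20 Hz is ample to
  localize a multi-second SCR peak while keeping trace files small.
* **Kernel timing.** Rise τ = 2 s, decay τ = 10 s, onset delay 1.6 s
  after stimulus onset. The closed-form kernel peak then falls
  delay + ln(τd/τr)·τrτd/(τd−τr) = 5.62 s after onset, i.e. ≈ 4.6 s after
  the offset of a 1-s stimulus — the latency regime typical of
  event-related SCRs. Any bi-exponential with the right peak timing would
  do; these values were chosen for that timing. Per-event delay jitter
  (SD 1.5 s, truncated at 0.1 s) supplies trial-to-trial latency
  variability; truncation biases the mean latency upward by ≈ 0.1–0.2 s,
  which the ±1 s latency checks absorb. The kernel is unit-normalized so
  an injected amplitude A produces a peak delta of exactly A (up to one
  sample's discretization) in a noise-free trace — the identity the
  extraction tests exploit.
* **Sessions.** The electrical task alternates weak/strong three times in
  a fixed order, one stimulus of 1 s every 44 s; currents per cell follow
  the configured means/SDs clipped to their instrument ranges
  (200–500 μA weak, 1000–2000 μA strong). Ratings (0–10) are discretized
  normals with weak < strong means per category and a participant-level
  offset. Sensation/pain thresholds are Normal/lognormal with group
  means matched to the published summaries (groups differ only in pain
  spread, none in location — the null the t-tests should find).
* **Observers.** 2IFC observers have P(correct) = γ + (1 − γ − λ)·
  F((x − θ)/σ) with logistic F and γ = 0.5; per-site thresholds are
  lognormal around plausible site means (palm < forearm ≲ neck) with
  spread proportional to θ. The comparison observer answers "stronger"
  with probability F(b·(x − PSE)), PSE ≈ 1.4 g, b ≈ 2 g⁻¹.
* **Randomness.** Everything flows from one integer seed through
  hierarchical stream splitting (`substream(seed, *keys)`, CRC-hashed
  spawn keys): any participant × task can be regenerated independently,
  and identical (spec, seed) is bit-identical.

What the generator does **not** emulate: electrode physics, motion and
respiration artifacts, non-stationary habituation of SCR amplitude across
trials, true counterbalancing schedules (interval order is drawn i.i.d.),
and any dependence of staircase thresholds on the latent autonomic trait
(discriminative and autonomic processes are independent by construction —
the null hypothesis of the perceptual comparisons). Passing tests
therefore certify the *procedures*, not the realism of any particular
physiological waveform.

## Staircases (`psytact.staircase`)

Transformed up-down (2-down/1-up) with the two task ladders (two-point
separations 2–90 mm; monofilament forces 0.008–6 g). Bookkeeping choices:

* The correct-counter resets on every error and whenever a move is
  triggered; because every level change is caused by an event that itself
  resets the counter, the `reset_on_change` option is accepted but
  behaviorally inert under this bookkeeping.
* A reversal is recorded at the level where the direction change occurred
  (the level of the trial that triggered the opposite move). Moves
  clamped at the ladder ends still count in their intended direction.
* Runs start at the ladder maximum (clearly suprathreshold) unless
  configured otherwise; termination is ten reversals, or ten consecutive
  correct trials at the ladder minimum ("passed minimum"). A 10,000-trial
  cap guards pathological observers.
* Participants who pass the minimum enter group analyses with the
  threshold recorded at the minimum level; the substitution is noted in
  the exclusion ledger rather than excluding the participant.

**Estimator behavior.** The rule's equilibrium is the P(correct) = √½ ≈
0.707 point, but the last-five-of-ten-reversals estimator is *not*
consistent as the rung spacing shrinks relative to the observer's spread:
when σ ≫ step the mean estimate overshoots the 70.7 % point by ≈ 0.5 σ
(an independent bare-bones re-simulation reproduces the same overshoot,
so it is a property of the procedure, not of this implementation). The
convergence validation therefore runs in the regime the procedure is
designed for — spread comparable to the local rung spacing (θ = 12 mm,
σ = 1.5 mm on the 1-mm region of the two-point ladder) — where the bias
is a fraction of a rung.

## Psychometric fitting (`psytact.psychometric`)

The printed form of such psychometric equations has no free parameters;
the minimal family consistent with fitting it to data is the
two-parameter location/scale logistic F(x) = expit(a + b·x), fitted by
maximum likelihood on the binomial counts with a weak ridge penalty on b
(default 10⁻⁴·b²) because 6 forces × 32 trials can separate. Optional
guess/lapse asymptotes are fixed parameters (default 0), not estimated.
Forces enter in raw grams (no log transform). Fully separable data
(every observed fraction exactly 0 or 1) are flagged `converged = False`
with a warning, and the slope accessor refuses them. PSE = −a/b;
slope at the 50 % point = (1 − γ − λ)·b/4, which reduces to b/4 with the
defaults. Group comparison uses per-participant slopes as the unit of
analysis. The start point is a logit-regression moment estimate;
optimization is L-BFGS-B with b bounded below by 10⁻⁹.

## Statistical battery (`psytact.stats`)

* Equal-variance (Student) t throughout — matching df = n₁ + n₂ − 2, not
  Welch; Cohen's d uses the pooled SD and is reported as a magnitude.
  The result's signed t follows the convention sign(t) = sign(m₂ − m₁).
* The mixed ANOVA uses the textbook split-plot decomposition with the
  subjects-within-groups error for the between factor and the
  level × subjects-within-groups error for the within factor and
  interaction; with a single between factor and complete within data this
  coincides with Type III for balanced groups, and unbalanced group sizes
  enter through the weighted level means. The partition
  SS_total = SS_between-subjects + SS_within-subjects is exact (machine
  precision) and asserted in tests; partial η² = SS_effect/(SS_effect +
  SS_error-of-that-effect). Sphericity corrections are not applied, and
  the result carries a `sphericity_corrected = False` flag.
* Mann-Whitney defaults: midrank tie correction ON, continuity correction
  OFF — the combination that best matches z values computed from printed
  U statistics without tie information; both flags are exposed, and the
  small-n tests show the continuity-corrected variant tracks the exact
  enumeration p.
* The Benjamini-Hochberg rule is implemented verbatim in its strict form:
  q = Q·i/m and significance for the largest p with p **<** q and all
  smaller p. The strict/non-strict distinction is observable only at
  exact equality p = q (tested); on generic p-values the decision set
  matches the standard step-up implementation in statsmodels. Ties share
  the decision of the highest-ranked tied member.

## Pipeline (`psytact.pipeline`)

One integer seed reproduces everything, including byte-identical
`stats_summary.json`. Cohort facts that are not rules — drop-outs for
scheduling, refusal or experimental error — are supplied as configuration
annotations (defaults mirror the emulated study: 2 + 1 ASD missing the
electrical tasks, 1 TD recording error, 1 ASD recording error per
staircase task); the computed exclusions (`no_scr_peak`) come from the
inclusion rule. All output is plain CSV/JSON with a `schema_version`
manifest. Stage failures abort with the stage name. The CLI verbs
(`simulate`, `analyze`, `report`, `all`) are a thin layer over
`simulate_frames` / `analyze_frames` / `render_report`.

## Problem sizes used in validation

Chosen as the package's standard validation sizes: staircase convergence
uses 2,000 runs; extraction-oracle agreement 1,000 traces; psychometric
recovery 40 simulated observers at 32 and 128 trials per force; the
calibrated power check 100 replicates at 200 participants per group
(the group SCR effect of the calibrated cells is ≈ 1 pooled SD, so
detection there is essentially certain — the check guards the pipeline
plumbing, not a marginal power calculation).

## Known limitations

* The trace model is additive and stationary; it cannot produce the
  habituation, superposition nonlinearity or recovery-limited peaks of
  real electrodermal recordings.
* The staircase estimator inherits the overshoot described above whenever
  an observer's spread is large relative to the rung spacing; thresholds
  from very shallow observers should be interpreted as upper bounds.
* Exact Mann-Whitney p-values are not computed for large samples; the
  normal approximation (optionally continuity-corrected) is used.
* No lapse/guess estimation in the psychometric fit; misspecified
  asymptotes bias b downward slightly at extreme forces.
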