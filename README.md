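# psytact

Simulation and analysis pipeline for a four-task tactile-sensitivity study
design: event-related skin-conductance responses (SCR) to electrical
stimuli, two transformed up-down staircase threshold procedures (two-point
discrimination and monofilament touch detection), a constant-stimuli touch
comparison task, and the accompanying statistical battery.

The package is aimed at psychophysicists and autonomic psychophysiologists
who want a fully reproducible, testable implementation of this analysis
chain. Because raw participant data of such studies are typically not
public, a seeded synthetic-data generator emulates the cohort structure —
two groups (ASD and typically developing adults) with a latent autonomic
reactivity trait that drives both phasic SCR amplitudes and questionnaire
subscores — so every stage of the pipeline can be exercised and validated
end to end without any external data.

## The statistics at the core

* **Event-related SCR.** For a stimulation with offset *t₀*, the response
  is Δ = max{SC(t) : t₀ < t ≤ t₀ + 10 s} − SC(t⁻), the windowed
  post-offset peak minus the conductance at the last sample strictly
  before onset. A participant enters group analyses only with ≥ 1
  responding trial (Δ ≥ 0.05 μS by default) at each intensity.
* **Transformed up-down staircase.** Two consecutive correct responses
  lower the stimulus one ladder level, one error raises it one level;
  the run stops at ten reversals (threshold = mean of the last five
  reversal levels) or ten consecutive correct trials at the ladder
  minimum. The rule converges at the P(correct) = √½ ≈ 0.707 point.
* **Cumulative-logistic psychometric function.** For comparison forces
  *x*, F(x) = 1 / (1 + e^−(a + bx)) is fitted by penalized maximum
  likelihood; PSE = −a/b and the sensitivity index is the slope at the
  50 % point, b/4.
* **Statistical battery.** Pooled-variance two-sample *t* with Cohen's
  *d*, 2 × K mixed-design ANOVA with partial η² (split-plot sums of
  squares, no sphericity correction), Bonferroni pairwise post-hocs,
  Mann-Whitney *U* with the normal approximation
  z = (U − n₁n₂/2) / √(n₁n₂(n₁+n₂+1)/12), Pearson correlations with the
  t-transform p, and Benjamini-Hochberg control with critical values
  q = Q·i/m and the strict p < q step-up rule.

## Worked example

```python
from psytact import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=3), out_dir="psytact_out")
scr = result.summary["est"]["event_scr"]
print(f"group main effect: F({scr['between']['df'][0]}, {scr['between']['df'][1]}) "
      f"= {scr['between']['statistic']:.3f}, p = {scr['between']['p']:.2e}, "
      f"partial eta^2 = {scr['between']['effect_size']:.3f}")
lat = result.summary["est"]["peak_latency"]
print(f"mean peak latency: {lat['per_trial_mean_s']:.3f} s")
```

prints

```
group main effect: F(1, 36) = 42.225, p = 1.51e-07, partial eta^2 = 0.540
mean peak latency: 5.037 s
```

i.e. with the generator calibrated to its default cell means (weak ≈ 1.0 vs
0.5 μS, strong ≈ 2.2 vs 1.3 μS) the simulated high-reactivity group shows a
reliably larger event-related SCR, and the simulated response peaks arrive
≈ 4.6–5 s after stimulus offset. `psytact_out/` receives every intermediate
table (trial CSVs, traces, fits, the exclusion ledger), a nested
`stats_summary.json` and a human-readable `report.txt`.

The same run is available from the shell:

```bash
psytact all --seed 3 --out psytact_out
# or staged: psytact simulate ... ; psytact analyze ... ; psytact report ...
```

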