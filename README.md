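# gazecomplexity

Detecting what a computer user is doing — reading a text, watching a video,
or typing — from desktop eye-tracker output, by contrasting two families of
eye-movement features:

* **conventional features**: seven summary statistics (min, max, median,
  mean, SD, variance, skewness) of eight tracker channels (fixation
  duration, four pupil-size channels, blink duration and rate, saccade
  magnitude) over consecutive 3-second windows — 8 × 7 = **56 features**;
* **complexity features**: each of nine channels is decomposed by empirical
  mode decomposition (EMD) into intrinsic mode functions (IMFs)
  `X(t) = Σᵢ cᵢ(t) + rₙ(t)`, and every IMF is scored with multiscale sample
  entropy — `SampEn(N, m, r) = −ln(Aᵐ(r)/Bᵐ(r))` on coarse-grained series
  `y_j^τ = (1/τ) Σ x_i` for scales τ = 1…10, with m = 2 and r = 0.15·SD of
  the raw channel — plus the complexity index CI = Σ_τ SampEn(τ).
  9 channels × 6 IMFs × (10 scales + CI) = **594 features**.

Both tables are screened per feature with a two-factor mixed-model ANOVA
(activity fixed, participant random; `F = MS_activity / MS_interaction`
with df (a−1), (a−1)(s−1)), and the four feature sets (all/screened ×
conventional/complexity) feed three classifiers (SVM, decision tree, random
forest) under a repeated 80/20 holdout protocol — the 12-model benchmark.

Because raw recordings from cohort studies of this kind are rarely shared,
the package ships a **synthetic cohort generator**: activity-specific scan
patterns (reading staircases, pursuit drift, typing zone alternation),
Poisson blinks, activity-dependent pupil baselines (watching 19.93 px >
typing 19.34 px > reading 17.97 px), and a per-activity spectral exponent
that gives each activity a distinct complexity signature. Every stage of
the pipeline runs end to end from a single seed.

It is aimed at researchers in eye-movement analysis and human-activity
recognition who want a tested, reproducible reference implementation of the
EMD + multiscale-entropy feature pipeline and its screening/benchmark
protocol.

## Worked example

```python
from gazecomplexity import (
    SimConfig, simulate_cohort, build_conventional_table,
    build_complexity_table, screen_features, BenchmarkSpec, run_benchmark,
)

cohort = simulate_cohort(SimConfig(n_participants=10, seed=5))   # 30 tasks
conventional = build_conventional_table(cohort)   # 600 rows x 56 features
complexity = build_complexity_table(cohort)       # 30 rows x 594 features

result, conventional_screened = screen_features(conventional)
print(result.n_retained)                          # 41 features significant

spec = BenchmarkSpec(methods=("RF",), base_seed=11,
                     feature_sets=("conventional_screened", "complexity_screened"))
_, complexity_screened = screen_features(complexity)
reports = run_benchmark(spec, {
    "conventional_screened": conventional_screened,
    "complexity_screened": complexity_screened,
})
for r in reports:
    print(r.summary())
```

Output for this seed:

```
41
RF / conventional_screened (41 features): 95.83 +/- 1.83 %
RF / complexity_screened (561 features): 100.00 +/- 0.00 %
```

41 of the 56 conventional statistics show a significant activity effect;
the random forest recovers the three activities from the screened
complexity features perfectly on this cohort and makes ~4% window-level
errors on the screened conventional features — the complexity features
carry the stronger activity signal, which is the package's central
reproducible result. (See `docs/methods.md` for why the synthetic
conventional accuracies are higher than real-data studies report.)

The same pipeline is scriptable from the shell:

```bash
gazecx run-all --out results/ --seed 5 --n-participants 10
```

which writes the recordings (CSV dialect with the FPOG/LPD/RPD/BKDUR/...
channels), both feature tables with provenance sidecars, screening grids,
confusion matrices and a 12-row comparison table, each stage with a
content-hash manifest.

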