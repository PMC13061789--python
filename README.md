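# multitact

Simulation and analysis tools for behavioral experiments that deliver
visual, auditory, and vibrotactile stimuli through smartphone browsers —
aimed at researchers who want to know **whether browser-delivered vibration
is good enough for reaction-time work**, and at anyone analyzing the
resulting data.

The package covers four analyses, each exercisable end-to-end on synthetic
data with known ground truth:

1. **LATER-model Monte Carlo power analysis** (`multitact.later_power`).
   Under the LATER model each trial's decision signal rises at a rate
   *v* ~ N(μᵢ, σᵢ) truncated at zero, and RT = 1/*v*. Participants are
   hierarchical: μᵢ ~ N(μ_base = 2.5, σ_μ = 0.3) s⁻¹ and
   σᵢ ~ |N(0.4, 0.1)| s⁻¹. A slowing manipulation decrements the mean rate
   by Δμ; stimulus-onset imprecision adds zero-mean Gaussian "onset noise"
   to every RT. Whole experiments (20 participants × 100 trials per
   condition) are simulated, paired participant mean RTs are tested with a
   two-sided Wilcoxon signed-rank test (exact null distribution for
   n ≤ 25), and the empirical power curve over a Δμ grid is interpolated
   to the smallest effect reaching 80% power. Δμ converts to an intuitive
   RT shift via 1/μ_base − 1/(μ_base − Δμ).

2. **Perceptual-intensity matching staircase**
   (`multitact.staircase_matching`). A 1-up-1-down staircase with a 5%
   step adjusts a comparison stimulus until it perceptually matches a
   reference vibration, terminating after 8 reversals, 50 trials, or a
   10-trial plateau at maximum intensity; the point of subjective equality
   (PSE) is the mean of the final six reversal values. A logistic
   simulated observer supports recovery testing.

3. **Redundant-target-effect (RTE) pipeline** (`multitact.rte_pipeline`).
   Trial-level RTs from a 7-condition multisensory detection task
   (V, A, T, AV, AT, VT, AVT + catch trials) are filtered (100–1000 ms
   range, then a single-pass 2.5-SD rule per participant × condition),
   summarized at the participant level, and analyzed with a one-way
   repeated-measures ANOVA (Greenhouse–Geisser ε from the condition
   covariance, Mauchly's W, classical and partial η²) plus Holm-corrected
   pairwise paired t-tests.

4. **Stimulus timing analysis** (`multitact.timing_analysis`). From mono
   session recordings, physical stimulus onsets are detected with a
   normalized RMS-envelope threshold detector (frame 2048 / hop 512,
   pluggable so an external detector can substitute, with sub-sample
   Hilbert-envelope refinement), cleaned by a spurious-onset rule
   (pre-onset amplitude > 0.01 rejected), matched to device markers and
   browser triggers, and summarized as lag/precision/asynchrony tables in
   ms, including an OLS regression of visual–vibration asynchrony on the
   vibration motor's ramp-up period.

`multitact.synthetic_data` generates every input with ground truth: RTE
trial tables (30 catch + 10×7 target trials per participant, correlated
participant condition means, contaminant trials) and timing sessions
(700-ms trials, stimuli nominally at 300 ms, per-channel lags, ramped
vibration bursts, closed-form device markers).

## Worked example

```sh
python examples/power_analysis.py
```

```
onset noise    0 ms: min delta_mu for 80% power = 0.0415 1/s (~6.75 ms slower RTs)
onset noise   10 ms: min delta_mu for 80% power = 0.0414 1/s (~6.74 ms slower RTs)
```

At 1,000 Monte Carlo replicates per grid point, a drift-rate decrement of
about 0.042 s⁻¹ — roughly a 7-ms mean RT slowdown — is the smallest effect
detectable at 80% power, and adding 10 ms of stimulus-onset jitter barely
changes it: trial-to-trial decision variability dominates onset
imprecision of this size. The other examples
(`staircase_recovery.py`, `rte_analysis.py`, `timing_session.py`) walk
through PSE recovery, the filtering + ANOVA pipeline, and the
waveform-to-lag-table analysis the same way.

A thin CLI mirrors the library for shell use:

```sh
multitact power --config power.yaml --out curve.csv
multitact staircase-sim --pse 0.6 --slope 0.05 --reps 500 --seed 1 --out results.csv
multitact rte-analyze trials.csv --out report.json
multitact simulate-session --config sess.yaml --out-dir fixtures/
multitact timing-analyze fixtures/vibration_mic.wav fixtures/events.json \
    --channel vibration_mic --out lags.csv
```

Every command writes a JSON run manifest (version, seed, config hash)
beside its outputs; identical config + seed reproduces outputs
byte-identically.

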