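# Methods notes

This note records the models, defaults, numerical conventions, and design
choices behind each stage, and what the synthetic-data generators do and do
not emulate.

## LATER Monte Carlo power analysis

**Model.** Per trial a decision rate *v* is drawn from N(μ, σᵢ) truncated
at zero and RT = 1/*v* (the LATER model's reciprocal-rate form). The
population is hierarchical: participant mean rates μᵢ ~ N(μ_base, σ_μ)
and rate SDs σᵢ = |N(σ_base, σ_σ)|, with defaults μ_base = 2.5 s⁻¹,
σ_μ = 0.3, σ_base = 0.4, σ_σ = 0.1. The experimental condition lowers the
mean rate to μᵢ − Δμ. Onset noise — trial-to-trial jitter of the physical
stimulus onset — is zero-mean Gaussian (SD in ms) added to every simulated
RT in *both* conditions; the manipulation of interest is the noise SD
(0 vs 10 ms), not a between-condition asymmetry. Noise-perturbed RTs are
not clipped: at the default parameters the noise (≤ tens of ms) is far
smaller than any RT (~400 ms), so negative RTs do not arise in practice.

**Truncation.** Rates are truncated at zero by rejection (redraw of
non-positive draws). With μ about six SDs above zero the rejection loop
essentially never fires, and the positive tail is undistorted. The formal
moments of 1/v under zero-truncation diverge logarithmically at v → 0;
this is a tail property that finite samples at these parameters never
probe (P(v < 0.5) ≈ 3·10⁻⁷), which is why the simulation is stable and
why the test-suite quadrature oracle integrates over the effectively
sampled range.

**Test statistic.** Each replicate experiment draws *fresh* participants
(the hierarchy is part of the simulated experiment), computes each
participant's mean RT per condition, and applies a two-sided Wilcoxon
signed-rank test to the 20 paired means. The exact null distribution of
W⁺ (dynamic programming over rank inclusion) is used for n ≤ 25, a normal
approximation with continuity correction above; zero differences are
dropped (Wilcoxon's convention; with continuous RTs they have probability
zero). The vectorized implementation is cross-checked against
`scipy.stats.wilcoxon` in the tests.

**Power curve and minimum effect.** Power at each Δμ is the fraction of
replicates with p < α (α = .05), with binomial Monte Carlo SE
√(p(1−p)/n_reps). The default grid is 0 to 0.08 s⁻¹ in steps of 0.005
(the grid is a package choice; only the interpolation rule is fixed), and
the minimum detectable effect is the piecewise-linear interpolant at the
first adjacent grid pair bracketing the target power (default 80%). Each
grid point runs on an independent RNG substream spawned from the top-level
seed, so curves are reproducible and parallelizable. The RT-space
interpretation of Δμ is 1/μ_base − 1/(μ_base − Δμ); for Δμ = 0.0421 at
μ_base = 2.5 this evaluates to 6.85 ms.

**Problem sizes.** The full design (10,000 replicates × 17 grid points ×
2 noise levels ≈ 3.4·10⁵ simulated experiments, 1.4·10⁹ trial draws) runs
in about a minute vectorized; the test suite uses 2,000 replicates, at
which the interpolated minimum effect is stable to about ±0.001.

## Staircase

One comparison stimulus intensity in [0, 1]; a "comparison more intense"
response moves it down one step, "vibration more intense" moves it up
(1-up-1-down), converging on the 50% point. Defaults: step 0.05 (5% of
the normalized range, fixed size, no step-halving), start 0.5, bounds
[0, 1]. A reversal is recorded at the value presented on the trial where
the step direction flips; moves clamped at a bound keep their intended
direction, so sitting at a bound does not accumulate reversals. Tracks
end after 8 reversals (configurable; one part of the source procedure
describes nine, the main procedure text eight — eight is the default), 50
trials, or when the last 10 presented values all sat at the maximum bound
(the plateau rule applies at the maximum only; an analogous minimum-bound
plateau was not described and is not implemented). The PSE is the mean of
the final six reversal values; with fewer than six reversals all are
averaged and the result is flagged degraded. The simulated observer is
logistic with scale `slope` and symmetric lapses; slope 0 gives a
deterministic threshold observer.

## RTE pipeline

Filters are order-fixed: catch trials and misses are excluded from RT
analysis first (but tabulated), then the absolute range filter
(RT < 100 ms or > 1000 ms removed), then a *single-pass* 2.5-SD rule using
the sample SD (n−1) computed per participant × condition on the range
survivors. Pass count and denominator are package choices where the
procedure's description is silent. Cells left with fewer than two trials
skip the SD rule with a warning.

Condition summaries are computed on participant means first (so N is the
number of participants), matching how such tables are conventionally
reported. The RM-ANOVA uses the classical sums-of-squares partition
(subjects, conditions, residual); Greenhouse–Geisser ε comes from the
double-centered sample covariance of the condition columns,
ε = tr(CSC)² / ((k−1)·ΣΣ(CSC)²ᵢⱼ); Mauchly's W uses the eigenvalues of
the covariance in an orthonormal contrast basis with the standard
chi-square approximation (no second-order term; pingouin's higher-order
correction makes its Mauchly p differ slightly, which the tests account
for by comparing W and χ² rather than p). Corrected p-values evaluate F
at ε(k−1), ε(k−1)(n−1); both corrected and uncorrected p are reported,
as are classical η² (SS_cond/SS_total, the headline value) and partial η²
(SS_cond/(SS_cond+SS_err)) — analysis packages differ in which "η²" they
print, so both are exposed. Pairwise comparisons are all 21 paired
t-tests on participant condition means with Holm step-down adjustment
(via statsmodels).

## Timing analysis

**Envelope.** Per-frame RMS (default frame 2048, hop 512 samples),
normalized to peak 1, computed with a cumulative-sum identity so long
sessions stay O(n). Frame time is the frame center.

**Onset detector.** The default detector reports the first upward crossing
of the normalized envelope above a threshold (default 0.05) after a
refractory interval (default 100 ms). The onset time convention is the
first sample of the crossing frame. With `refine=True` (default) the
estimate is sharpened to sub-sample precision: the analytic-signal
(Hilbert) amplitude envelope is computed on a window around the crossing
frame — with a 256-sample margin discarded on each side, since the FFT's
periodic extension otherwise leaks the burst plateau into the pre-onset
region — and the threshold crossing is located by linear interpolation.
Refinement matters: frame-level quantization (hop/sample-rate, ~11.6 ms
at 44.1 kHz) would otherwise dominate millisecond-level lag statistics.
The detector is pluggable (`detect_onsets(..., detector=...)`) so a
trained onset-detection network can be substituted; the envelope-threshold
default is what ships.

**Spurious-onset rule.** Each onset is annotated with the normalized RMS
of the last frame lying wholly *before* the crossing frame — the
amplitude already present before the putative onset. Onsets with
pre-onset amplitude strictly above 0.01 are rejected as spurious (a real
onset rises out of silence; a mid-burst false alarm sits on top of signal).
Annotating the crossing frame itself would be useless here, since it is
≥ the detection threshold by construction; and for slow-attack (ramped)
stimuli even the immediately preceding frame overlaps the stimulus's own
ramp, which is why the wholly-before convention is used.

**Matching and tables.** Device markers are paired with the nearest
accepted onset within 150 ms (unmatched markers are reported, never
silently dropped); lag = marker − onset, positive when the marker trails
the physical onset. Lag/asynchrony tables report mean, SD (n−1), min,
quartiles (linear interpolation between order statistics), and max in ms;
internal computation is in seconds at full sample resolution. The ramp
regression is ordinary least squares with classical SEs, t-tests, 95%
CIs, R², and the overall F.

## Synthetic data

**RTE tables.** Participant condition means are multivariate normal
around the configured group means with covariance ρ·σᵢσⱼ (default
ρ = 0.8 across conditions — a package choice needed for realistic
repeated-measures behavior). The default group means/SDs describe a
plausible multisensory sample in which redundant targets are ~50–80 ms
faster than single targets. Trial RTs are normal around the participant
mean (trial SD default 80 ms), contaminated at configurable rates with
anticipations (uniform 20–95 ms), slow outliers (uniform 1.05 s to the
1.7-s response window), and misses; each participant contributes 30 catch
trials plus 10 per target condition (100 total).

**Timing sessions.** Trials are 700 ms (300-ms foreperiod, 200-ms
stimulus) with trigger streams at 0/300/700 ms; 1000 trials in blocks of
250 by default. Each channel carries a tone burst (light proxy 400 Hz,
sound 440 Hz, vibration 180 Hz) whose amplitude envelope ramps linearly
(optionally exponentially) over the channel's ramp duration and holds to
stimulus offset, on top of a Gaussian noise floor; physical onsets are the
nominal onset plus a per-trial Gaussian channel lag. Defaults place the
light at 35.9 ± 4.3 ms, sound at 40.9 ± 3.4 ms, vibration onset at
48.1 ± 3.0 ms with a 30.46 ± 5.28 ms ramp — magnitudes typical of
browser-delivered stimuli on a phone. Device markers are computed in
closed form as the time the deterministic amplitude envelope crosses the
marker threshold (default 0.4 of peak), emulating a sound-level trigger
box and giving exact crossing-time oracles for tests: delay = f·τ for a
linear ramp, −(τ/3)·ln(1−f) for the exponential form. The light channel
is modeled as a tone whose ramp spans at least one carrier cycle; a
near-DC carrier with a sub-cycle ramp behaves like a hard step, whose
Hilbert-envelope precursor degrades sub-millisecond onset estimation.
The vibration channel is a pure ramped tone by default; broadband motor
noise is not modeled (configurable frequency, but no spectral model of
specific phone motors), and device lags are i.i.d. across trials — real
sessions may drift or show block structure.

**What passing tests show.** Recovery tests demonstrate that the analysis
code measures what the generators put in (lag means to within twice the
table's standard error, regression slopes/intercepts within twice their
SEs, ANOVA effects where built in). They do not certify performance on
real recordings — real vibration spectra, room noise, device drift, and
detector substitution (e.g., a neural-network onset detector) are outside
what the generators emulate.

## Degenerate inputs and tie-breaks

Zero-variance rate draws (σᵢ = 0) and zero ramp durations are exact
special cases, not errors. A constant condition matrix yields F = 0 and a
trivially spherical (W = 1) Mauchly result. Wilcoxon rows with ties or
zeros fall back to scipy's implementation. An all-zero recording keeps an
all-zero envelope (no normalization blow-up). Staircases that plateau
without a single reversal report the maximum bound as a degraded PSE.
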