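# Methods

This note documents the models, conventions and numerical choices behind
`ldstest`, in the order data flow through the package.

## Synthetic data

The generators produce data with the statistical structure the analyses
assume. They are first-class, tested code — the study conditions they encode
(sample sizes, stimulus schedule, noise levels) are fixed defaults, not knobs
tuned per analysis.

**Stimulus schedule.** One LDS-test run is laid out on a single timeline:
six PRE tone-pip trains (10 s at 21.1 Hz, 10-s gaps), 60 s PRE silence, the
60-s LDS, 240 s POST silence, six POST trains. Each train holds
⌊10 × 21.1⌋ = 211 pips, i.e. 1,266 per condition, and the pip cycle is
1/21.1 s ≈ 47.39 ms. In the original experiments spontaneous and sound-driven
activity were separate recordings; a single recording cannot place both the
240-s silence and the first tone train immediately after LDS offset. The
afterdischarge analysis references POST-silence bins to LDS offset and the
plasticity analysis injects its effect through the generator's `post_scale`,
so the compromise does not bias either analysis.

**Spike trains.** Superposed Poisson processes per channel: homogeneous
spontaneous firing over the whole run; an added constant rate during the LDS
(`lds_evoked_rate`, needed so channels can satisfy the sound-driven
responsiveness criterion); onset-locked pip responses as constant-rate bursts
over `[onset_latency, onset_latency + duration]` after each pip, scaled by
`post_scale` for post-LDS trains; and, where planted, an afterdischarge rate
increment `multiplier × spontaneous_rate × exp(−t/τ)` from a delay after LDS
offset, sampled by inversion. Additivity (superposition) is the simplest model
consistent with sound-driven rate increases; the exponential afterdischarge
decay is a convention — the source literature describes only "a sustained
increase in spontaneous firing" with no distributional detail. Defaults:
spontaneous 5 Hz, evoked 100 Hz over 12 ms from 6 ms latency, multiplier 5,
τ = 20 s. All randomness flows from one seed; channel substreams use
`default_rng([seed, channel])`, so datasets are bit-reproducible.

**ABR sweeps.** Each sweep is a six-wave template plus white noise
(default 1 µV SD, 1,266 sweeps, 25 kHz, 15-ms window). Each wave is biphasic —
a positive Gaussian lobe at its latency and a negative lobe (70% of the
amplitude) delayed by 2.2σ — chosen for differentiable, parameterizable peaks;
the study did not model waveforms. Default latencies (2.2, 3.0, 3.9, 4.9, 6.0,
7.4 ms) and amplitudes (0.70, 0.60, 0.65, 0.55, 1.40, 0.50 µV, σ = 0.2 ms) are
mouse-plausible and chosen so wave V's following trough is the global minimum
of the waveform — the anchor the picking rule requires — and remains so under
post-LDS amplitude scaling down to 0.5. POST applies per-wave amplitude scales
and latency shifts to the template before noise.

**Avoidance sessions.** Bernoulli trials per (session, frequency) cell on a
9–36 kHz quarter-octave grid (9 frequencies), 5 sessions, 8 trials per cell
(≈72 trials/session, matching the task's ~70), baseline avoidance probability
0.85 (trained animals performed ≥75%), with an optional frequency-specific
dip.

What the generators do **not** emulate: cochlear damage and frequency tuning
(FRA), rate adaptation within trains, correlated noise across ABR sweeps
(myogenic artifacts), session-to-session learning drift. Passing tests
therefore demonstrate correctness of the analysis rules under their stated
assumptions, not robustness to every pathology of real recordings.

## Afterdischarge rule

Rates are binned at 2.5 s; trailing partial bins are discarded so every rate
covers a full bin. The "95% confidence interval of the PRE rate" is read as a
**prediction band**: bound = mean + 1.96·SD (ddof = 1) of the PRE bin rates,
because individual POST bins are compared against the variability of
individual PRE bins. A CI-of-the-mean reading (mean + 1.96·SD/√n) would be
exceeded by single noisy bins almost by construction; both readings are
implemented (`mode="prediction_band" | "ci_of_mean"`), prediction band is the
default. A call requires ≥3 consecutive POST bins strictly above the bound
("exceeded" is strict; ties do not count) with the first qualifying run
starting ≤30 s after LDS offset; the onset is that run's left bin edge. The
rule's false-positive rate is whatever the rule produces — the acceptance
suite measures it against a brute-force Monte-Carlo of the identical rule
rather than assuming 5%.

## PSTH and tone metrics

Spikes are assigned to the preceding pip and folded on the cycle; the last
bin is shortened to end exactly at the cycle so spike counts are conserved
(Σ bins × n_pips = spikes within cycles, checked exactly). PSTH bin width
defaults to 0.5 ms (unstated in the source; configurable). Overall rates are
PSTH totals over the full cycle — PRE from all six trains, POST from T1 only.
Onset = left edge of the first bin exceeding spontaneous mean + 2 SD sustained
for ≥2 bins; duration extends that run tolerating single-bin gaps. These
thresholds are conventions (the source defines neither quantity's math) and
are configurable. Validity requires onset > 3.4 ms. A channel is responsive
when the PRE or T1 overall rate exceeds the spontaneous threshold and the LDS
epoch rate exceeds the spontaneous band (`lds_responsive`). Δ is undefined at
PRE = POST = 0 and flagged not-computable rather than coerced.

## ABR processing

Averaging is the pointwise sweep mean. Filtering is a 4th-order Butterworth
band-pass (500–3,000 Hz) run forward-backward (`sosfiltfilt`), i.e.
zero-phase: a symmetric pulse's extremum never shifts, keeping PRE/POST
latencies comparable. The picker finds strict local extrema (plateaus resolve
to their earliest sample) on the **full** waveform — prominences computed on
the windowed segment would be truncated for waves near the window edge — and
keeps candidates inside the 2–14 ms window with prominence ≥5% of the window's
peak-to-peak range (noise-ripple suppression; configurable). Wave V = last
candidate maximum before the window's global minimum; IV…I = preceding maxima
in reverse; VI = first maximum after V's trough; each wave's trough = first
candidate minimum after its peak; waves are absent when candidates run out
(including wave VI when no later minimum exists — flagged rather than
guessed). Peak and trough positions/values are refined by the parabola through
the three samples around each extremum, which keeps amplitudes within
interpolation error of the analytic template at 25 kHz. Manual overrides
replace individual waves, mirroring the original manual-picking workflow.
Thresholds at the range limits are censored (lowest − step/2, highest +
step/2) instead of excluded; a non-monotone detection profile falls back to
the lowest level above which all levels are detected, with a warning.

## Bootstrap correlation

Within a condition, each iteration splits the sweeps into complementary
random halves (⌊n/2⌋ vs. the remainder — the extra sweep joins the
complement), averages each half, band-pass filters the averages, and
correlates them over 2–14 ms at native sampling (no resampling). Across
conditions the split is not fully specified by the source; the default draws
complementary index halves (half the indices average PRE sweeps, the other
half POST sweeps), which is statistically equivalent to independent halves for
independent noise but avoids re-using the same sweep when the two sets share
provenance; `cross_mode="full"` (full average vs. full average) is available.
With a single iteration the SD of the R distribution is reported as 0 by
convention. The three distributions of one recording draw from one shared
seed stream.

## Tinnitus decision rule

The dip frequency is the minimum of the per-frequency mean percentages (ties
break to the lowest frequency, seed-independently). The test sample is that
frequency's per-session percentages; the null value is the grand mean treated
as a fixed constant, computed as the **unweighted mean of per-frequency
means** (robust to unequal trial counts); whether it should exclude the dip
frequency is ambiguous in the source — the default includes it (literal
reading), exclusion is a switch. The t-test is one-sample, lower-tailed,
df = sessions − 1, α = 0.05. Zero variance at the dip is degenerate: equal to
the grand mean → no evidence; strictly below → tinnitus with p reported as 0
and flagged. The min-then-test construction inflates the false-positive rate
far above nominal α; the package surfaces this operating characteristic via
Monte-Carlo comparison instead of "fixing" the rule.

## Statistics layer

The two-sample proportions z uses the pooled standard error, no continuity
correction, and a **two-sided** normal p — the reading consistent with the
published z/p pairs (e.g. z = 0.159 ↔ p = 0.874 matches only 2·Q(|z|)). One of
the published pairs (z = −5.247, p = 1.54e−10) is internally inconsistent
(two-sided p is 1.55e−7, an apparent exponent typo) and is excluded from the
acceptance anchors. One-way ANOVA is delegated to `scipy.stats.f_oneway`,
one-sample t to `scipy.stats.ttest_1samp`, two-way ANOVA to statsmodels OLS +
`anova_lm` with **Type II** sums of squares (appropriate for the unbalanced
cohort sizes; equals Type I on balanced designs); Scheffé post-hoc is
implemented directly — F_pair = (mean difference)²/(MS_within(1/nᵢ+1/nⱼ))
referred to (k−1)·F_{k−1,N−k} — since no installed package provides it. All
delegated routines are verified against from-definition sums-of-squares
oracles in the tests. Degenerate inputs (pooled proportion 0 or 1, zero
within-group variance, constant two-way response, zero-variance t samples)
return flagged results rather than raising mid-pipeline.

## Problem sizes

The test and acceptance suites run the detector's operating characteristic on
2,000 stationary channels (oracle: 20,000 Monte-Carlo replicates on Poisson
bin counts), the bootstrap suppression check on 100 seeded recordings of
1,266 sweeps, the classifier on 1,000 seeded animals (31-frequency grid,
20 trials/cell — a denser grid than the behavioural task's 9, which sharpens
the selection-inflation measurement), and the type-I calibrations on 10,000
replicates. `scripts/acceptance.py` uses smaller cohorts (hundreds of
channels/animals, 20 bootstrap seeds) chosen to keep a full from-scratch run
under a minute while leaving Monte-Carlo error well inside the reported
margins.

## Known limitations

- The peak picker is a rule-based stand-in for manual picking by a blinded
  researcher; the manual-override path exists precisely because automatic
  picks on pathological waveforms (merged waves, wave VI without a trough)
  are absent rather than inferred.
- Generator parameters for afterdischarge magnitude and time course are
  conventions, not estimates — the source gives no distributional
  description.
- The cohort-level drivers plant effect sizes to reproduce qualitative group
  patterns; published channel-level counts do not exist to calibrate them.
- `two_way_anova` with an empty factor cell fits the additive model and flags
  the interaction not-estimable instead of silently dropping cells.
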