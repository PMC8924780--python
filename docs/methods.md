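# Methods

This note documents the models, conventions, and design choices behind
`hrval`, in the order data flow through the pipeline.

## Criterion truth model (synthetic cohorts)

A subject's "true" heart rate over a session is modelled as a
first-order response to an activity protocol: within each activity of
target rate `T` (bpm), HR obeys `dH/dt = (T(t) − H)/τ`, with the
subject's time constant `τ` and continuity across activity boundaries.
With a within-activity target slope the exact solution of this linear
ODE is used; there is no numerical integration. The model is the
simplest one producing the physiologically expected shape — rapid
exponential approach to a new demand level, with subject-specific
inertia. HR outside [30, 220] bpm at any time is rejected as a
parameterization error.

The default 10-activity protocol escalates from rest and sedentary
phases through low- and high-intensity exercise to a recovery rest
(durations 2, 1.5, 1.5, 1.5, 1, 1, 2, 1.5, 1.5, 1.5 minutes; targets
76, 79, 74, 68, 89, 86, 100, 120, 129, 106 bpm). The targets are
typical group-mean rates for these activities in young healthy adults;
they, and the subject-parameter distributions below, are package
defaults that users can override:

* baseline HR ~ Normal(70, 8) truncated to [50, 95] bpm,
* τ ~ Uniform(8, 25) s,
* RR jitter sd ~ Uniform(5, 40) ms.

**Beats.** Beat times are laid down sequentially from t = 0 with
`RR_k = 60/H(t_k)` plus Gaussian jitter (sd = the subject's
`hrv_sd_ms`, truncated so RR > 0.25 s) — a deliberately simple HRV
stand-in with no autocorrelation structure. With zero jitter, `60/RR_k`
equals the trajectory at the beat time by construction.

**Realized HR.** Devices do not observe the idealized trajectory; they
observe the beat process. `RealizedHR` is the piecewise-constant
instantaneous HR a pulse-sensing device sees: at time t, `60/RR` of the
most recently **completed** interval. Two properties motivate this
convention:

* *Shared fine structure.* Criterion and device measurements derive
  from the same beats, so their beat-to-beat fluctuations correlate.
  This is what makes integer-second synchronization well-posed; against
  a smooth trajectory the correlation objective is nearly flat across
  neighbouring lags.
* *No length bias.* Sampling "the interval containing t" favours long
  intervals (an interval is hit with probability proportional to its
  own duration), deflating time-sampled HR by ≈ HR·CV². The
  last-completed interval is instead held for its *successor's*
  duration, independent of its own length, so time-sampled device
  values have the same expectation as the criterion's beat-weighted
  within-second averages.

## ECG synthesis and R-peak detection

Synthetic ECG renders each beat as a sum of five Gaussians
(P, Q, R, S, T; R amplitude 1 mV, width 12 ms) centred on the beat
time, sampled at ≥ 128 Hz (default 256 Hz), plus white noise at a
requested SNR (dB); `snr_db=None` is noise-free. This is a stereotyped
single-lead morphology, sufficient for exercising a QRS detector — it
makes no claim to clinical realism (no morphology variation, baseline
wander, or muscle artefact).

The detector is the classic energy-based chain: band-pass 5–15 Hz
(2nd-order Butterworth, zero-phase), derivative, squaring, 150 ms
moving-window integration, then adaptive signal/noise peak thresholds
(running estimates, threshold = noise + 0.25·(signal − noise)) with a
200 ms refractory period. Peak times are refined to the raw-trace
apex within ±100 ms of the envelope peak. No peak is reported within
250 ms of either trace end. An all-constant trace yields an empty beat
list; rates below 128 Hz are rejected (QRS undersampled).

**RR cleaning.** RR intervals outside the open window (0.25, 3.0) s —
20–240 bpm — are dropped with a logged count. This window is the
automatic stand-in for the manual review a human scorer would apply to
evidently wrong beats.

**1 Hz reduction.** Instantaneous HR samples (one per interval,
timestamped at the interval's end beat) are averaged within each
half-open second `[s, s+1)`. A second containing no sample (HR below
60 bpm) takes the HR of the RR interval spanning that second — the
measurement actually in force during it — located by the second's
midpoint. Seconds covered by neither rule (before the first interval,
after the last, or inside a cleaning gap) are masked invalid.

## Device observation model

A device sample emitted at time t reports
`smooth(realized HR)(t − lag) + bias + noise`, where `smooth` is an
optional trailing moving average (algorithmic inertia), `lag` a clock
plus processing delay, `bias` a systematic offset, and `noise`
per-sample Gaussian. Emission times are either uniform at a configured
rate or sparse with inter-sample gaps uniform in
`[min_interval, max_interval]` seconds. Samples are then thinned by a
dropout probability, and a malfunction window can override values:
`flatline` pins them to a level; `excess` adds a bounded random walk
(step sd 2 bpm, reflected at ±40 bpm of the level) to a grossly
elevated level, mimicking the erratic traces a device with poor skin
contact can produce.

The two reference device archetypes used throughout tests:

* **tracker** — sparse sampling, gaps 1–5 s (training-mode fitness
  trackers), lag 3 s, bias −2 bpm, noise sd 3 bpm;
* **watch** — uniform 25 Hz (smart-watch sensor APIs), lag 7 s,
  bias +4 bpm, noise sd 3 bpm.

The watch archetype is deliberately oversampled rather than exactly
1 Hz: an emission clock exactly aligned with the analysis grid is a
measure-zero coincidence in practice, and it interacts pathologically
with integer-lag estimation (the half-beat content delay of the
realized-HR semantics then falls entirely on one side of the bucket
boundary, shifting the estimated lag by one second). Within-second
averaging of a dense stream centres each bucket's content and removes
the artefact.

## Resampling to 1 Hz

* **Sparse (next-value imputation):** each grid second takes the value
  observed in that second (the last one if several); otherwise the
  *next* available observation's value (backward fill). Trailing
  seconds with no later observation carry the last value forward — the
  only completion that does not extrapolate. Note the direction: most
  pipelines carry the *previous* value forward; this pipeline
  standardizes on next-value imputation for sparse wearable exports, so
  an imputed second always holds the measurement nearest after it.
  Only observations inside the requested span participate; a span with
  no observations yields a fully masked series.
* **Oversampled (averaging):** arithmetic mean per half-open second;
  empty seconds are masked invalid and skipped downstream.

Both rules guarantee every unmasked output value is a convex
combination of observed values.

## Synchronization

Device clocks are distrusted on principle. For each device the pipeline
scans integer lags in ±`max_lag_s` (default 60 s) and picks the lag
maximizing the Pearson correlation over the pairwise-valid overlap,
skipping lags with overlap below `min_overlap` (default 30 s) or zero
variance. Ties break toward the smallest |lag|, then the more negative
lag, making the search deterministic. A raw cross-correlation objective
(`objective="xcorr"`, mean of products) is available; on zero-mean
windows it selects the same lag as the PCC.

Lag estimation runs on the **observed-seconds-only** series
(within-second averages with gaps masked), and the estimated lag is
then applied to the imputation-completed series. Backward fill copies a
*later* observation into earlier seconds, which advances the imputed
series by about half a sampling gap and would drag the correlation peak
one or two seconds early; observed seconds carry the device's actual
timing. One global lag is estimated per device per recording; lags are
whole seconds by construction of the 1 Hz grid.

## Agreement metrics

For paired per-second values (criterion x, device y):

| metric | definition | conventions |
|---|---|---|
| MAE | mean \|y − x\| | bpm |
| MAPE | 100 · mean(\|y − x\| / x) | criterion in the denominator, never the device |
| bias | mean(y − x) | negative = device under-reads |
| LoA | bias ± 1.96 · sd(y − x) | sample sd (n−1); percentile method (2.5/97.5) behind a flag |
| PCC | product-moment correlation | error on zero variance |
| CCC | 2·s_xy / (s_x² + s_y² + (x̄−ȳ)²) | population (1/n) moments, per Lin's original estimator |
| validity | MAPE strictly < 10% | a device exactly at 10% is not valid |

Descriptive means and SDs use the sample sd. The sd-convention split
(sample sd for Bland-Altman and descriptives, population moments inside
CCC) is pinned for exact reproducibility; at study-scale n the
difference is negligible. No confidence intervals are attached — the
report carries point estimates.

`|CCC| ≤ |PCC|` holds on every input, with equality iff means and
variances agree; this is asserted property-style in the tests.

## Reporting and pooling

Activity windows are half-open `[start, end)`, non-overlapping within a
participant, with an optional symmetric trim for slack at activity
boundaries. Exclusion semantics: a (participant, activity) span is
dropped only when its *criterion* data are inadequate; evidently wrong
device data stay in, since such data would also occur in deployment and
dropping them would flatter the device. "Annotated" spans (criterion
beats manually corrected upstream, supplied as a corrected `beats.csv`)
count as included. Participants with every activity excluded vanish;
partially excluded participants keep their remaining spans in both
per-activity and overall pools.

Pooling is second-level by default: all retained seconds across
participants form one pool per (device, activity) and one overall pool
per device, matching a per-second comparison design with a single SD
per cell. A per-participant mode (equal participant weight, metrics
averaged across participants) is available but non-default. The overall
pool includes transition seconds between activities by default
(configurable); with transitions excluded, the overall n equals the sum
of the activity-block n's exactly.

The default cohort exclusion scenario ships a 23-participant status
grid — three participants fully excluded, two losing the
high-intensity activities, one losing the final rest, plus scattered
annotated spans — so exclusion bookkeeping (20 of 23 retained) is
reproducible end to end.

## Numerical and validation choices

* All timestamps are seconds from recording start; buckets are
  half-open `[s, s+1)`.
* Every synthetic output is a pure function of (parameters, seed);
  per-subject and per-device seeds derive from a master seed via
  `numpy.random.SeedSequence` spawning.
* Cohort-level acceptance checks compare recovered device bias against
  the configured bias with tolerance `3·noise_sd/√n_eff`, where
  `n_eff` is the number of *independent* device observations in the
  pool: for sparse devices roughly two-thirds of grid seconds are
  imputation copies and carry no new information, so the paired-second
  count would overstate the estimator's precision.
* A small (< 0.1 bpm at default HRV levels) methodological offset
  remains between recovered and configured bias: the criterion's
  equal-weight per-second averaging slightly down-weights short RR
  intervals (inspection bias of averaging ratios within buckets before
  pooling buckets). This is a property of the measurement chain itself,
  not of the simulator, and is absorbed by the tolerance above.

## What the generator does and does not emulate

The synthetic cohort reproduces the *structure* of a device-validation
study — protocol-driven HR dynamics, beat-level variability, device
lag/bias/noise/sampling patterns, dropout, gross malfunctions, and
exclusion bookkeeping. It does not model PPG waveforms or their failure
physics (motion artefact, skin tone, perfusion), HRV autocorrelation,
ectopic beats, ECG morphology pathology, or device firmware filtering
beyond a moving average. Passing tests therefore demonstrate that the
pipeline's statistics, synchronization and bookkeeping are correct and
recover known parameters under realistic sampling conditions — not that
any physical device meets a validity threshold.

## Known limitations

* The lag search is integer-second; sub-second alignment is out of
  scope, and device content genuinely sits at sub-second offsets
  relative to bucket centres.
* The RR plausibility window and the empty-second fill rule are fixed
  conventions standing in for manual criterion review; pipelines with
  trusted corrected beats should supply them directly.
* Sensitivity analysis re-runs aggregation on already-processed
  participants; it does not re-estimate lags, which are per-participant
  and unaffected by exclusions.
* `MetricBlock` rounding in the CSV report (3 decimals for metrics,
  2 for bpm summaries) is presentational; the JSON report carries full
  precision.
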