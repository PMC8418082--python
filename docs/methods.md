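# Methods

This note documents the statistical models, algorithms, parameter choices
and limitations of `seizeval`.

## Time conventions and domain model

All timestamps are ISO 8601 UTC; all intervals are half-open
`[start, end)`. An alarm raised exactly at a seizure offset is therefore
*not* a true positive, and boundary alarms can never be double counted
between adjacent intervals. Durations are kept in seconds and converted
to hours only when a rate is reported.

A `RecordingSession` is one patient's monitored period: disjoint wear
intervals, device alarms (validated to lie inside wear time — a data
error here is raised, never silently dropped), and the patient's
consensus seizures. Ages 6–20 inclusive are pediatric, 21+ adult; ages
below 6 are outside the device indication and rejected.

## Adjudication (2-of-3 majority rule)

Three reviewers annotate seizures independently. Annotations of the same
convulsive type (GTC or FBTC) group by transitive closure of any positive
temporal overlap; a group becomes a consensus seizure when it contains at
least `min_supporting` (default 2) distinct reviewers. Consensus
onset/offset is the element-wise median of the supporting annotations
(with three reviewers the median is the middle value; with two it is the
midpoint); an `EARLIEST` pooling rule is available. Whether reviewers
must also agree on the *type* (rather than just presence) is a config
switch (`match_types`, default on); with it off, the type is decided by a
2-of-3 majority within the overlap group. Non-convulsive annotations are
carried but never produce consensus events. Overlapping consensus events
of different types — possible only in contrived configurations — are
resolved in favor of the earlier onset with a warning, keeping the output
sorted and disjoint.

## Alarm scoring

A consensus seizure is detected iff at least one alarm of the evaluated
operating mode falls inside its clinical interval; the latency is onset
to the first such alarm. Any alarm in no consensus seizure is exactly one
false alarm; extra alarms inside an already detected seizure are
absorbed, which keeps the detected count and the false-alarm count
disjoint totals. Pooled sensitivity is detections over events; FAR is
`24 * FA / hours`. Both the mean/SD and the median of latencies are
reported, since monitoring studies quote both summaries.

Stratification is two-axis. Age strata partition sessions. Rest strata
partition *events within sessions*: a seizure belongs to the rest stratum
iff its clinical onset lies in a detected rest interval (onset governs
alerting utility), a false alarm by its timestamp, and exposure is the
overlap of wear time with rest intervals. Detection status is decided
globally and then assigned, so stratum totals always sum to the overall
totals. For per-patient hour summaries both the pooled ratio
(total hours / patients) and the mean of per-patient values are
available, since the two differ on heterogeneous cohorts.

## Clustered inference

Detection outcomes of seizures from the same patient are correlated.
The intraclass correlation is estimated by the one-way ANOVA (Fleiss)
estimator on the per-event binary indicators grouped by patient, with
cluster-size weighting `n0 = (N - sum(m_i^2)/N) / (k - 1)`, clamped to
[0, 1] and defined as 0 when every cluster has one event or the
between-cluster mean square does not exceed the within-cluster one (this
also covers the degenerate all-detected case, where both mean squares
vanish). The design effect `DE = 1 + (m_bar - 1) rho` (unweighted mean
cluster size over seizing patients) deflates the counts to effective
values `x/DE` of `n/DE`; the cluster-corrected sensitivity is the 95%
Wilson score midpoint on the effective counts and its interval the Wilson
interval there. With `DE = 1` this is bitwise identical to the plain
Wilson computation; with `DE > 1` the interval is never narrower. The
midpoint is deliberately below the maximum-likelihood proportion near 1 —
the correction removes the inflation that pooling clustered events
produces.

Precision is reported as the MLE `TP/(TP+FA)` with Wilson bounds. When no
false alarms were observed the MLE is exactly 1, so the estimate switches
to Laplace's rule of succession `(s+1)/(n+2)` and the interval to the
Wilson interval on the Laplace-adjusted counts — a conservative
convention for all-success runs at small n.

The FAR interval is a patient-level percentile bootstrap: sessions are
resampled with replacement (same cohort size), the pooled FAR recomputed
per replicate, and the 2.5th/97.5th percentiles reported; 100,000
replicates by default (reduced in tests), chunked to bound memory, and
deterministic given the seed. A single-session cohort yields a flagged
degenerate `[point, point]` interval. Percentile intervals on skewed
rate distributions undercover mildly at n in the low hundreds; the
package's own coverage test measures ~93% at nominal 95% under strong
(gamma shape 0.5) patient heterogeneity, which is a property of the
method, not a defect of the implementation.

Group comparisons: (1) FAR — conditional on the total count
`N = FA1 + FA2`, the group-1 count is Binomial(N, T1/(T1+T2)) under the
null of equal rates; the default p-value is a continuity-corrected normal
approximation, with a central exact binomial option (twice the smaller
tail). The two agree to ~0.02 when `N pi (1-pi) >= 10`; the residual gap
at large two-sided p reflects the discreteness of the exact distribution.
(2) cSensitivity — the difference of the two corrected estimates with
variance the sum of binomial variances at the Wilson midpoints over the
effective (DE-deflated) denominators, tested against a normal reference.
Using midpoint-based variances avoids the zero-variance breakdown when
one group detects every event; when *both* groups sit at the same
boundary proportion the test is flagged degenerate and returns p = 1.

Sample-size planning inverts the same machinery: the smallest number of
seizing patients whose cluster-corrected Wilson interval at the expected
sensitivity has at most the target half-width, found by direct scan — it
is monotone in the half-width and in the ICC by construction. The ICC to
assume is an explicit input; the package does not guess one.

## Curves for a monitoring stream

A continuous recording has no natural count of negative events, so
specificity is defined against pseudo-negatives: the non-seizure time is
tiled into `floor(non-seizure seconds / mean CS duration)` slices
(pooled across the cohort by default). For threshold sweeps the package
uses event-level counts — a labeled event is detected at threshold t iff
its maximum window score reaches t, and a false alarm is a negative slot
whose maximum score reaches t — which makes sensitivity, FAR and
specificity non-increasing in the threshold by construction. (Alarm
streams shaped by the refractory rule are used for operating-point
scoring, not for curves: a refractory period can suppress a later alarm
and break monotonicity.) Per-point intervals are Wilson for the
proportion-like metrics and the Poisson normal approximation
`24 (FA ± z sqrt(FA)) / hours` for the FAR; bands are pointwise, not
simultaneous. The default grid is 101 evenly spaced thresholds.

## Rest detection

The tri-axial magnitude is band-pass filtered (Butterworth order 3,
0.25–3 Hz, zero-phase so onset/offset times are not biased), activity
counts are upward crossings of 0.02 g accumulated over 30-s epochs, and a
centered 30-min moving average is compared to a count threshold (default
10 counts/epoch): rest begins when the average falls below it and ends
when it rises above. Rest periods less than 2 h apart are merged,
treating the gap as a rest interruption (the merged span, including the
gap, counts as rest). The band corners, crossing threshold and count
threshold are not published for the production algorithm this emulates;
the defaults here were set so that the synthetic generator's nightly
sleep blocks are recovered, and all three are config-exposed. Detected
rest approximates sleep plus long quiet wakefulness; no sleep staging is
attempted, and reproducing any particular cohort's rest fraction is a
calibration exercise rather than an exact target.

## Surrogate detector

The production classifier (40 proprietary features, pre-trained model) is
not reproduced; the surrogate implements only the published architecture
so the pipeline can run end to end: 10-s windows with 75% overlap
(2.5-s stride; a window's detection time is its end, so latencies are
non-negative and stride-quantized), a per-window probability, and a
thresholded decision rule with a refractory period (default 180 s)
preventing alarm trains. The score is a logistic combination of
clonic-band (2–6 Hz) RMS of the per-axis band-filtered acceleration
(per-axis, because the vector magnitude rectifies oscillations to twice
their frequency and hides motion orthogonal to gravity), a rhythmicity
score, and the rectified EDA slope. Rhythmicity is the local regularity
of upward zero-crossing intervals (`1 - 3 *` mean absolute successive
gap difference over the mean gap): it is high for coherent oscillations
even when the frequency drifts as clonic jerks slow, and low for noise or
a phase-scrambled burst with an identical power spectrum — i.e., it
depends on phase, which a spectral feature cannot. The weights were fixed
so that flat input scores below 0.1 and an injected clonic burst with an
EDA surge above 0.9, with the score strictly increasing in clonic-band
energy. The two operating modes are two thresholds (high-sensitivity
default 0.5, high-specificity 0.85); with a per-mode refractory rule,
timestamp-level subset nesting between modes is not a theorem, so the
nesting guarantee tested is the meaningful one: the stricter mode never
detects more events nor raises more false alarms on the same record.
Absolute sensitivity/FAR values of the surrogate characterize the
surrogate, not any production device.

## Synthetic cohorts

The event-level generator draws, per patient: wear hours (lognormal,
mean 68 h, sigma 0.5, floored at 6 h); seizure count (zero with
probability 1 - 24%, else zero-truncated geometric with mean ~1.8);
a patient-level detection probability from a Beta with mean 0.98 and
ICC `1/(alpha+beta+1)` (default 0.05), applied Bernoulli per event;
false-alarm counts Poisson with a Gamma-mixed rate (mean 0.83 per 24 h,
shape 0.5 — about half the patients experience none, mirroring the
heavy patient heterogeneity such studies report); nightly rest blocks
totalling ~38.8% of wear; seizure durations truncated-normal 84.56 ± 34.57 s
and alarm latencies truncated-normal 37 ± 21 s clipped inside the event.
Alarms of the high-specificity mode are a thinned subset of the
high-sensitivity alarms, so threshold nesting holds by construction.
These defaults encode the structure of a 152-patient multi-center EMU
test cohort and are the package's fixed study conditions, not tuning
knobs. The signal generator is decoupled (statistics tests never pay
waveform-synthesis cost) and injects clonic motifs, movement artifacts
and post-ictal EDA surges over a rest/active schedule.

What the generators do *not* emulate: real inter-device differences,
off-wrist gaps inside wear intervals, non-convulsive seizures, circadian
seizure timing, or physiological EDA morphology beyond a tonic drift
plus phasic surge. Passing tests therefore demonstrate the correctness
and calibration of the *evaluation machinery* under the assumed
statistical structure, not field performance of any detector.

## Numerical choices and degenerate inputs

- Wilson computations accept non-integer effective counts; `n = 0`
  raises; zero-success lower bounds clamp at 0 and all proportion
  intervals clamp to [0, 1].
- Statistics on empty denominators (no seizures, no detections, no
  alerts, zero hours) raise `UndefinedResultError` rather than returning
  NaN; a single detection reports SD 0 with a flag.
- Rendered tables round half-to-even at 2 decimals, and only at render
  time; reports are byte-identical across reruns with the same config
  and seed.
- Bootstrap and generators use `numpy.random.default_rng` seeded
  explicitly; no global RNG state is touched.
- Problem sizes used by the test suite (e.g. bootstrap B = 5,000 over
  100 replicate cohorts, ICC recovery at ~300 clusters, 1,000
  oracle-equivalence sessions) were chosen to give stable Monte-Carlo
  margins at interactive runtimes.

## Known limitations

- The ANOVA ICC on binary data is biased downward in small, unbalanced
  cohorts; recovery is guaranteed only to ±0.1 at a few hundred clusters.
- The cluster-corrected Wilson construction applies one pooled design
  effect; it does not model per-patient detection probabilities directly
  (no GEE/Bayesian alternatives are provided).
- Rest detection thresholds are calibration parameters; on real
  actigraphy they require re-tuning against a validated reference.
- The percentile bootstrap interval, per its construction, can undercover
  slightly for strongly skewed false-alarm distributions.
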