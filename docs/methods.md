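# Methods

This note documents the models, statistics, and design choices behind
`ildpipe`: a pipeline from raw two-photon somatic fluorescence traces to
interaural level difference (ILD) tuning, binaural interaction categories,
opponent-channel population decoding, and spatial-organization statistics,
together with the synthetic-experiment generator that provides ground
truth for every stage.

## Signal model and response statistic

Each neuron's raw trace F(t) is high-pass filtered at 0.02 Hz — realized
as subtraction of a zero-phase moving average spanning one cut-off period,
with the trace mean restored; zero-phase matters because responses are
peak-based. The baseline F0 is the median of the samples whose rank
percentile lies in [10, 70] (rank bounds ceil(0.10 n)..floor(0.70 n) on
the sorted trace), so the brightest 30% of frames — calcium transients —
never enter the baseline. ΔF/F0 = (F − F0)/F0, and neuropil contamination
is removed on the ΔF/F scale as corrected = cell − r × neuropil with
r = 0.6.

The response to one stimulus presentation is the peak ΔF/F0 in the 14
frames from stimulus onset (onset frame included) minus the peak in the
14 frames immediately before onset (~500 ms windows at ~30 Hz). The
alternative window-sum statistic is available via
`RunConfig(response_stat="sum")`. Subtracting the pre-window peak controls
for local fluctuations, but it has two consequences worth knowing:

* **Inter-trial carryover.** With a GCaMP6m-like decay (~600 ms) and
  0.65 Hz presentation, the previous trial's transient has not fully
  decayed by the pre-window. The pre-window peak catches the early
  (larger) part of that tail while the post-window peak rides its later
  (smaller) part, so every measured response is reduced by approximately
  0.175 × (previous transient amplitude) — a near-constant offset under a
  randomized trial order. We verified this by regressing measured
  responses on planted rates (residuals < 2% of the response scale).
  Because the binaural interaction index (BII) is a ratio of such
  responses, the offset inflates mid-range BIIs.
* **Conservatism under spontaneous activity.** On silent traces (white
  measurement noise only) the one-tailed paired t-test is calibrated
  (~1.0% rejections at alpha 0.01 over >70,000 null condition tests).
  When spontaneous calcium transients are added (1–5 Hz baseline rate),
  window-max differences become platykurtic and the test turns
  conservative (~0.6–0.7%). The type-I calibration scenario therefore
  uses silent null neurons — the natural no-signal null for a
  responsiveness test — and this conservatism should be kept in mind when
  interpreting responsive fractions in spontaneously active tissue.

## Per-neuron statistics

* Responsiveness: one-tailed paired t-test (post > pre window peak) per
  condition (each ILD, each monaural side, each tone frequency), alpha
  0.01; a neuron is noise- (tone-) responsive if any condition is
  significant. Zero-variance difference vectors return p = 1 (or p = 0
  for a constant positive shift) rather than NaN so deterministic
  simulations classify cleanly.
* ILD sensitivity: one-way fixed-effects ANOVA over the 7 ILDs,
  separately per ABL, alpha 0.05, applied to responsive neurons.
* Peak ILD: argmax of the trial-averaged curve, ties broken toward the
  most contralateral ILD. Slopes: differences between contiguous ILD
  means (6 per curve); the steepest slope is the maximum absolute slope,
  reported at the midpoint of its ILD pair.
* Weighted ILD (centroid): sum(ILD_i · r_i) / sum(r_i) over the
  trial-averaged responses. The denominator is the summed response, the
  standard response-weighted centroid; a denominator of summed ILDs would
  be identically zero for the symmetric −30..+30 dB set. Negative mean
  responses are floored at zero first (configurable) so suppression
  cannot push the centroid outside the tested range.
* Frequency sensitivity: two-way fixed-effects ANOVA (frequency × level,
  with interaction) on tone responses, alpha 0.05 on the frequency main
  effect. Balanced grids use closed-form sums of squares (vectorized;
  cross-checked against statsmodels `anova_lm`); unbalanced grids fall
  back to statsmodels type-II.
* Best frequency: argmax over frequencies of the level-averaged FRA
  (ties toward the lowest frequency); the BF is "clear" only if the mean
  response there exceeds the prestimulus mean by 3 prestimulus SDs, both
  computed from pre-window peaks across the neuron's tone trials. The
  3-point FRA smoothing (edge-truncated, renormalized kernel) is for
  display only — statistics use the unsmoothed matrix. Because the
  prestimulus statistics are window *maxima*, spontaneous transients
  inflate their SD and the 3-SD rule becomes quite conservative when
  evoked responses are modest relative to spontaneous activity; with the
  generator's default tone amplitudes and 1–4 Hz baseline rates most
  recovered BFs are flagged "no clear BF" even though the BF itself is
  recovered accurately (BF-recovery scenarios gate on frequency
  sensitivity, the precondition of the BF computation).
* Tonotopic axis: Pearson correlation between log2(BF) and the projected
  position, recomputed while rotating the projection axis in 1° steps
  through 360°; the angle of strongest negative correlation is the
  gradient orientation. The profile satisfies r(θ) = −r(θ+180°) exactly.
  **Limitation:** under anisotropic neuron sampling (e.g., a 4:1 field)
  the argmin is biased toward the long axis whenever BF noise is present,
  because the rotation maximizes covariance weighted by positional
  variance; recovery tests use a 2:1 region where the bias is negligible.
* Field BF variation: SD (ddof 1) of log2(BF), in octaves.

## Binaural categorization

At each ABL, three one-tailed paired t-tests (contralateral monaural,
ipsilateral monaural, diotic) assign the monaural class: EO (contra
only), OE (ipsi only), EE (both), OO/F (diotic only), else unresponsive.
For EO/OE/EE, BII = diotic / (contra + ipsi) on trial-mean responses with
negatives floored at zero. BII > 1.2 → facilitation (/F), BII < 0.8 →
inhibition (/I), the closed band [0.8, 1.2] → no interaction (/N —
boundary values deliberately fall in the N band). EE neurons with
BII < 0.8 split into EE/O ("occlusion": diotic > 80% of the dominant
ear) and EE/I otherwise; EE/I is reported separately so category totals
remain auditable.

## Opponent-channel decoder

Single-trial responses to binaural noise are pooled across ABLs. Each
noise-responsive neuron is regressed (OLS) on signed ILD; a significant
slope (p < 0.05) makes it "monotonic", joining the contralateral
(negative slope) or ipsilateral channel. Responses are normalized by the
maximum of the neuron's trial-averaged ILD curve; the population opponent
value of a trial is the mean normalized response of the contra channel
minus that of the ipsi channel. A trial is decoded as the ILD whose
reference opponent value — the mean over all *other* trials
(leave-one-out) — is nearest; ties break toward the smaller |ILD|.
Accuracy is the mean unsigned error (MUE) in dB, also normalized by the
maximal possible error, taken as 60 dB (|−30 − (+30)|); both are
reported. Random subpopulations of each size are drawn without
replacement from the monotonic pool (1000 resamples by default,
configurable; the calibration suite uses 100) and the MUE averaged. A
uniform random guesser on this 7-ILD task has MUE 160/7 ≈ 22.9 dB.

## Correlations and spatial statistics

Noise correlation: Pearson correlation of trial responses after
subtracting each neuron's mean response to the presented stimulus. Signal
correlation: correlation of the two condition-mean tuning vectors minus
the pair's noise correlation — so signal + noise equals the raw
tuning-vector correlation by construction (the subtraction form can
therefore stray slightly outside [−1, 1] by the sampling error of the
noise term). Both are defined only within simultaneously imaged fields.
Shuffle nulls redraw each neuron's responses with replacement — within
condition for noise, across all trials for signal — 1000 times, and the
observed correlations are compared to the null means by paired t-test
across pairs (alpha 0.01). Correlation-versus-distance relationships are
OLS fits against rostro-caudal and dorso-ventral distance separately.

Spatial clustering of a tuning parameter (weighted ILD, BF in octaves,
or the EO/I / EO/F / OO/F categories coded −1/0/+1) is tested per
experiment: the mean absolute preference difference over local pairs
(≤150 µm in the 2D cortical plane; 100/200/250 µm configurable) is
compared with the fifth percentile of 1000 bootstrap means over equally
many distant (>150 µm) pairs — drawn without replacement within a draw
when enough distant pairs exist, with replacement otherwise. Significance
requires the observed mean to fall strictly below the percentile. The ILD
and category tests include only neurons with a clear BF ≥ 10 kHz, where
mouse ILD cues are physically meaningful.

**Known limitation.** This bootstrap is anti-conservative whenever local
pairs share neurons: the observed local mean then has neuron-level
dependence that random distant-pair samples do not replicate, and
without-replacement draws further shrink the null spread by the
finite-population factor. At realistic cortical density (30 analyzed
neurons over 1000 × 250 µm) the measured false-positive rate is ~9–12%
at nominal alpha 0.05; it approaches 5% only when local pairs are mostly
disjoint (sparse fields). Power for clearly clustered maps is unaffected
(100% in the planted-cluster scenario below). Negative clustering
findings obtained with this test are therefore conservative; positive
ones should be interpreted with the inflated alpha in mind.

## Synthetic experiments

The generator emulates the stimulus design the analysis expects: 7 ILDs
(−30..+30 dB, 10 dB steps; negative = contralateral-louder) × 2–3 ABLs ×
12 repetitions of 100 ms noise bursts plus monaural bursts per ear, and
diotic tones at 18 log-spaced frequencies (1.9–50 kHz, ~0.277-octave
steps — 18 steps over that range force ~0.27 octaves) × 4 levels × 10
repetitions, presented at 0.65 Hz on a 30 Hz frame clock: 46 frames per
trial, stimulus spanning 3 frames, noise and tone blocks contiguous with
a seeded pseudorandom order within block (ABLs interleave with ILDs
within the noise block).

Per neuron, the expected rate is baseline + gain × ILD-tuning ×
ABL-gain for noise (sigmoidal contra/ipsi-monotonic, Gaussian peaked, or
flat tuning families), and a Gaussian-in-log-frequency profile that
widens and grows with level for tones (V-shaped FRA). Spikes are Poisson
per frame; a deterministic mode replaces counts with their expectation
(leaving only measurement noise), and a fully noiseless mode also drops
drift, white noise, and the shared latent. Spike trains are convolved
with a double-exponential kernel (50 ms rise, 600 ms decay — GCaMP6m-
like; configurable) and scaled into ΔF/F (0.10 per spike). Traces add a
slow sinusoidal drift (3% of F0, 120 s period), white noise (SD 0.04
ΔF/F per frame), and a field-common per-trial latent: a kernel-shaped
transient at stimulus onset whose amplitude (SD 0.1 ΔF/F) is shared
across the field and weighted by each neuron's `noise_share`. A constant
per-trial offset would cancel in the post-minus-pre statistic; the
onset-locked transient is what actually induces trial-level noise
correlations. The neuropil channel carries the field-average signal, and
a fraction r = 0.6 of it contaminates each measured cell trace. All
randomness derives from one root seed through named substreams, so a
seed reproduces an experiment bit-identically.

Binaural classes are planted in *measured-response* space: the target
monaural-to-diotic ratios (e.g., EE/N at BII 1.0, EO/I at 0.5, EE/O at
contra 1.0 / ipsi 0.9 / diotic 1.0 — a 20% occlusion margin) are
converted to firing-rate ratios by adding back the expected carryover
offset, computed exactly from a deterministic periodic transient train
(`carryover_bias_fraction`). Without this compensation, a planted EE/N
neuron would be *measured* at BII ≈ 1.25 and misclassified as
facilitation — by the pipeline's own deterministic bias, not by noise.

What the generator does **not** emulate: motion artifacts and
registration errors, ROI segmentation errors and spillover between
neighboring somata, nonstationary baselines beyond sinusoidal drift,
indicator saturation, and frequency-dependent acoustics. Passing tests
therefore certify the analysis code under the stated statistical model,
not the imaging preprocessing upstream of it.

## Calibration scenarios and problem sizes

The calibration suite (`ildpipe.calibration`, exercised by the test
suite and `scripts/acceptance.py`) uses the following scenarios, chosen
to emulate the target experiment at desk scale:

* type-I calibration: 3500 silent neurons (73,500 t-test conditions,
  10,500 one-way ANOVAs) plus 10,000 null 18×4×10 response grids for the
  two-way ANOVA;
* parameter recovery: 300-neuron experiments — full Poisson noise for
  peak-ILD recovery (±10 dB at 60 dB ABL among detected tuned neurons)
  and deterministic spiking (measurement noise ≈ response/10 at the FRA
  peak) for exact BF recovery on a grid-snapped BF population;
* class recovery: fully deterministic, one untuned neuron per class with
  flat ABL gain (so the carryover compensation is exact at every ABL);
* decoder: population sizes 10–300, 100 resamples each; the noiseless
  separability check uses mirrored step pairs tiling the six inter-ILD
  thresholds, which make the opponent value strictly monotonic in ILD;
* cluster test: 400 spatially random fields (false-positive rate) and
  200 fields with two planted ILD clusters 400 µm apart, 2 dB
  within-cluster spread, 30 dB gap (power), 30 neurons per field over
  1000 × 250 µm, 1000 bootstrap draws;
* tonotopy: 200 simulations, 120 neurons over 500 × 250 µm, 4-octave
  gradient span at 37°, 0.3-octave BF jitter (together with the gradient
  this yields within-250-µm BF scatter comparable to reported cortical imaging fields).

## Degenerate inputs and tie rules

Constant traces return their own value as F0; F0 ≤ 0 aborts that neuron
with an exclusion log entry. All-equal response groups make the ANOVA F
undefined — reported as NaN, not significant. A nonpositive summed
response leaves the centroid undefined (flagged). Ties: peak ILD → most
contralateral; BF → lowest frequency; decoder reference → smaller |ILD|;
cluster-test percentile ties → not significant. Neurons whose maximum
trial-averaged response is nonpositive cannot be max-normalized and are
excluded from the PCA matrix and the decoder (logged).
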