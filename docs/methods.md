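# Methods

## Scope and model of the data

`hrvdcan` implements the signal-processing and statistical pipeline used to
look for early diabetic cardiovascular autonomic neuropathy (DCAN) in
short laboratory recordings: a single-lead ECG sampled at ~1000 Hz,
beat-to-beat systolic/diastolic finger pressure, a 16-min supine rest
condition (SUP) and a 10-min 70° head-up tilt (HUT), the traditional
autonomic-test battery, and the SCOPA-AUT symptom questionnaire.  The
clinical premise is that early DCAN depresses vagal heart-rate modulation
in conditions of high vagal tone, so vagally mediated HRV indexes measured
supine discriminate patients from controls before the traditional tests
do.

All analysis operates on the NN (normal-to-normal) interval series — RR
intervals between sinus beats with ectopy and artifacts removed.  Times
are seconds from record start, intervals milliseconds, pressures mmHg,
and every analysis window is half-open `[start, end)`.

## Beat detection and NN cleaning

R peaks are detected on the smoothed squared derivative of the ECG with an
adaptive threshold (`threshold_factor` × the local 3-s running maximum of
the feature signal, default 0.3) and a refractory period (default 0.25 s).
Each candidate is moved to the local ECG maximum and refined by fitting a
parabola to the three samples around it, giving sub-sample R-peak times
and amplitudes.  The detector assumes upright R waves; on noise-free
synthetic ECG it attains recall = precision = 1 between 40 and 180 bpm
with timing errors far below one sample.

Ectopy/artifact rejection must be deterministic to be reproducible, so the
interactive review step common in clinical practice is replaced by a rule
plus an override list: an RR interval is non-NN when shorter than 0.75× or
longer than 1.5× the running median of the last 11 accepted intervals
(thresholds configurable — they are this package's defaults, not values
asserted by any particular study); a short interval marks its terminating
beat premature, and every interval adjacent to a non-normal beat is
excluded.  A manual-override mapping (beat index → label) reproduces any
reviewer's decisions exactly.  Gaps left by exclusions are recorded as
contiguity flags; successive-difference statistics skip pairs spanning a
gap, while spectral resampling bridges gaps by linear interpolation
("interpolating possibly missing beats").

## Time domain

pNN50+ / pNN50− are the percentages of contiguous successive pairs
differing by at least +50 / −50 ms (inclusive comparison; denominator =
number of valid pairs, which keeps the statistic well-defined across
gaps).  RMSSD is the RMS of the same differences.  SDNN index is the mean
of sample standard deviations (n−1 denominator) over 5-min windows slid by
60 s (step configurable); windows with fewer than 30 intervals are skipped
with a warning.

## Frequency domain

The tachogram assigns each NN value to its interval onset and is linearly
interpolated onto a uniform 5 Hz grid.  Spectra are Welch periodograms
with 120-s Hann windows, 50% overlap, and per-segment *mean* removal only
— linear detrending would eat into the VLF band, which starts at 0.005 Hz.
An optional frequency-domain moving-average ("wideband smoothing") is ON
by default with a 0.01 Hz bandwidth; the bandwidth of the original
technique is not recoverable, so it is configurable, and the default is
narrow enough not to blur band edges (at the default resolution of
1/120 Hz it spans a single bin).

Band powers integrate the one-sided density with the trapezoid rule over
VLF 0.005–0.04, LF 0.04–0.15, HF 0.15–0.40, and total 0–0.5 Hz, with PSD
values interpolated at the exact band edges.  The total power excludes the
DC bin by replacing the f = 0 value with the first interior bin, which
discards mean leakage without shrinking the integration interval (a flat
1000 ms²/Hz spectrum integrates to exactly 500 ms²).  LF/HF is reported
as NaN, with a warning, when HF is zero.  Parseval holds to within 2% on
stationary series and a single in-band oscillation of amplitude A returns
band power A²/2 within 5%.

## Complexity domain

**Sample entropy.** SampEn(m, r) = −ln(A/B), where B counts template
pairs of length m within Chebyshev tolerance r (ties |d| = r count as
matches, self-matches excluded, the first N−m templates used at both
lengths) and A the pairs still matching at length m+1.  Defaults m = 1,
r = 15% of the series SD.  The production implementation counts matches in
row blocks so no full n×n matrix is materialised; tests pin it, exactly,
to an independent brute-force pair-counting oracle, and for iid Gaussian
data it reproduces the analytic value −ln(2Φ(r/√2)−1) ≈ 2.47 at r = 0.15.

**Multiscale entropy.** MSE(τ) applies SampEn to coarse-grained series at
integer beat scales; the default coarse-graining is an *overlapping*
moving average with the tolerance fixed at 15% of the SD of the
*original* series, so entropy changes across scales reflect genuine loss
of variability rather than renormalisation.  The classic non-overlapping,
m = 2 variant is available as the `costa-replication` preset for
cross-study comparison.  Beat scale s maps to time as τ = s × mean NN;
band summaries average MSE(τ) over 2.5 ≤ τ < 6.7 s (MSE_HF) and
6.7 ≤ τ < 25 s (MSE_LF).

**Multiscale DFA.** The mean-removed NN series is integrated; box sizes
are log-spaced at 8 per octave from 4 beats to n/8; each box is detrended
with an order-1 polynomial (standard DFA-1; the order is configurable) and
F(n) is the RMS residual.  The scale-dependent coefficient α(τ) is the
local slope of log F vs log n by centred finite differences (one-sided at
the edges), with τ = n × mean NN.  α_Short averages 5 ≤ τ ≤ 11 s, α_Long
averages 17 < τ < 61 s (band edges as conventionally printed).  A global
exponent estimator (`dfa_alpha`) fits one least-squares slope over boxes
of ≥ 10 samples — below that, order-1 detrending visibly biases F(n) for
uncorrelated series — and recovers α within ±0.1 for white noise (0.5),
Brownian motion (1.5) and 1/f^β surrogates with α = (β+1)/2.

## Baroreflex sensitivity

BRS uses the transfer-function method over the LF band: gain(f) =
|S_xy(f)| / S_xx(f) with x = 5-Hz-resampled SBP and y = the tachogram,
estimated with the same Welch settings, and BRS = the unweighted mean of
the gain over 0.04–0.15 Hz, in ms/mmHg.  Of the two readings of the
denominator ("root-squared" pressure spectrum), only S_xx is dimensionally
consistent with ms/mmHg, so that is implemented.  Because the modulus
discards phase, coupling delays up to ~2 s do not bias the gain.  The
magnitude-squared coherency |S_xy|²/(S_xx·S_yy) averaged over LF
quantifies coupling strength; it requires at least 3 Welch segments (one
segment's coherency is identically 1), and its no-coupling bias floor is
≈ 1/K for K segments.

## Autonomic tests and questionnaires

All test outcomes are extremum-minus-baseline contrasts over annotated
windows (the baseline is summarised by its mean — a single "baseline
value"): deep-breathing ΔHR (max−min heart rate, HR = 60000/NN), Valsalva
ratio (largest over three maneuvers of longest phase-IV RR over shortest
phase-II RR), handgrip ΔDBP, HUT 30:15 ratio (windows default to
post-tilt beats 25–35 and 10–20; "around" the 30th/15th beat has no
canonical width, so both windows are configurable), HUT ΔSBP (minimum in
the first 3 min of tilt, typically negative, not clamped), and
cold-pressor ΔDBP/ΔHR over a 90-s immersion window.  Ewing's score sums
0/0.5/1 (normal/borderline/abnormal) over the five battery tests; the
cut-offs ship as an editable YAML-able table whose defaults are the
classic Ewing values (ΔHR 15/10 bpm, Valsalva 1.21/1.10, 30:15 1.04/1.00,
orthostatic ΔSBP −10/−30 mmHg, handgrip ΔDBP 16/10 mmHg).  SCOPA-AUT is
scored as a percentage of the maximum achievable score (23 items,
per-item maximum 3 by default); missing items are prorated out of both
numerator and denominator unless strict mode is requested.

## Statistics

AUC is computed through the Mann-Whitney identity with midrank ties; the
`case_low` direction (patients score low) is the default for HRV indexes,
`case_high` for symptom scores.  The standard error defaults to
Hanley-McNeil with DeLong as an option (reports rarely name their
estimator; both are standard, one has to be the default), and the p-value
is the two-sided normal approximation of U against AUC = 0.5.  The Youden
cut-off maximises sensitivity + specificity − 1 over midpoints between
adjacent pooled values, breaking ties toward higher specificity, and is
suppressed when the AUC is not significant at the configured α = 0.05.  A
Gaussian-model utility converts a cut-off into model-based sensitivity
Φ((c−μ)/σ).  Pointwise profile comparisons run a two-sided Mann-Whitney
test per frequency/scale (exact distribution below 8 subjects per group)
with 5% and 1% masks and optional Benjamini-Hochberg adjustment;
`fdr_adjust` delegates to statsmodels.  Mixed-effects modelling is
deliberately out of scope: the pipeline emits a tidy long-format cohort
table ready for any external mixed-model routine.

## Synthetic data: what it emulates and what it does not

The generators provide ground truth for every stage:

* **Tachograms** are built in the beat domain: VLF/LF/HF oscillators plus
  1/f^β Gaussian background (β default 1, matching the ~0.8–1.1
  self-similarity of real supine tachograms) are evaluated at each beat
  onset and the next beat is placed one interval later.  Configured powers
  are in ms² *as measured by the packaged estimator*: oscillator
  amplitudes are pre-compensated by 1/sinc²(f·NNI_m) for the attenuation
  that linear interpolation of a beat-sampled sinusoid onto the 5 Hz grid
  imposes (at 0.25 Hz and 900 ms mean NN that attenuation is ~16% of
  power, far from negligible).  Integral pulse-frequency modulation is
  deliberately not modelled — the analysis operates on the tachogram, so
  generating directly in the beat domain is the contract that matters.
* **ECG** places one Ricker-wavelet QRS (width 12 ms) per beat with
  amplitude (1 + depth·sin(2πf_resp·t)), the mechanism ECG-derived
  respiration exploits.
* **Pressure-tachogram coupling** drives RR as mean + gain·(SBP(t−delay) −
  mean) + noise.  The default LF drive is a 23-tone comb spanning the
  whole 0.04–0.15 Hz band (RMS amplitude 5 mmHg): a drive with power at
  every LF bin is required for the transfer function to be identified
  across the band — with a single tone, off-peak LF bins contain only
  beat-sampling distortion and the band-averaged gain and coherency
  degrade even without noise.  A pure-tone mode is kept for didactic use.
* **Cohorts** draw per-subject index values from the published group
  distribution table (mean/SD per index × group × condition).  The table
  reports only marginals, so indexes are drawn independently by default
  (an optional Gaussian-copula correlation matrix is available).  Two
  marginal shapes are offered because the underlying shape is unknown:
  `gaussian` with negative draws truncated at 0 (several indexes have SD
  on the order of the mean) and `lognormal-matched` (moment-matched
  log-normal, strictly positive).  Under truncation the sample mean
  converges to the clipped-Gaussian mean, not the nominal mean; the tests
  assert against the analytic truncated-moment oracle.

What the synthetic data does *not* emulate: QRS morphology beyond a single
wavelet, arrhythmias, nonstationarity within a condition,
respiratory-cardiac phase coupling, closed-loop baroreflex dynamics, or
inter-index correlation structure.  Passing tests therefore demonstrate
the correctness of the *estimators* under known ground truth, not
robustness to every artifact of clinical recordings.

## Problem sizes and numerical choices

Test and consistency runs use desk-scale sizes chosen to keep sampling
error well inside the asserted tolerances: 16-min records (≈ 1000 beats)
for spectral/complexity recovery, n = 4096 and 20 seeds for DFA exponent
recovery, n = 5000 for the analytic SampEn check, 100 000 draws per group
for binormal AUC consistency, and a 20-per-group signal-level cohort
(16-min SUP + 10-min HUT each) for the end-to-end run.  Degenerate inputs
are signalled, not silently patched: undefined quantities (zero HF power,
no entropy template matches, empty scale bands, zero LF pressure
variance) return NaN with an `UndefinedResultWarning`, while invalid
inputs raise `ValueError`.

## Known limitations

* The R-peak detector expects upright QRS complexes and a dominant R
  wave; inverted leads must be negated upstream.
* EDR returns the global spectral maximum; bimodal breathing spectra are
  reported by their largest peak only.
* τ mapping uses the segment's mean NN; under strong within-segment heart
  rate drift the beat-scale-to-seconds mapping is approximate.
* The DFA detrending order of published multiscale profiles is not always
  recoverable; order 1 is the default and configurable.
* Ewing thresholds and SCOPA-AUT item maxima are configuration, not
  constants: studies cite them from heterogeneous sources.
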