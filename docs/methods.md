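# Methods

## Signal model and processing pipeline

A sedation session is a single-channel frontal biopotential recording
(μV, native rate ≥ 300 Hz) with per-second annotation streams: RSS scores
2–6 at nail-bed compressions, GAG 0/1 at tube insertions, and predicted
effect-site concentrations Ce_prop (μg/ml) and Ce_remi (ng/ml). The signal
is treated as a superposition of band-structured EEG and broadband facial
EMG; no source separation is attempted, because the EMG content of the
60–145 Hz range *is* the information of interest for arousal prediction.

Two analysis streams are derived by band-limiting and polyphase resampling:
0.1–45 Hz at 128 Hz (δ θ α β) and 0.1–145 Hz at 300 Hz (HF, VHF, TB). Mains
(50 Hz) and impedance-self-test (100 Hz) interference are excluded by the
band edges themselves (60–95 and 105–145 Hz), so no notch filter is applied.

**Segmentation.** For each annotation at time t the nominal window is
[t−90 s, t−30 s); the 30 s guard keeps the stimulation response out of the
window. The window is accepted only if |ΔCe| between its first and last
second is below 0.1 (both drugs, in their units); otherwise it is shortened
from its *start* one second at a time until stability holds — keeping the
samples closest to the event preserves the pre-stimulus state. Windows
shorter than 50 s are discarded. The directional choice (shorten from the
start) is a deliberate resolution of an ambiguity; the alternative (shorten
from the end) would erode the stimulation guard.

**Artifact handling.** Two automated rules, in order:

1. *ASEF peak suppression.* The instantaneous envelope is |analytic
   signal|; samples whose envelope exceeds k × median envelope (default
   k = 5) are rescaled so their local envelope equals that threshold. This
   flattens high-amplitude electrode/movement peaks while preserving local
   frequency content.
2. *Jump rejection.* Scanning forward with the running mean of absolute
   first differences, the window is truncated just before the first
   difference exceeding `factor` × running mean (default 10). The test
   starts only after the running mean rests on ≥ 50 differences: a
   cold-start mean estimated from a handful of samples would otherwise
   truncate nearly every window at its first few points. A rule reading of
   "10% of the mean difference" instead of a 10× exceedance multiplier
   would reject essentially every physiological sample, so the multiplier
   form is the normative definition here (config-exposed).

No visual screening is performed; recordings are assumed pre-screened.

**Band filtering.** Windowed-sinc FIR band-pass filters, Hamming window,
order 50 (51 taps), scaled to unity gain at the passband center, applied
forward–backward (zero phase). At these orders the stop-band leakage of the
narrow traditional bands is modest in a single pass (e.g. a 10 Hz tone
passes the θ filter at gain ≈ 0.19) and the forward–backward application
squares it (≈ 0.04). Zero-phase application costs a doubled effective
order but guarantees that window-level measures are not group-delay
shifted. Inputs shorter than 3 × filter length are rejected.

## Linear measures

Welch PSD with one-second Hamming-tapered segments, 25% overlap, density
scaling and constant detrending, so the integrated density equals the
window variance up to taper discretization (verified as a property test at
10%). Band measures: `P_band` = trapezoidal in-band area / total area over
the stream's support (0–64 Hz for the 128 Hz stream, 0–150 Hz for the
300 Hz stream — the denominator choice is config-relevant and documented
because "total area" depends on the analyzed support); `mF` = in-band PSD
centroid; `SEF50/75/90` = smallest frequency reaching 50/75/90% of in-band
cumulative area, linearly interpolated between grid points to remove the
1 Hz staircase bias. The TB centroid/SEF use the 300 Hz stream since TB
extends to 145 Hz. The biased sample autocorrelation (lag-0 normalized to
1) is computed per band window over the same lag horizon as the AMIF.

## Auto-mutual information

Each band-filtered window is quantized into 32 equidistant amplitude
partitions spanning the *window's own* min–max range (making all AMIF
measures invariant to affine amplitude transforms — important given large
inter-individual EMG amplitude variability; a constant window is flagged
degenerate and yields NaN measures). Joint probabilities at lag τ are bin-
pair frequencies of (x_i, x_{i+τ}); marginals are row/column sums of the
joint table, i.e. they describe the leading/trailing subsequences.

Shannon AMIF uses the 0·log 0 = 0 convention. The Rényi-q sum is evaluated
in log domain (logsumexp) because at q = 100 the linear-domain terms
under/overflow double precision; the nested-sum test oracle evaluates the
literal formula with per-term log/exp for the same reason. Empty joint
cells contribute nothing to either sum. The lag horizon is 1 s — 300
samples on the 300 Hz bands, 128 samples on the 128 Hz bands — a compromise
between resolving the slow δ band and EEG stationarity. Curves are
normalized by AMIF(0); at τ = 0 the Shannon curve equals the marginal
entropy (≤ 5 bits, exactly 5 for uniformly occupied bins, for any Rényi
order as well).

**Curve measures.** `m` = mean over τ ≥ 1 (τ = 0 is the normalization point
and carries no predictability information); `maxL` = curve *value* at the
first relative maximum (first strict rise then non-rise at τ ≥ 2, plateau →
first point; NaN when monotone non-increasing) — the value rather than the
lag, because maxL groups with m and min as magnitude measures; `min` =
signed minimum over τ ≥ 1 (signed so that autocorrelation minima near −1
are informative); `FD` = value(0) − value(1), computed on the normalized
curve. Semantics: higher m/maxL/min ⇒ more regular; higher FD ⇒ more
complex. These orderings are verified on synthetic extremes (white noise vs
slow sinusoid).

## Evaluation

*Screening.* Mann-Whitney U per measure per trial; exact enumeration when
both groups have ≤ 20 observations and no ties, tie-corrected normal
approximation otherwise; Bonferroni adjustment min(1, p·m) with the family
size m logged (number of lags for per-τ curve screening, number of measures
for table screening).

*Trials.* trial1: RSS 5 vs 6; trial2: RSS < 6 vs 6; trial3: RSS < 5 vs 5;
trial4: RSS < 5 vs 6; trial5: RSS < 5 vs ≥ 5; gag: GAG 1 vs 0. Response is
always the positive class.

*Classifier.* Linear discriminant with pooled within-class covariance and
equal priors: w = S⁻¹(μ₁ − μ₀), threshold at the midpoint of the projected
class means. This is deliberately minimal and deterministic; it is cross-
checked against an independent LDA implementation in the test suite.
Validation is leave-one-out; Sen/Spe are the held-out classification rates
of the response/no-response classes, and Pk is computed on the held-out
discriminant scores.

*Pk.* Concordance over all between-class pairs with ties counted half,
response class high. The standard error is the delete-one-case jackknife
(the standard choice in the indicator-performance literature), computed in
O(n²) with per-case pair-count downdates. Two indicators are compared via
(Pk_a − Pk_b)/√(SE_a² + SE_b²) against the normal distribution.

*Subset search.* Each iteration draws up to 4 measures whose pairwise
|Spearman ρ| < 0.7 (the "uncorrelated" criterion made explicit and
config-exposed), evaluates them leave-one-out and keeps the subset when Sen
and Spe both strictly exceed 60%. Results are ranked by Pk, ties broken by
Sen + Spe and then lexicographically, making the ranked list a pure
function of the seed. Draw probabilities are proportional to each measure's
univariate evidence (−log₁₀ Mann-Whitney p, floored): with a pool of ~30+
measures and ~10³ iterations, uniform draws of 4-subsets explore only a few
percent of the combination space, while evidence-weighted sampling
concentrates iterations on the informative region and still explores
(uniform sampling is available via `weight="uniform"`). Repeated subsets
are cached, so iteration count bounds unique evaluations.

## Synthetic generator

The generator reproduces the statistical structure the measures read, not
biophysics (no neural-mass or PK/PD model). Per pre-event segment, the
signal is a sum of unit-variance frequency-domain-shaped Gaussian
components scaled by state-conditional amplitudes:

| component | baseline σ (μV) | state dependence (effect size s) |
|---|---|---|
| δ noise 0.3–4 Hz | 9 | none |
| θ mixture: narrow 5.5–6.5 / broad 4–8 Hz | 5 | narrow fraction 0.5 ± 0.25 s (responsive high) |
| α narrowband at peak f | 4 | peak 10 ± 0.6 s Hz (responsive high) |
| β noise 12–30 Hz | 2.2 | σ × (1 ± 0.25 s) |
| EMG mixture: broad 60–145 / narrow 115–135 Hz | 2.0 | σ × (1 ± 0.3 s); narrow fraction 0.5 ∓ 0.25 s |

plus 50/100 Hz mains sinusoids (1 μV / 0.5 μV), Poisson peak artifacts
(0.1/min, ±100–200 μV, 3–7 samples — "occasional" electrode/movement
artifacts; higher rates are exercised in tests), and per-event lognormal
amplitude jitter (σ = 0.2). Unresponsive segments therefore show lower β
power, a lower α centroid, weaker and narrower-band (hence more
predictable, lower-FD) high-frequency activity, and less predictable
(lower-m) θ content — the five qualitative directions the measures are
meant to read. The narrowband-mixture mechanism controls lag-1
predictability of the EMG surrogate, standing in for motor-unit firing-rate
desynchronization.

Events alternate randomly (seeded shuffle) between 100 responsive (RSS
drawn 2–5; GAG events, when configured, flagged 1) and 100 unresponsive
(RSS 6 / GAG 0) at 100 s spacing; concentrations ramp over a 120 s lead-in
and then plateau with drift far below the stability thresholds, so every
scheduled window is concentration-stable. `effect_size = 0` makes the two
classes exactly exchangeable (null calibration); 2 makes them
near-separable.

What the generator does *not* emulate: genuine EEG 1/f structure and
nonstationarity, drug-concentration dependence of the spectrum beyond the
two-state contrast, inter-subject variability, real artifact morphologies,
and any nonlinear coupling between bands. Passing end-to-end tests
therefore demonstrates that the *pipeline recovers planted structure of the
expected direction and size*, not clinical performance; the clinical
figures reported for this methodology require a patient database and are
out of scope here.

## Numerical and design notes

- Resampling is rational polyphase (`resample_poly`) with built-in
  anti-aliasing; 60 s at 900 Hz → exactly 7680 samples at 128 Hz.
- Quantization assigns the window maximum to the top bin (right-inclusive
  edge); ramp inputs occupy all bins uniformly.
- The reference four-measure combination used in examples and calibration
  checks — `m(Re_50)_θ`, `P_β`, `P_VHF`, `FD(Re_05)_VHF` — spans the
  traditional-band complexity, β power, EMG-band power and EMG-band
  complexity axes, one measure per mechanism.
- End-to-end checks run at 100 events per class (≈ 190 surviving windows),
  the size at which median-direction and leave-one-out Pk checks are stable
  while a full run stays around a minute.
- Degenerate inputs are flagged, not silently repaired: constant windows
  give NaN AMIF measures (excluded pairwise in evaluation), zero-power
  bands give NaN spectral measures with a warning, and folds that lose a
  class raise.

## Known limitations

- EDF files are read (via MNE, first EEG-typed channel) but not written;
  the CSV dialect is the round-trip format.
- The discriminant is linear only; a quadratic variant is a natural
  extension point but is not implemented.
- `maxL` is undefined (NaN) on monotone curves, which occurs regularly for
  broad-band windows; downstream evaluation excludes such rows pairwise
  for subsets that include it.
- The jackknife SE of Pk assumes independent windows; windows from the
  same synthetic recording segment are independent by construction, but
  for real repeated-measures data the SE would be optimistic.
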