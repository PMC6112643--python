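# Methods

This note documents the models, conventions, and numerical choices behind
`ehgkit`. It is written for users who want to know exactly what the toolkit
computes and where its desk-scale validation does — and does not — carry
over to clinical recordings.

## Signals and records

A uterine record holds up to four channels sampled at 20 Hz: three bipolar
abdominal EHG signals (S1: upper horizontal pair, S2: left vertical pair,
S3: lower horizontal pair) in µV, and optionally the external tocogram
(TOCO), the mechanical uterine-pressure signal from a tocodynamometer
digitized at the same rate (150 µV of amplifier input per Pa). Records are
stored in a WFDB-compatible dialect: a plain-text `.hea` header plus a
16-bit little-endian interleaved `.dat` file, with obstetric metadata
(gestational age at recording and delivery, clinical group) in `#`-comment
lines. Interval annotations label *contraction* spans (TOCO deflection with
simultaneous EHG bursts) and *dummy* spans (quiescent stretches of
comparable length). Indices are 0-based and intervals half-open
`[onset, offset)`, so lengths are simply `offset − onset`; whether a
clinical annotator intends edge samples inclusively is not standardized,
and this convention is a deliberate, documented choice.

## Analysis bands and filtering

All features are computed in four strictly separated bands plus a wide
band:

| band | Hz          | content                                        |
|------|-------------|------------------------------------------------|
| B0   | 0.08 – 1.0  | contraction bursts, maternal respiration (0.2–0.34 Hz) |
| B1   | 1.0 – 2.2   | maternal heart rate fundamental (72–132 bpm)   |
| B2   | 2.2 – 3.5   | second cardiac harmonic                        |
| B3   | 3.5 – 5.0   | third cardiac harmonic                         |
| WIDE | 0.08 – 5.0  | pre-filter rejecting baseline wander and HF noise |

Each band is a fourth-order digital Butterworth band-pass (−80 dB/decade
roll-off) applied forward and backward, which squares the magnitude
response (−160 dB/decade effective) and cancels the phase exactly. The B0
lower edge at 0.08 Hz deliberately retains the respiration component so
that the spectrum always contains a strong low-band peak to normalize by.

**Edge handling.** Bidirectional filtering needs padding; the filters ring
for roughly `order / min(bandwidth, f_low)` seconds, so the default
odd-reflection pad targets six ring times (capped at the signal length −
1). Shorter pads leave direction-dependent transients of order 1e−1 at the
record edges for the narrow bands at 20 Hz; with this pad the
time-reversal symmetry of the output holds to ~1e−12. Inputs shorter than
`3·(2·order+1)+1` samples are rejected outright.

Re-filtering a WIDE-filtered white-noise signal reduces its RMS by ~3.5%:
the pass band is untouched but the transition bands are attenuated again
(the ratio follows `√(∫|H|⁸ / ∫|H|⁴)` of the analytic response). This is a
property of any finite-order filter, not an implementation artifact, and
the test suite checks the measured ratio against that closed form.

## Features

Eleven features per signal per interval (or per whole record):

* **Sample entropy** `SE(m, r) = −log(c_m / c_{m−1})`, with `m = 3` and
  `r = 0.15`, computed in each band B0–B3 from the time-domain subband
  signals. Templates of length `m` and `m − 1` are evaluated at the same
  `N − m` starting positions with Chebyshev tolerance `r`, so
  `c_m ≤ c_{m−1}` and SE ≥ 0 in the regular branch. Segments are
  standardized to zero mean and unit variance before matching, making `r`
  a fraction of the segment SD and the statistic gain-invariant; a
  zero-variance segment is the all-match case (SE = 0). When either count
  is zero the fallback `−log((N−m)/(N−m−1))` is returned *verbatim*; note
  that this published form is slightly negative (its argument exceeds 1),
  and we keep it rather than silently taking the reciprocal. Low SE in a
  band indicates a periodic mechanism (e.g. the cardiac fundamental in
  B1); high SE indicates its absence. Matches are counted as ordered
  pairs; only the ratio enters the statistic. The optimized counter (a
  compiled early-abort scan, with a vectorized numpy fallback) is verified
  to agree *exactly* with a naive O(N²·m) double loop.

* **Median frequency** `MF` and **normalized peak amplitude** `PA`, read
  per band from a single spectrum of the WIDE-filtered signal: Hanning
  window, FFT power spectrum with `M` equal to the segment length (no
  zero-padding, so the smoothing span in bins tracks the true resolution),
  a centered moving average spanning 0.1 Hz (window forced to an odd bin
  count; shrinking at the edges), then division by the global maximum
  `P_max` over [0, fs/2]. `MF` is the frequency of the first in-band bin
  at which cumulative in-band power reaches half the in-band total; `PA`
  is the in-band maximum of the normalized spectrum and equals 1 exactly
  when the global peak lies in the band. Smoothing precedes
  normalization. Band-edge bins are assigned by rounding `f·M/fs`; a bin
  shared by two bands belongs to the lower band, keeping band features
  disjoint. `PA` in B0 is omitted (the normalization peak almost always
  lies there), giving 11 features per signal. `PA` in B1 is the marker of
  interest: it quantifies the electro-mechanical coupling of the maternal
  heart into the uterus, which is strong in term pregnancies far from
  delivery and weak close to delivery or in preterm-prone pregnancies.

Whole-record mode applies no transient trimming by default (a
`trim_seconds` option exists for sensitivity analysis), and the smoothing
span stays 0.1 Hz regardless of segment length. Recording-to-delivery gaps
of ≤ 3 weeks define the *labor* group (an intentionally early boundary,
configurable).

## Separability and feature selection

Univariate separability uses Gaussian-moment forms computed from the two
class-conditional sample means and variances:

* pooled-variance two-sample t-test (two-sided p);
* Bhattacharyya distance
  `C_B = (μ₁−μ₂)²/(4(σ₁²+σ₂²)) + ½·ln[(σ₁²+σ₂²)/(2σ₁σ₂)]`;
* symmetrized Kullback–Leibler divergence `½[KL(1‖2) + KL(2‖1)]`.

Ranking is by descending criterion (ascending p) with ties broken by
column order.

Subset selection is a sequential-forward-selection wrapper: a stratified
20% holdout is split off (reporting only — it does not influence
selection), features are enumerated in descending `C_B` order (order
only), and at each step the candidate minimizing the 10-fold
cross-validated misclassification error (MCE) of a QDA classifier on the
training split is added. The MCE-vs-k curve is evaluated over the *entire*
feature range and the subset is cut at its global minimum (smallest k on
ties) — stopping at the first local minimum is known to stop prematurely.
Because single runs are unstable, the run is repeated (default 200 times
with per-run seeds spawned from one master seed), a selection-frequency
histogram is accumulated, and the final subset takes the most frequent
features, with the subset size set by the argmin of the run-averaged MCE
curve. Ties in frequency resolve by earlier average selection position,
then column order.

A caveat worth knowing: because each curve point is a minimum over
remaining candidates, the averaged curve can keep creeping down by tiny
amounts after the informative features are in (selection bias of the
best-of-k step), so on weakly separated data the argmin can land a few
positions past the true subset size. This mirrors the behaviour of the
underlying procedure, not a bug.

## Balancing and classification

* **SMOTE** equalizes class counts exactly by placing synthetic minority
  rows uniformly on segments between a minority sample and one of its
  k = 5 nearest minority neighbors.
* **ADASYN** allocates synthetic counts per minority sample proportionally
  to the fraction of majority points among its k nearest neighbors in the
  full data (uniform fallback when every neighborhood is pure minority);
  rounding is trimmed so the minority count approaches parity from below.

Classification is quadratic discriminant analysis: one Gaussian per class
with its own mean and covariance, priors from class frequencies, scores =
posterior probability of the positive class (always the clinically
alarming one: preterm, labor, or non-pregnant depending on the task). The
public fit goes through scikit-learn; a singular class covariance (e.g. a
constant feature) falls back to an internal implementation that adds
`λ·trace(Σ)/d` to the covariance diagonal with λ = 1e−6 (escalating ×100
on repeated failure). The same internal discriminant serves as the fast
path inside cross-validation and SFS loops; a test pins its agreement with
scikit-learn.

Evaluation is stratified k-fold (5 or 10) cross-validation repeated 30
times. Confusion counts are pooled across folds within a repetition
(Se = TP/(TP+FN), Sp = TN/(TN+FP), CA = (TP+TN)/total), AUC is the
trapezoidal area under the ROC of the fold-pooled scores, and all four are
averaged over repetitions and reported in percent. By default,
oversampling runs *inside each training fold only*, so evaluated rows are
never synthetic; a `balance_upfront` mode balances once before CV for
protocols that report balanced class sizes as the experimental population.
Both modes are tested.

## The synthetic record generator

The simulator exists so the entire pipeline can be exercised end-to-end
without clinical data. Each record (default 1800 s at 20 Hz, channels
S1/S2/S3/TOCO) sums:

* white sensor noise (0.5 µV EHG, 0.3 TOCO);
* a respiration sinusoid, frequency drawn in 0.2–0.34 Hz, amplitude
  2.5 µV — large enough that the normalization peak `P_max` sits in B0, as
  it does in real records;
* a cardiac harmonic stack: fundamental drawn in 1.2–1.5 Hz (72–90 bpm)
  with 2nd/3rd harmonics at a 0.45 amplitude decay and a slow ±0.05 Hz
  sinusoidal frequency modulation giving the spectral peak realistic
  width. The tocogram receives the fundamental at full strength but
  harmonics attenuated ×0.25 — mechanically the heart *rate* transmits,
  not the sharp electrical waveform. A harmonic stack is used instead of a
  filtered ECG template because only the spectral signature matters to the
  features;
* contraction bursts: Gaussian-envelope-modulated band-limited
  (0.1–1.0 Hz) noise at 12 µV on the EHG channels during three scheduled
  ~85 s intervals, with the envelope mirrored into TOCO as the smooth
  pressure deflection annotators key on. Dummy annotations are placed in
  the gaps with lengths matched to neighboring contractions. The 12 µV
  scale keeps dummy-interval burst-band energy below 10% of contraction
  intervals despite the respiration floor inside that band (this contrast
  is a property of the full-length records; scaled-down records leak
  relatively more burst energy out of band).

Three archetypes set the cardiac coupling: `term_nonlabor` (strong, EHG
amplitudes 3.0/2.0/1.5 µV for S1/S2/S3 — strongest in S1 — and 3.0 in
TOCO), `preterm_like` (×0.15, the danger signature), and
`nonpregnant_like` (no contractions; EHG cardiac present at ×0.8 but TOCO
cardiac absent — the mechanical pathway requires the pregnant uterus).
Cohorts jitter heart rate, amplitudes, and schedules per record; every
draw flows from one seed through counter-based Philox streams, so
identical configurations emit byte-identical files on any platform.

**What passing tests show — and what they do not.** The simulator
reproduces the *spectral* phenomenology the features read (band placement
of mechanisms, harmonic structure, amplitude ordering between archetypes),
so end-to-end tests demonstrate that the pipeline recovers injected
parameters and separates archetypes nearly perfectly (CA ≥ 95%,
AUC ≥ 97% on 30+30-record cohorts). Real EHG is non-stationary, has
1/f-like broadband background, motion artifacts, electrode drift, and far
smaller effect sizes; desk-scale results bound implementation correctness,
not clinical performance.

## Problem sizes and determinism

Default desk-scale experiments are sized to run on one CPU in minutes: the
selection benchmark uses 100 balanced rows × 10 features × 200 SFS runs;
the end-to-end benchmark uses 30+30 records × 3 dummy intervals × 2
signals under 10-fold × 30-repetition CV. All pipelines are deterministic
given their seeds; feature extraction is seed-free and bit-reproducible.

## Known limitations

* No contraction detection: annotations are inputs.
* Criteria use Gaussian-moment forms; heavily non-Gaussian features will
  be mis-ranked by `C_B`/`D_KL` (the SFS wrapper is distribution-free).
* The SE fallback branch keeps the published (negative) closed form.
* AUC is computed from fold-pooled scores per repetition; fold-wise AUC
  averaging would differ slightly on small folds.
* The WFDB dialect reader supports format 16 only.
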