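# Methods

`seegflow` re-implements, as a tested library plus pipeline, an interictal
resting-state SEEG analysis that localizes the seizure onset zone (SOZ) and
predicts post-surgical seizure outcome from three families of markers:
within-frequency directed information flow, cross-frequency directionality,
and the aperiodic 1/f power slope.  Because clinical SEEG cohorts of this
kind are not publicly deposited, the package ships a synthetic-cohort
generator that serves as the ground-truth surface for every downstream
stage; all empirical claims made by the test suite and the acceptance
script are recovery and calibration properties computed on that surface.

## Preprocessing (core_io)

Recordings are EDF files in microvolts with a tab-separated channel table
(label, RAS coordinates in mm, white-matter flag, SOZ flag).  The
preprocessing chain is: optional bipolar re-referencing along electrode
shafts (anode − cathode; position = contact midpoint; a bipolar channel is
SOZ if either contact is, and white matter only if both are), exclusion of
white-matter channels, a zero-phase second-order IIR notch at 60 Hz
(quality factor 30, one filter per harmonic below Nyquist; zero-phase so
the phase relations used by the directionality estimators are preserved),
polyphase resampling to a common 500 Hz analysis rate (Nyquist 250 Hz
matches the top analysis frequency, making the 1–250 Hz grids identical
across patients), artifact-free segment selection, and epoching into
non-overlapping 1 s segments (trailing remainder discarded).

Artifact screening in the clinic is visual; here it is replaced by an
automated, testable rule: a sample is artifactual when any channel's
robust amplitude z-score (median/MAD scale) exceeds 6, and only segments
(default 180 s, scanned at 1 s steps) free of such samples are
concatenated, up to the requested total (default 600 s).  This is a
declared stand-in, not a reconstruction of any specific clinical screening
protocol.

## Directed transfer function (mvar_dtf)

A single multivariate autoregressive (MVAR) model per patient is fitted by
pooled least squares across all 1 s epochs (regressions never cross epoch
boundaries); the residual covariance comes from the pooled residuals.
Model order defaults to AIC over p = 1..20 (BIC available; ties break to
the smallest order).  When the design is data-poor (fewer than 5·n·p
regression rows) a small ridge term (1e-3 × mean diagonal of the normal
equations) is added and logged.  From the fitted coefficients the spectral
transfer matrix is H(f) = (I − Σ_k A_k e^{−i2πfk/fs})^{−1} and the
squared, inflow-normalized DTF is

    γ²_ij(f) = |H_ij(f)|² / Σ_m |H_im(f)|² ,

so each target's row over sources sums to one (asserted to 1e-9 on every
tensor the package builds).  The frequency grid is fixed to 1..250 Hz in
1 Hz steps.  Flow summaries: group-to-group means between SOZ and non-SOZ,
per-channel inward/outward strength (mean flow received from / sent to all
other channels), and distance stratification with short (< 33 mm), mid
(33–60 mm, closed at 33) and long (> 60 mm) ranges between bipolar
midpoints.

Squared inflow-normalized DTF was chosen over the unnormalized variant
because inward-strength averaging is only well-scaled on the normalized
form; one model per patient (rather than per-epoch averaging) maximizes
data per estimate.

## Cross-frequency directionality (cross_freq_directionality)

CFD asks whether low-frequency activity (LFA, < 30 Hz) of one channel
leads or lags the high-frequency amplitude (HFA, > 30 Hz) envelope of
another.  The estimator is the phase-slope index (PSI) between the raw
phase-channel signal and the Hilbert envelope of the band-passed amplitude
channel: ψ = Im( Σ_f conj(C(f)) C(f+δf) ) over a window fp ± 2 Hz, where C
is the complex coherency from 2 s Hanning segments with 50% overlap
(0.5 Hz resolution), normalized by its jackknife standard deviation.
Positive ψ means the LFA phase leads the HFA amplitude.  The envelope
bandwidth is max(0.3·fa, 10) Hz so the modulation sidebands at fa ± fp are
retained.  PSI is computed in explicit real arithmetic, which makes
argument-swap antisymmetry exact to the last bit (complex multiplication
in floating point is not sign-symmetric).

Surrogate nulls circularly shift the amplitude envelope by at least 1 s,
preserving both spectra while destroying cross-channel timing (200
surrogates by default).  Per patient the dominant CFD pattern across
electrode pairs is extracted by k-means (k = 3, best of 20 initializations)
on the vectorized maps, separately for the SOZ-phase→non-SOZ-amplitude and
reverse directions; the dominant centroid is the one with the largest mean
|ψ|, and a one-sample t-test across patients compares the dominant-pattern
cell means against zero.

## Aperiodic 1/f slope (spectral_aperiodic)

Per-channel spectra are Hanning-tapered FFT periodograms of the 1 s
epochs, averaged over epochs on the 1–250 Hz, 1 Hz grid.  The aperiodic
model is fit in semilog-power space (linear frequency, log10 power):

    log10 P(f) = b − χ·log10 f + Σ_g h_g exp(−(f − c_g)²/(2 w_g²)) ,

by iterating (up to 3 outer rounds, keeping the best iterate; the mean
absolute residual is non-increasing by construction) between (1) a robust
offset/exponent line fit that refits on the points below the 60th
percentile of residual (oscillatory peaks only push power up), (2)
largest-first Gaussian peak extraction on the flattened residual
(threshold max(2 sd, 0.05 log10 units), width limits 1–12 Hz, up to 6
peaks, overlapping weaker peaks pruned), with a bounded least-squares
joint refit, and (3) an aperiodic refit on the peak-subtracted spectrum.
The 58–62 and 118–122 Hz bins are excluded from the loss because notch
filtering would otherwise bias the fit.  The reported power slope is −χ,
the conventional proxy for the excitation:inhibition ratio (more negative
slope, higher E:I imbalance).  Only the fixed (no-knee) mode is
implemented; the emulated analyses report a single broadband slope.

## Group statistics (group_stats)

Frequency-wise group comparisons are Welch (unequal-variance) two-sample
t-tests at each of the 250 bins with Benjamini–Hochberg FDR control across
bins (q = 0.01 for the flow comparisons, 0.05 elsewhere); bins with zero
variance in both groups get p = 1 with a warning.  The per-patient flow
asymmetry is Δ = mean₁₋₂₅₀(non-SOZ→SOZ) − mean₁₋₂₅₀(SOZ→non-SOZ); its
association with outcome is a Welch t-test between the seizure-free and
non-seizure-free classes.  Slope comparisons are electrode-level Welch
tests pooling electrodes across patients, plus a patient-level sign count
(patients whose mean SOZ slope is more negative).  A note on power: for a
1-pooled-sd effect at 50 of 250 bins with n = 30/30 at q = 0.05, the
BH-effective per-test level is ≈ 0.01 and the per-bin power ≈ 0.88; the
calibration test asserts that oracle value.

## Classification (classify_predict)

Electrode-level features are the 250 inward-flow values (mean DTF received
from all other electrodes at 1..250 Hz); patient-level features are the
250-bin mean non-SOZ→SOZ flow spectrum (a bidirectional variant is
available behind a flag).  Class imbalance (SOZ electrodes ≈ 116:573) is
handled by SMOTE — synthetic minority rows are uniform interpolations
between a minority sample and one of its 5 nearest minority neighbors,
oversampling to parity by default — fitted strictly inside each training
fold, plus inverse-class-frequency tree weighting in a 500-tree random
forest (sqrt features per split).  Evaluation is stratified five-fold
cross-validation with pooled held-out probabilities: ROC/AUC, accuracy at
threshold 0.5, and per-class precision/recall.  Electrode-level folds pool
electrodes across patients, matching the emulated evaluation; because this
lets a patient straddle folds, a grouped (patient-stratified) mode is
provided behind a flag.  The two-stage outcome variant derives each
patient's SOZ mask from the electrode classifier's out-of-fold
probabilities (threshold 0.5; a patient with no electrode above threshold
falls back to its top-1 electrode, logged) before building patient
features.

## Synthetic cohorts (synthetic_cohort)

The generator's defaults are the emulated clinical conditions: 27 patients
(19 seizure-free = Engel I; 8 not: 4 II, 3 III, 1 IV; 15/9/3
nonlesional/focal/diffuse), 600 s of resting-state signal per patient at
500 Hz, an SOZ:non-SOZ electrode ratio of 116:573, SOZ aperiodic
exponents drawn at 2.23 ± 0.33 and non-SOZ at 2.08 ± 0.44, and contacts
placed on depth-electrode shafts (3.5 mm pitch) inside a cortex-scale
sphere so inter-electrode distances span the short/mid/long strata.

Each patient's signal is built in three independently tunable layers:

1. **Directed network.**  A stable MVAR (lag-1 coupling, lag-2 diagonal;
   companion spectral radius checked < 1 at generation) in which every
   non-SOZ→SOZ pair couples at (base + Δ)/(n−1) and every SOZ→non-SOZ
   pair at base/(n−1) (background non-SOZ edges at a quarter of base),
   jittered U(0.5, 1.5).  Δ is the flow-asymmetry effect size:
   Δ_free = 0.25 for seizure-free patients, Δ_nonfree = 0.08 otherwise,
   base = 0.20.  No quantitative coupling scale is available for real
   cohorts, so these are the generator's declared effect sizes, fixed once
   from a calibration in which the fitted-DTF asymmetry had to (a) track Δ
   monotonically, (b) be positive in ≥ 90% of patients at Δ > 0, and
   (c) separate the outcome classes at cohort size; they are not estimates
   of any clinical effect.
2. **Common tilt + aperiodic background.**  The MVAR realization is passed
   through a causal AR(1) filter (pole 0.85) shared by all channels — a
   causal scalar filter keeps the process a finite-order VAR and cancels
   exactly in the inflow-normalized DTF, so the coupling ground truth is
   untouched, while the network component acquires the 1/f-like decay of
   field recordings.  (A zero-phase spectral tilt was rejected: non-causal
   filtering scrambles the directed structure that MVAR estimation needs.)
   Independent per-channel noise with expected spectrum ∝ 1/f^χ (spectral
   shaping of white noise) is then added at 1.0 × channel RMS, so each
   electrode's measured PSD slope reflects its own χ.  The pole/weight
   pair was chosen from a small design scan as the point where both the
   slope contrast and the DTF asymmetry remain recoverable; with a white
   (untilted) network component the flat high-frequency floor dominates
   the 1–250 Hz fit and no weight can express the χ contrast.
3. **Cross-frequency coupling.**  A 100 Hz carrier whose amplitude
   envelope is (1 + depth·cos φ_src(t − lag))/2, with φ_src the 3 Hz-band
   phase of an SOZ channel, is added to a non-SOZ channel (depth 0.6,
   lag −30 ms, i.e. the high-frequency amplitude leads — the direction
   reported for interictal resting-state epilepsy networks).  Positive lag
   means LFA leads HFA and yields positive CFD.

All randomness flows from one root seed through named SeedSequence
substreams, making cohorts byte-reproducible.  What the generator does
*not* emulate: non-stationarity, interictal spikes and HFOs, volume
conduction / common reference artifacts, electrode-geometry-dependent
coupling, and any interaction between the E:I proxy and the coupling
graph.  Passing tests therefore demonstrate method correctness and
recoverability under the declared generative model, not clinical
performance.

## Problem sizes

The generator defaults keep the emulated conditions (600 s per patient,
27 patients, 116:573 imbalance).  The test suite and the acceptance script
run scaled-down instances chosen as the smallest sizes at which each
property is stable: 60–120 s recordings, 12–16 electrodes per patient,
order-6 MVAR fits, 200 phase-randomized surrogates, 20-seed recovery
loops, and 300-tree forests for the cohort classifiers (30–100 trees for
null-calibration loops).  The acceptance pipeline cohort is 27 patients ×
16 electrodes × 120 s.

## Numerical choices and degenerate inputs

Bounded least squares with tolerance 1e-8 and deterministic data-derived
initialization for all nonlinear fits (no random starts); PSI returns
exactly 0 for identical inputs (guarding the 0/0 jackknife ratio);
zero-variance frequency bins test at p = 1 with a warning; an unstable
fitted MVAR is flagged and warned about but still evaluable; empty
distance strata are reported with count 0 and no spectrum; a singular
spectral matrix names the offending frequency; EDF physical bounds are
parsed back from their 8-character header fields so the written scaling
matches the header exactly (round-trip error is pure 16-bit quantization).

## Known limitations

Electrode-level cross-validation pools electrodes across patients, so
patient-level information can leak between folds (the grouped mode
quantifies this); the additive independence of background and network is
a realism limit; the aperiodic fit implements only the fixed mode; CFD is
estimated on sampled pairs in the pipeline for cost reasons; distances use
straight-line geometry, not anatomical connectivity.
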