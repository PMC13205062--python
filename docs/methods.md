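# Methods

This note documents the models and procedures `fatigue3` implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Study design assumed by the pipeline

A session is 81 minutes: a 1-minute rest followed by an 80-minute drive.
Time zero is the start of the rest; the driving period is [60, 4860] s
and all feature windows are half-open 30 s intervals covering only the
drive (160 windows, midpoints 75, 105, … s). Fatigue self-assessments
(1–5) are reported every 10 minutes during the drive. EEG (Fp1, Fpz,
Fp2, left-earlobe reference) is sampled at 250 Hz; fNIRS at 12.5 Hz over
six 30 mm long channels (pairs S1D2+S2D1, S2D3+S3D2, S3D4+S4D3 mapping
to Fp1/Fpz/Fp2) and four 8.4 mm short channels (S1D1, S2D2, S3D3, S4D4),
each long channel flanked by two short ones.

## Fatigue labeling

Scores map 1–2 → NonF, 3 → ModF, 4–5 → SevF. An inter-report interval
whose endpoints agree keeps that stage; otherwise it is a transition
segment crossing |level difference| steps. Upward refinement pools the
N largest PERCLOS first differences with the N earliest valid yawn
onsets and keeps the N earliest distinct times; downward refinement uses
the N most negative differences only. PERCLOS is the closed fraction of
each consecutive 8 s eye-state block; the first difference is assigned
to the later block's start time. A yawn is valid iff its duration
strictly exceeds 1.5 s.

Degenerate-case rules (design choices): a first difference qualifies as
a candidate only when its sign matches the transition direction — on a
flat PERCLOS stretch a tie of zero differences would otherwise become
the "earliest" candidate and outrank genuine evidence; and a derivative
candidate within one PERCLOS block (8 s) of a yawn candidate is treated
as the same behavioral event, since PERCLOS timestamps are quantized to
the block length while yawn onsets are not. Without the second rule a
two-step segment is structurally unrecoverable: both of its candidate
slots fill with duplicate evidence of the first change. When a segment
offers no usable candidates the transition is placed at the segment
midpoint and flagged `low_confidence` (the original protocol's manual
video verification is replaced by this flag). The span before the first
report inherits the first report's level. A window midpoint exactly on a
transition boundary takes the later stage.

## EEG chain

Zero-phase IIR notches (Q = 30) at the four optical-switching crosstalk
lines 12.5/25/37.5/50 Hz, then a zero-phase 4th-order Butterworth
band-pass 0.5–30 Hz. Bad channels — an automated proxy for manual
inspection — are masked when > 30% of their 30 s windows show
peak-to-peak > 500 µV or a flat run > 5 s.

Blink removal is wavelet-assisted adaptive cancelation: a stationary
wavelet transform (sym4, 6 levels) isolates the < 2 Hz approximation;
samples where it exceeds 3 scaled MADs form the blink reference. The
gate is dilated (±0.15 s) and smoothed with a 0.4 s Hann taper — a hard
on/off gate injects broadband steps through the subtraction. The
canceller is a normalized LMS filter (order 3, µ = 0.5), updated only
while the gate is on. Recursive least squares was evaluated first and
rejected: under bursty, gated excitation its covariance matrix winds up
between blink epochs and the filter diverges; NLMS is unconditionally
stable for 0 < µ < 2 at the cost of slower convergence, which is
irrelevant at blink energies.

Band powers use Welch's method per 30 s window (4 s Hann segments, 50%
overlap), integrating the periodogram over δ 0.5–4, θ 4–8, α 8–13,
β 14–30 Hz; the 13–14 Hz gap belongs to no band, following the printed
band definitions literally. Relative powers and η = P_β/(P_θ+P_α) are
scale-invariant; channel averages are arithmetic means over unmasked
channels.

## fNIRS chain

ΔOD = −log10((V − dark)/(V_baseline − dark)) with V_baseline the mean
over the first 2 s (rest). The quality screen (proxy for visual
inspection) masks saturation plateaus (flat > 0.5 s), |ΔOD| > 1
excursions, and 30 s windows without a locally prominent cardiac
spectral peak in 0.5–2.5 Hz (≥ 3 dB above the flanking background and
not at the band edge — drift leakage is monotone across the band and
would otherwise pass a naive peak-to-median test).

Motion correction detects epochs where the 1 s moving SD exceeds 3× its
channel median, extends each epoch while the smoothed level has not
returned to the pre-epoch baseline (bounded at 15 s, so step+decay tails
are corrected, not just the step), subtracts a smoothing-spline artifact
estimate re-anchored to the neighbours, and finally clips wavelet detail
coefficients (db4, 4 levels) beyond 4 scaled MADs. Cubic drift is then
removed by least squares per channel.

Superficial physiology is removed per wavelength by the dual
short-channel regression: ΔOD_brain = ΔOD_L − S(SᵀS)⁻¹SᵀΔOD_L with
S = [ΔOD_short-src, ΔOD_short-det], computed once over the whole
detrended series, no intercept (all series are baseline-referenced).
Null or collinear regressor columns are dropped with a warning. The
residual norm never exceeds the input norm (projection contract).

The Beer–Lambert inversion uses extinction coefficients (1/(mM·cm)) at
735/805/850 nm of 0.450/0.810/1.058 for HbO and 1.123/0.770/0.691 for
HbR (tabulated compendium values), DPF 6.0 at all wavelengths, and
pathlength L = DPF·r (r = 3.0 cm long, 0.84 cm short); all are
config-exposed, and the simulator shares the same table, making the
forward/inverse pair exact on noise-free data. Concentrations are
reported in µmol/L, low-passed at 0.1 Hz (zero-phase Butterworth),
combined into ΔHbT = ΔHbO+ΔHbR and ΔCOE = ΔHbR−ΔHbO, and averaged
within location pairs (one masked member → use the other, flagged).
Windows with > 50% masked samples are missing. Window means are
normalized per experiment (subject × paradigm) by 5–95 percentile
min–max to [−1, 1], clipped; a degenerate spread normalizes to 0 with a
warning.

## Pulse variability

Short-channel ΔOD → Beer–Lambert (r = 0.84 cm) → zero-phase 0.5–2.5 Hz
band-pass; peaks are detected on ΔHbO_pulse, whose waveform is cleaner
than ΔHbR_pulse. AMPD builds the local-maxima scalogram over scales
k = 1…N/2 after linear detrending, picks the scale with the most maxima,
and keeps samples that are maxima at every retained scale.

At 12.5 Hz a raw peak index quantizes beat times to 80 ms — an order of
magnitude above the beat-to-beat variability of interest — so beat times
are refined by per-beat template matching: the window's mean beat
waveform (zero-meaned) is cross-correlated with each beat on an
8× Fourier-upsampled grid and the correlation maximum is interpolated
parabolically. Template matching preserves genuine beat-to-beat
variability; narrowband phase methods act as resonators that smooth it,
and single-point parabolas hop between the lobes that band-passing a
sharp pulse creates (both were tried and rejected).

IBI cleaning keeps intervals in [0.33, 1.5] s (40–180 bpm) and within
3 scaled MADs (3 × 1.4826 × MAD) of the window median; the MAD rule is
skipped when MAD < 2 ms, i.e. below timing resolution, where it would
veto ordinary beats. A window needs ≥ 10 surviving intervals for a PRV
value, else it is missing (not zero). SDNN and RMSSD both use N−1
denominators; a zero-variance interval sequence returns exactly 0.
Channel averaging happens on raw values; normalization (per experiment,
5–95 percentile, to [0, 1]) afterwards.

## Statistics

Per feature and paradigm: REML fit of `y ~ stage + (1 | participant)`
(statsmodels MixedLM, default BFGS optimizer — L-BFGS silently stalls at
a boundary solution for this design). EEG features are analyzed raw,
hemodynamic and PRV features on their normalized scale. Estimated
marginal means are the model-implied stage means; contrasts
(NonF→ModF, ModF→SevF, NonF→SevF) use a normal (Wald/z) approximation —
no Satterthwaite/Kenward–Roger correction; this is flagged in the result
metadata and is why the null calibration tolerates rejection rates
slightly above nominal. Holm step-down adjustment is applied within each
feature's three contrasts; direction codes are ↑/↓ only at adjusted
p < 0.05. A singular random-effects fit falls back to OLS, flagged.
Friedman tests (tie-corrected, χ² reference) and the two-way
repeated-measures ANOVA on transition times (fatigue type × transition
type, Shapiro–Wilk per cell) use scipy and pingouin.

## Synthetic data

The generator inverts the analysis chain, so every downstream stage can
be tested against programmed truth.

*Schedules.* Transition times are drawn per subject from
N(34.3, 10.3²)/N(53.8, 15.4²) min (active) and N(24.5, 8.8²)/
N(40.2, 13.2²) min (passive), redrawn until ordered with ≥ 4 min gaps
and margins. All stage-scheduled quantities cross-fade over 10 s raised
cosines at the transitions.

*EEG.* Per-band unit-variance noise is synthesized spectrally
(brick-wall confinement — Butterworth-shaped synthesis leaks programmed
variance into neighbouring bands and distorts the very ratios under
test), scaled by the per-stage SD schedule, summed, and decorated with
crosstalk sinusoids at the four notch lines, white sensor noise
(1 µV SD), and lognormal-amplitude 0.3 s blink bumps (4/min, stronger at
Fp1/Fp2). The active band-variance profile encodes the inverted-U of η
(≈ 0.98 → 1.15 → 0.91) and the passive profile its late decline
(0.82 → 0.81 → 0.76).

*fNIRS.* Programmed per-stage (ΔHbO, ΔHbR) means (µmol/L, zero during
rest) run forward through the shared Beer–Lambert tables into long-
channel ΔOD. Each short channel carries superficial Mayer (0.1 Hz,
1 µM) and respiration (0.25 Hz, 0.5 µM) waves plus the cardiac pulse;
each long channel receives 0.4× the ΔOD of both flanking shorts, so the
regression's assumed mixing is exact. Cardiac beats follow the
stage-scheduled mean IBI and jitter SD; the gamma-shaped beat kernel is
evaluated at fractional-sample offsets (quantizing beat times to the
12.5 Hz grid would fabricate ≈ 35 ms of spurious IBI variance, swamping
the programmed jitter). Pulse amplitude is 2.0 µM HbO / −0.5 µM HbR
(≈ 0.01 raw OD oscillation on shorts, typical of scalp-coupled optodes).
Motion spikes are shared step+decay events (0.3/min, 0.08 OD, τ = 3 s),
drift is a random cubic (0.02 OD), and detector noise is white in OD —
4·10⁻⁴ on long channels (consistent with a ~64 dB long-channel SNR) and
1·10⁻⁴ on shorts, which collect roughly an order of magnitude more
light. Voltages are V = dark + V₀·10^(−ΔOD).

*Behavior.* The eye-state stream is a deterministic duty cycle: within
each 8 s block the eyes are closed for exactly the stage's PERCLOS
fraction (0.02/0.05/0.09), so block-wise PERCLOS steps cleanly at
transitions; 2 s yawns mark each upward transition, with sub-threshold
distractor events included. Self-reports read the true stage at each
report time.

*Cohorts.* Subjects share the fixed stage effects and differ by
N(0, 0.1²) µM hemodynamic intercepts, lognormal(0, 0.06) β-variance
factors, lognormal(0, 0.1) jitter factors, and independently drawn
transition times — the random-intercept structure the mixed model
assumes. `simulate_feature_cohort` draws window-level features directly
from that model (160 windows/subject, stage split 0.45/0.25/0.30 as in
the reported window counts) and is used for the 200-replicate null
calibration, where the quantity under test is the model fit, not the
signal chain; the direction-pattern checks do run the full signal
pipeline on 3 seeded 11-subject cohorts per paradigm.

*What passing does not show.* The generator's noise is stationary and
Gaussian within stages, artifacts are stylized, the superficial layer
mixes linearly and identically across wavelengths, and behavioral
streams are far cleaner than video-derived measures on humans. Passing
tests demonstrate correctness of the implementation under the assumed
forward model and adequate power at the programmed effect sizes — not
that real recordings satisfy those assumptions, and not any particular
human cohort's effect sizes.

## Problem sizes

Tests and the acceptance script use full-length 81-minute sessions
throughout; replicate counts are scaled to the machine: 50 trials for
denoising and labeling recovery, 200 feature-level null replicates,
3 full-pipeline cohort replicates per paradigm, 100 null replicates in
the acceptance script.

## Known limitations

Degrees of freedom for mixed-model contrasts are asymptotic; with few
subjects and strong imbalance the adjusted p-values are mildly
anticonservative. The EDF writer covers only the minimal header needed
here. The dual short-channel regression assumes wavelength-matched
regressors (no cross-wavelength terms). Downward transitions rely on
PERCLOS alone and inherit its 8 s resolution.
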