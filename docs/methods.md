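# Methods

`respsym` analyzes synchronized resting recordings of ECG, continuous
arterial pressure, respiration and the integrated muscle sympathetic
nerve activity (MSNA) neurogram, and quantifies how the respiratory
cycle modulates sympathetic outflow and hemodynamics. Because raw
microneurography recordings of this kind are rarely shareable, the
package pairs the analysis with a synthetic-signal generator carrying
exact ground truth, so that every estimator is validated by parameter
recovery rather than against reference data.

## The analysis

**Landmarks.** R waves are detected by thresholded peak picking with a
0.25-s refractory constraint (explicit annotations pass through
unchanged). Heart rate is computed beat to beat (60/RR). For each
cardiac cycle the diastolic point is the pressure minimum in a window
`[R − 0.1 s, R + 0.4·RR]`; systolic pressure is the maximum and mean
arterial pressure (MAP) the mean ("modulus") of the waveform between
adjacent diastolic points, pulse pressure their difference. The
respiratory trace is zero-phase low-pass filtered (1 Hz) before
prominence-based extremum detection; each candidate extremum is then
refined to the raw-trace extremum within ±0.25 s because smoothing
shifts the extrema of asymmetric breaths. Inspiration is trough → peak,
expiration peak → trough; partial breaths and beats at the record edges
are discarded rather than extrapolated. Breath amplitude is normalized
to the subject's largest breath (so its mean is a within-subject
percentage with the largest breath at 100%).

**Bursts.** The integrated neurogram is normalized to the tallest
burst after subtracting a robust baseline; the baseline noise SD is
estimated as 1.4826× the median absolute deviation of the samples at or
below the median (bursts contaminate only the upper tail). Detection
smooths the trace with a 0.2-s Hann window matched to the burst
envelope, keeps local maxima above `snr_min` (default 3) times the
smoothed trace's noise SD, and refines peak time and amplitude on the
unsmoothed trace. Each candidate is assigned to the most recent R wave
whose lag lies within the latency window (default 0.8–1.8 s, bracketing
the peroneal conduction delay); at most one burst per cardiac cycle is
kept (the tallest). Latency is measured R wave → burst *peak*. The mean
latency shifts the neurogram (and burst times) backward so bursts align
with their cycle of origin; the trailing region without source data is
NaN. Resting MSNA is expressed as bursts/100 heartbeats, bursts/min and
total burst area/s (summed interval area over window duration, in % of
the tallest burst — the integral-over-duration convention implied by
"area/s" with units of %).

**Respiratory phases.** Each inspiratory and expiratory period is
divided into five equal intervals (half-open, so every sample belongs
to exactly one interval). Two composite phases are assembled per
breath: inspiration/postinspiration = inspiratory intervals 4–5 plus
expiratory intervals 1–3; mid-late expiration = expiratory intervals
4–5 plus inspiratory intervals 1–3 of the *following* breath. The
following-breath composition makes the two phases alternate
contiguously through the record; the alternative (same-breath) reading
is available via `boundary_policy="preceding"`. Phase instances missing
their cross-breath partner at the record boundary are dropped, and a
phase instance is removed whole when any member sample exceeds the
artifact threshold (default 150% of the tallest burst) or overlaps a
user-supplied artifact mask. Heartbeats are assigned to phases by raw
R-wave time (the latency shift aligns bursts to their cycle of origin,
making the two timelines commensurate); bursts by shifted peak time.
Phase metrics are burst incidence (bursts/100 HB), burst frequency
(bursts/min), total area/s and mean area/s, and the modulation summary
is the absolute and percent change from mid-late expiration to
inspiration/postinspiration — negative values mean inspiratory
inhibition.

**Sympathetic baroreflex sensitivity (sBRS).** For each diastolic
pressure it is determined whether a burst occurred in the *following*
cardiac cycle, and the mean of the shifted normalized neurogram in
±0.4 s around the following cycle's R wave is sampled. Occurrence
probability (%) and mean area (%) are aggregated in 1-mmHg diastolic
bins; the slope of the count-weighted linear regression on bin pressure
is the sBRS (solved in closed form from the weighted normal equations).
A fit requires ≥3 bins spanning ≥3 mmHg (bin coverage); otherwise the
result is flagged unavailable rather than raised, mirroring per-subject
missingness in cohorts. Bins with n = 1 are retained (the weighting
already down-weights them).

**Per-breath coupling.** Respiratory sinus arrhythmia (RSA) is the
max − min of beat-to-beat heart rate between adjacent end-expiration
points (= respiratory troughs); Traube–Hering (TH) amplitude is the
max − min of beat-wise MAP between one end-expiration point and the
next *plus 1 s* (the extension applies to TH only). Respiratory-
modulated MSNA is the integral of the raw, unshifted neurogram over
1.5× the inspiratory duration from inspiration onset (V·s on the raw
voltage scale; a normalized variant is config-switchable). Per-subject
product-moment correlations couple this measure to TH amplitude of the
same breath and of the adjacent breaths (lags −1, 0, +1), with a
"significant positive" flag at p < 0.05 and r > 0.

**Cohort statistics.** Respiratory sympathetic modulation is tested by
a split-plot mixed ANOVA (phase within, group between, partial η² per
effect; pingouin). Group comparisons use one-way ANOVA unless a
Shapiro–Wilk pre-check (α = 0.05 per group) fails, in which case
Kruskal–Wallis is used; Welch's ANOVA is available as an explicit mode.
Pairwise follow-ups are Bonferroni-adjusted: Dunn-type mean-rank
comparisons (tie-corrected) after Kruskal–Wallis, two-sample t tests
otherwise. Proportions are compared by χ² (no continuity correction),
switching to the Fisher exact test for sparse 2×2 tables; a zero margin
returns p = 1 (the proportions are identical by construction), and
sparse tables wider than 2×2 fall back to χ² with a flag. Correlations
between the percent change in burst incidence and resting SBP/DBP/MAP
and resting burst incidence use Pearson's r when both variables pass
the normality pre-check in the subset at hand, Spearman's ρ otherwise,
pooled and per group (skipped below n = 5).

## The generator

A subject is generated from one seed spawning three independent
substreams (respiration, cardiac, MSNA), so changing e.g. the neurogram
noise cannot perturb the respiratory realization.

*Respiration* is built from raised-cosine breaths — monotone rise over
`insp_fraction` of the period, monotone fall over the rest, smooth at
both landmarks — with independent normal breath-to-breath period and
amplitude variability (defaults: period CV 0.10, amplitude CV 0.15;
the literature gives no variability statistics, so these are exposed,
realistic placeholders).

All respiratory modulation uses `m(t) = −cos(2π·phase-within-breath)`:
−1 at end-expiratory troughs, +1 mid-breath, so heart rate and MAP
bottom out at end expiration.

*Cardiac.* Instantaneous heart rate is `hr_base + (rsa_amp/2)·m(t)`;
R times advance by forward (Euler) integration, i.e. each RR interval
is set from the rate at the beat onset. This makes the recovered
beat-to-beat heart rate a point sample of the modulation waveform —
with trapezoidal integration the paper-style max−min RSA estimator
would additionally be attenuated by beat averaging. Each cycle's
pressure waveform is a raised-cosine upstroke (rise time 0.3 RR) to
SBP followed by a linear decay to the next cycle's DBP. Beat-wise SBP
and DBP are co-modulated by three terms: the respiratory (TH) term
`(th_amp/2)·m(t − th_lag_s)`, a slow Mayer-band sinusoid (`bp_lf_amp`,
default 4 mmHg peak-to-peak at 0.1 Hz, random phase) and iid per-beat
jitter (`dbp_jitter_sd`, default 1 mmHg). A small per-beat offset makes
each cycle's waveform mean equal the target beat-wise MAP exactly, so
the per-beat MAP series point-samples the modulation.

*MSNA.* For each cardiac cycle a burst occurs with probability
`clip(p_phase + (baro_slope/100)·ΔDBP_prev, 0, 1)`, where `p_phase` is
`burst_prob_insp` when the cycle's R wave falls in the composite
inspiration/postinspiration window (last 40% of inspiration + first
60% of expiration) and `burst_prob_exp` otherwise, and `ΔDBP_prev` is
the *previous* cycle's **non-respiratory** diastolic deviation (slow
wave + jitter, mean-centered). Two deliberate choices here:

1. *Previous cycle.* The sBRS analysis pairs a diastolic pressure with
   burst occurrence in the following cycle; gating on the same cycle's
   DBP would attenuate the recovered slope roughly tenfold through the
   low lag-1 autocorrelation of the respiratory DBP wave.
2. *Non-respiratory deviation.* The within-breath baroreflex action of
   the TH wave itself is already expressed by the two phase-gated
   probabilities — exactly the decomposition the respiratory-phase
   analysis measures. Gating on the full DBP (TH included) at
   physiological magnitudes (th_amp 10–13 mmHg, slope −5 %/mmHg) swings
   the probability by ±0.25–0.3 phase-locked to respiration and
   erases the configured inspiratory–expiratory contrast. With the
   decomposition, `burst_prob_*` and `baro_slope` are independently
   recoverable; the sBRS measured on a full default subject is an
   emergent mixture of both mechanisms, as in real recordings.

An occurring burst is a raised-cosine pulse (width 0.5 s) centered
`burst_latency_s` (default 1.3 s) after the R wave, with gamma
amplitude (mean 1 V, CV 0.25). Bursts that would be clipped by the
record edge are suppressed and excluded from ground truth. Noise is
Gaussian, low-pass filtered at 8 Hz and scaled to `noise_sd`: the
residual noise of a rectified, leaky-integrated (0.1-s time constant)
neurogram is band-limited but substantially broader-band than the burst
envelope — this separation is what makes matched smoothing effective in
detection. An optional mode (`th_msna_coupling > 0`) scales each
breath's TH amplitude by that breath's burst mass in the same window
the coupling analysis samples, producing a causally coupled MSNA→TH
system for validating the lagged-correlation analysis.

*Cohort.* The default three-group cohort emulates young female, young
male and postmenopausal female resting physiology (group medians:
HR 62/58/64 beats/min, SBP 136/125/146, DBP 78/69/72 mmHg, TH
12/13/6 mmHg, RSA 6/8/3 beats/min, breath period 4.1/4.5/4.6 s, burst
probabilities 0.65→0.40 / 0.62→0.38 / 0.82→0.74, baroreflex slope
−5.3/−7.1/−3.4 %/mmHg). The postmenopausal-like group therefore has a
higher resting burst incidence (~78 vs ~51 bursts/100 HB), roughly a
quarter of the young groups' inspiratory–expiratory contrast (−10% vs
−38% change in burst probability), and smaller TH/RSA oscillations.
Between-subject variability is independent normal per parameter
(e.g. SD 0.06 on each burst probability, 2 mmHg on th_amp, 5 beats/min
on hr_base), with probabilities clipped to [0.02, 0.98].

## What the generator does and does not emulate

It reproduces the *statistical* structure the analysis assumes:
pulse-synchronous bursts at a fixed latency, phase-gated and
pressure-gated occurrence, respiratory modulation of HR and MAP with
breath-to-breath variability, and band-limited neurogram noise. It does
not attempt realistic ECG morphology (an impulse train suffices for
R-wave timing), biophysical pressure-wave shapes, burst-amplitude
baroreflex modulation (only occurrence is pressure-gated), apnea or
deep-breathing protocols, arrhythmia/ectopy, or movement artifacts.
Passing recovery tests therefore demonstrates that the estimators
measure what they claim under the stated model — not that they are
robust to every pathology of real microneurography data.

## Validation experiments and problem sizes

All validation is by simulation at fixed, stated sizes: phase-grid
geometry on 1,000 randomized breath sets; the weighted sBRS regression
against a statsmodels WLS oracle on 1,000 random bin tables plus one
hand-computed example (slope exactly −50 %/mmHg); percent-change
recovery with probabilities 0.8/0.2 over ~300 breaths × 20 seeds
(expected −75%) and an equal-probability null × 50 seeds; RSA/TH
recovery on noise-free subjects at HR 70 beats/min and 5-s breaths
(≈5.8 beats/breath — the max−min estimators subsample the within-breath
waveform, so dense beat sampling is the appropriate benchmark; the
residual ~7% negative bias at this density is inherent to the
estimator, not a defect); latency recovery at default noise; baroreflex
slope recovery at ~600 cycles × 20 seeds with equal phase probabilities
and th_amp = 0 (isolating the gated mechanism); detection sensitivity/
false-discovery at burst SNR 5 × 20 seeds; statistics-layer calibration
on 500 null replicates; and 100 end-to-end cohort replicates (4-min
records at 100 Hz, n = 12/12/13) for the phase×group interaction.
`scripts/acceptance.py` re-runs all of these from scratch and writes
the measured quantities to JSON.

## Numerical conventions, degenerate inputs, limitations

Interval and phase membership is half-open `[start, end)`; events on a
boundary belong to the later interval. Samples are assigned to
intervals by `ceil` of the boundary-sample index, so contiguous
intervals tile without overlap. Neurogram integration clips negative
excursions at zero and treats NaN (shifted tail) as zero contribution.
Degenerate inputs raise informative errors (flat pressure, monotone
respiration, no bursts above threshold, empty windows) or are flagged
rather than raised where the quantity is legitimately missing per
subject (insufficient sBRS bins, undefined percent change when the
expiratory value is zero, constant series in correlations). The
pipeline records stage failures per subject and continues the cohort.

Known limitations: burst *area* metrics are within-subject quantities
only (normalization to the tallest burst removes absolute scale);
Fisher's exact test is applied only to 2×2 tables; the mixed ANOVA
assumes the two-level within factor (no sphericity issues arise with
two levels); and the max−min RSA/TH estimators carry the sampling bias
discussed above, which is a property of the published estimator itself.
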