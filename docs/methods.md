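# Methods

This note documents the models, estimators and numerical choices behind
`ultradian`, and what the synthetic benchmark does and does not establish.

## The physiological setting

Small nocturnal rodents such as the Djungarian hamster organise their
metabolism in ultradian rhythms (URs): oscillations of oxygen consumption
(MR), core body temperature (T_b) and locomotor activity with periods between
0.3 and 6 h, much shorter than the circadian day.  Continuous indirect
calorimetry at 1-min resolution resolves three coexisting UR classes,
distinguished by amplitude and period:

| class  | period      | MR amplitude above RMR |
|--------|-------------|------------------------|
| small  | ~1 h        | ~+20%                  |
| medium | ~1.5–2.2 h  | ~+50%                  |
| large  | ~2–5 h      | >+100%                 |

Large bursts are accompanied by locomotor activity, a lagged T_b rise and a
drop of the respiratory exchange ratio (RER) toward lipid oxidation; small
bursts are of purely metabolic origin.  During the light (resting) phase the
burst amplitudes are attenuated by roughly 40%.  The package implements the
full analysis chain for such recordings — period detection, burst extraction,
energy partitioning, longitudinal synchrony, and an IR-thermography activity
index — together with a synthetic generator that emulates the recordings'
statistical structure so every stage can be validated against known truth.

## Synthetic generator

A day is 1440 one-minute samples.  MR is a flat resting baseline
(`rmr_level`, default 1.0 mL O2 min⁻¹) plus three quasi-periodic trains of
positive bursts with default periods 1.0 / 2.0 / 3.5 h and amplitudes 0.2 /
0.5 / 1.2 × RMR.

**Pulse shape.** Each burst is an asymmetric raised-cosine-squared (Hann²)
pulse with per-class rise/decay feet of (13, 30), (40, 55) and (70, 100) min.
The 13-min small-class rise matches the reported rise time of small metabolic
bursts; the large pulse's FWHM (~85 min) matches the reported 1–2 h duration
of large bursts.  The smooth shape was chosen deliberately: pulse trains with
sharp corners put 2nd/3rd-harmonic power of the large class at the same
periodogram level as the small class's fundamental, which makes the weakest
class undetectable at the 1:6 amplitude ratio.  Hann² pulses also keep long
near-zero tails, so the summed trains still expose the resting baseline
between bursts — the property the RMR envelope estimator relies on.

**Timing jitter.** Events are displaced independently from a regular grid by
lognormal factors sized so that inter-burst spacing has CV = 0.15 around the
class period.  The displacement is *phase-stable* (errors do not accumulate):
a renewal process with the same spacing CV accumulates phase error across the
day and smears the single-day periodogram peak of the fast class into the
background, which contradicts the sharp peaks seen in real single-day
records.

**Circadian gating.** Burst amplitudes are multiplied by
(1 − `circadian_attenuation`) (default 0.4) when the burst peak falls in the
light phase, half-open [08:00, 16:00).

**Coupled channels.** Each burst independently drives T_b and activity with a
per-class coupling probability (defaults: T_b 0.32/1.0/1.0, activity
0.56/0.79/1.0, mirroring the reported fractions of small/medium bursts that
lack a T_b or activity response).  T_b is the burst drive passed through a
first-order low-pass with a 10-min time constant (thermal inertia; the
constant is a modelling choice, the source data only show that T_b stays
elevated after a burst).  RER dips from 0.96 to 0.84 with the large-class
unit pulse; the dip is deliberately not gated so that every large burst
reaches the same minimum RER.  Noise is additive Gaussian per channel
(defaults: MR 0.05 mL O2 min⁻¹, T_b 0.05 °C, RER 0.01, activity 1 count);
activity is floored at zero and rounded to integer counts.

**Day-to-day drift.** Log-periods follow one shared Gaussian random walk
(SD `period_drift` = 0.05/day) plus independent per-class jitter
(SD 0.025/day), so classes co-vary without being harmonics.  0.05/day gives a
~±25% period range over three weeks — the lower end of the variability seen
in real time-courses.  Larger drift pushes realized periods across the class
bands, which scrambles band-fallback classification on days where fewer than
three peaks are detected; this is a known limitation of fixed-band class
assignment, not of the generator.

**Surface-temperature traces.** The 1-s hamster trace has a per-minute SD of
0.05 + 0.08 × activity °C (motion shakes the surface the camera sees); two
cage-floor traces sit at ambient (~15 °C) and rise to ~33 °C during
outside-nest episodes, which default to the spans of injected large bursts.

What the generator does *not* emulate: torpor, ambient-temperature dynamics,
slow RMR trends within a day, feeding-related RER excursions, or any
mechanistic coupling between the three oscillator classes beyond the shared
period drift.  Passing tests therefore demonstrate that the estimators
recover the structure they assume, not that real recordings satisfy those
assumptions.

## Wavelet period detection

`morlet_cwt` implements the continuous wavelet transform with the analytic
Morlet wavelet (centre frequency ω₀ = 6) in Fourier space, zero-padded to the
next power of two, on a log-spaced period grid with dj = 1/50 octave
sub-steps restricted to 0.3–6 h.  Period = Fourier factor × scale with the
standard Morlet factor 4π/(ω₀ + √(2+ω₀²)).  Power is bias-rectified
(|W|²/scale) so equal-amplitude sinusoids give equal periodogram peaks across
the band.  The cone of influence (e-folding distance √2·s) is recorded per
time point; COI-affected samples are *included* in the time-averaged
periodogram (the analysis averages full 24-h windows).  Sensitivity: masking
the COI mainly depresses the longest periods; since class assignment already
ignores peaks above 5 h (see below), the choice does not affect the class
periods in practice.  Up to 5% missing samples are linearly interpolated;
more is an error.

**Shuffle surrogates.** Significance is assessed against surrogates obtained
by randomly permuting the original samples (destroying all autocorrelation,
keeping the marginal distribution); the per-period threshold is the k-th
largest surrogate periodogram value with k = floor(α(n+1)).  Under
exchangeability the marginal rate of `real > threshold` is exactly k/(n+1):
with the conventional n = 150 at α = 0.05 that is 7/151 ≈ 0.046; n = 59 at
α = 0.05 (3/60) and n = 99 at α = 0.01 (1/100) are exact.  The calibration
test counts one period bin per replicate because all bins of one record share
the same surrogate set — only across-replicate flags are independent
Bernoulli trials to which a binomial reference applies.

**Peak detection.** When a surrogate threshold is attached, peaks are local
maxima of the signal-to-noise curve (periodogram / threshold) with
significance SNR > 1 and a minimum separation of 12 grid steps (~¼ octave,
the practical resolution of the ω₀ = 6 Morlet).  No prominence gate is
applied in this mode: a prominence threshold proportional to the maximum
power silently discards the small-amplitude class, whose power is only a few
percent of the large class's.  Without a threshold (e.g. for clean test
signals) peaks are found on the raw periodogram with a 1% prominence gate.

## Class assignment

Three usable peaks are assigned small/medium/large by ascending period —
this mirrors observed "compressed" days where, e.g., periods 1.1/1.33/1.91 h
still represent the three classes.  With more than three significant peaks
the strongest peak per fallback band (small < 1.25 h ≤ medium < 2.4 h ≤
large) is retained first, because a dominant class often splits into several
nearby maxima that would crowd out a weak class under global top-3 selection.
With fewer than three, peaks fall into the bands directly; two peaks
colliding in one band are split by ascending period onto that band's class
and the next one up.  Peaks above 5 h are ignored entirely: in a 24-h record
the 4.8-h and 6-h harmonics of the circadian cycle leak into the top of the
analysis band and are not ultradian oscillators.

## Burst extraction

For each class, a search window equal to the class period slides over the
channel; a candidate local maximum is kept if it is the maximum of its own
window, and candidates closer than half a period collapse onto the larger
one.  The burst minimum is the *last* occurrence of the lowest value within
one period before the peak (so rise time is measured from the end of the
preceding trough).  A burst is dropped only when that minimum-search window
extends before the record start.  Two filters keep small/medium statistics
"close to baseline": (i) a candidate whose peak lies within 5 min of a peak
already claimed by a larger class is the same event and is flagged
superimposed; (ii) a candidate whose minimum sits above the RMR envelope
plus 25% of the day's mean large-burst amplitude is riding on a larger burst.
Both thresholds are package choices; the source procedure states the
exclusion only qualitatively.  Co-amplitudes over the rise window are
channel[t_peak] − channel[t_min], with T_b read 10 min after the peak to
respect the thermal lag.

## RMR envelope and energy budget

MR is smoothed with 6-min running averages; a rolling minimum with a window
equal to the day's large-class period (fallback 3 h) anchors the burst
minima; anchors sitting more than 1% of the series range above the local
floor (rolling minimum over a doubled window) are pruned — a window whose
bursts overlap end-to-end never touches the baseline and would otherwise
drag the envelope up — and the envelope interpolates linearly between the
surviving anchors.  The doubled-window local reference keeps the estimator
local, so a genuine step in RMR is still tracked.  An alternative
(`method="minima"`) averages only the anchored minima.  The ultradian series
is max(MR − envelope, 0) and the resting series the remainder, so
DEE = RMR energy + ultradian energy and mean MR = RMR mean + ultradian mean
hold exactly by construction.  Energy uses
HP [mW] = (4.44 + 1.43·RER)·VO₂ [mL O2 h⁻¹], integrated per minute; missing
RER samples are filled with the day's 30-min running average.

## Synchrony

Day-by-day class periods per variable form a time-course; Pearson
correlations (two-sided p, pairwise-complete days, at least 5 pairs) are
computed for class pairs within variables and variable pairs within classes.
No multiplicity adjustment is applied — significance counting follows the
raw p < 0.05 convention of the summary it reproduces.  Pearson rather than
rank correlation because the relationship of interest is the linear co-drift
of periods.  Detection gaps concentrate in the small class of T_b and
activity (weak coupling, thermal low-pass), so their comparisons are often
reported missing; MR-internal synchrony is the robust signal, matching the
source's observation that MR classes synchronise best.

## Thermovision

The activity index is the per-minute sample SD (ddof = 1) of the 1-s hamster
surface-temperature trace; sample rather than population SD is a convention
choice.  A minute counts as outside-nest when either cage-floor trace
exceeds 30 °C for at least 30 of its 60 samples (the ≥30/60 rule formalises
an otherwise qualitative definition); contiguous minutes merge into episodes.  MR–activity
regressions can be computed on z-scored activity so transmitter counts and
the IR index (different units) yield comparable slopes.

## Problem sizes and tolerances

The validation suite uses 20 seeded days for period recovery (median
absolute relative error of recovered periods < 10% per class), 100
replicates × 59 shuffles for surrogate calibration, 5-day means for the
cold-challenge contrast, and noise-free days for the exact checks (budget
closure to machine precision, burst amplitudes exact, energy-fraction
recovery within 2% relative).  These sizes keep the full suite and the
acceptance script each within a few minutes on one CPU while leaving the
Monte-Carlo tolerances comfortably binding.

## Known limitations

* Period estimates are quantised to the 1/50-octave grid (~1.4% steps).
* The fixed class bands misassign periods on days when drift carries a class
  across a band edge and fewer than three peaks are detected.
* The shuffle null is white noise with the sample's marginal distribution;
  strongly autocorrelated backgrounds (not modelled here) would need
  autocorrelation-preserving surrogates.
* The RMR envelope assumes bursts are positive excursions from a slowly
  varying baseline; sustained elevations longer than the large-class period
  are absorbed into RMR.
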