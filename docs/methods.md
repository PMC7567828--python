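# Methods

This note documents the models and numerical choices behind
`spindletools`: what each stage computes, which parameters matter, what
the synthetic generator does and does not emulate, and where the design
was genuinely open.

## Signal model and preprocessing

All analyses operate on uniformly sampled voltage traces in microvolts
with time in seconds from recording start; intervals are half-open
`[start, end)` and hypnogram epoch `k` covers `[k, k+1)` seconds (1-s
epochs by default). Wide-band acquisition chains are reduced to the 1000
Hz analysis rate by `decimate_to_target`: an order-8 Chebyshev type I
low-pass (edge 400 Hz, 0.05 dB passband ripple) applied zero-phase
(forward and reverse), then integer-factor sample picking. Zero-phase
application squares the magnitude response; the package's own tests use
the squared response as the oracle, not the single-pass design curve.

Band-pass filtering everywhere uses window-based (Hamming) FIR designs
applied forward and reverse. The two reference orders — 6000 taps for the
slow-wave band (0.5–4 Hz) and 333 for the spindle band (9–16 Hz) — are
defined at 1000 Hz and scaled proportionally to other sampling rates,
since a fixed tap count changes its transition width with the rate. The
6000-tap filter is applied by FFT convolution with reflect padding of
three filter lengths, which is numerically equivalent to direct
`filtfilt` away from the edges and tractable on hour-long traces.

## Spindle detection

Detection is threshold-crossing on band-averaged wavelet energy:

1. **Wavelet energy.** Continuous wavelet transform with the complex
   frequency B-spline wavelet (order m = 2, bandwidth f_b = 1, center
   frequency f_c = 1 by default; all three overridable and tunable by the
   screening module). `|W(f, t)|²` is averaged over a 0.5-Hz grid spanning
   9–16 Hz. Scales map to frequencies through each wavelet's analytic
   center frequency; per-scale L2 normalization is used. Signals are
   mirror-padded by the largest wavelet support so edges carry no spurious
   energy.
2. **Smoothing.** Convolution with a unit-area 200-ms Hann kernel.
3. **Dual threshold.** Candidates exist where smoothed energy exceeds
   mean + 3 SD of the baseline and extend outward to the surrounding
   crossings of mean + 1 SD. The baseline is the set of NREM-scored
   samples when a hypnogram is supplied (avoiding wake-artifact inflation
   of the SD), otherwise the whole trace; this scope is recorded in the
   run metadata. Thresholds are data-relative, so detection is invariant
   to global amplitude rescaling.
4. **Event filters.** Duration must lie in 0.4–2 s; the number of
   positive local maxima of the 9–16 Hz filtered trace inside the event
   (the cycle count) must lie in 5–30; and the event's Hann-periodogram
   band power in 9–16 Hz must be at least that of both flanking bands
   (6–8.5 and 16.5–20 Hz), computed over the event extent.
5. **Features.** Central frequency is the 9–16 Hz argmax of the
   zero-padded amplitude spectrum (padding to at least 8x the event
   length and to ≤ 0.15 Hz resolution). Peak-to-peak amplitude is max −
   min of the band-passed trace in the event. Symmetry is the relative
   position of the smoothed-energy argmax within the event: 0.5 is fully
   symmetric; < 0.5 is a leftward (waxing-weighted) peak. The vigilance
   state is the label with the largest temporal overlap (ties resolve to
   the midpoint's epoch).

Candidates are thresholded on the full trace and state-labeled
afterwards; detections during wake/REM are reported as "spindle-like
events" rather than suppressed, since band-limited wake/REM transients
(fast theta) are a real phenomenon a user may want to inspect.

## Wavelet screening

The screening criterion is *normalized spindle power*: mean band energy
over annotated spindle samples divided by the mean over all other
samples. Free parameters (B-spline order ∈ {1,2,3}, bandwidth ∈ {0.5, 1,
1.5, 2}, center frequency ∈ {0.5, 1, 1.5}) are tuned by exhaustive grid
search with a deterministic first-in-grid tie-break; families without
free parameters are single grid points. Twenty-one standard continuous
families are screened by default (frequency B-spline, complex Morlet,
Shannon, Morlet, Mexican hat, complex and real Gaussian derivatives of
orders 1–8); the list is configuration, not a fixed claim.

On synthetic recordings the frequency B-spline family scores at or above
the complex Morlet when the background contains adjacent-band theta: the
B-spline's compactly supported frequency window rejects 6–10 Hz activity
that leaks through the Morlet's Gaussian tails. On a background with no
adjacent-band structure the two families are near-equivalent, which is
the expected matched-filter behavior.

## State dynamics

Rates are events per minute; events attribute to episodes and windows by
their midpoint. NREM episodes are maximal label runs classified by
successor (N2R → REM, N2W → wake); the final, right-censored episode is
excluded. Pre-transition profiles use windows of 5–40 s (5-s steps)
ending at the transition; windows are clipped to the episode start and
clipped windows contribute their covered duration to the denominator, so
short episodes never bleed events from the preceding state. Slow
dynamics use a 30-min moving window sliding by 5 min; windows with under
one NREM minute are flagged and carry no rate rather than a zero.
Undefined rates (zero dwell time) are always `None`, never 0.

## Units and coupling

**Spikes** are threshold crossings of the 600–4000 Hz elliptic-filtered
(order 4, 0.1 dB ripple, 40 dB stopband, zero-phase) wide-band trace at
7.5x the median of the absolute filtered signal — a median-based scale
that is robust to the spikes themselves. Both polarities are grouped
within a 1-ms refractory window and timed at the extremum. Spike sorting
is out of scope; trains may also be supplied externally.

**Bursts** are maximal runs of ≥ 3 spikes with all inter-spike intervals
< 6 ms whose first spike follows ≥ 50 ms of silence — the classic
low-threshold calcium-spike burst criterion.

**Spike–field coupling** extracts ±250 ms of the 9–16 Hz filtered LFP
around each spindle's central peak (the filtered-trace local maximum
nearest the spindle midpoint; equidistant ties take the earlier peak),
collects spikes in the same frames, and cross-correlates the
across-spindle mean LFP with the trial-averaged firing rate (10-ms
windows sliding 2 ms). The coupling value is the peak normalized
cross-correlation within ±100 ms; positive lag means spikes follow the
LFP. The value is invariant to LFP rescaling. Note the absolute scale
depends on the rate-curve window: a perfectly delta-locked train cannot
reach 1.0 because a 10-ms boxcar bump train carries harmonic energy a
sinusoidal field does not; smoothly rate-modulated trains (intensity
affine in the field) recover values near 1. Validation therefore uses
rate-modulated constructions and checks lag recovery to ±2 ms (the grid
step) and monotonicity in the generator's coupling parameter.

**SW–spindle coupling** averages the 0.5–4 Hz trace and the Hilbert
envelope of the 9–16 Hz trace over [−1, +2] s around spindle onsets and
reports their peak normalized cross-correlation within ±500 ms. Averages
whose SD falls below 1e−4 of the raw-signal SD are flagged degenerate
(no slow-wave content) instead of returning a meaningless ratio.

**UP states** are positive half-waves of the zero-phase 0.5–4 Hz
filtered trace, from negative-to-positive zero crossing to the next
positive-to-negative one, kept when ≥ 200 ms long and with peak
amplitude at least the global mean of the absolute filtered trace
("peak" is the documented reading of the amplitude rule; positive
deflection = UP is a configurable sign convention). A spindle coincides
with UP states when its overlap with their union reaches 50% of the
spindle duration (with a 1e−9 s tolerance so exact ties count).

**Delta power during spindles** is the 0.5–4 Hz Hann-periodogram power
of a 4-s window centered on each spindle midpoint, averaged over events;
windows that would cross the recording edge drop the event with a
warning.

## Synthetic polysomnography

The generator is the package's ground-truth factory. It emulates:

- **State structure**: a semi-Markov Wake/NREM/REM chain (exponential
  bout durations with floors; REM entered only from NREM; means 80/120/60
  s with floors 10/30/10 s) at 1-s epochs.
- **Background**: 1/f noise (exponent 1.0, SD 30 µV), NREM slow waves
  (0.5–4 Hz band noise, SD 100 µV, cosine-ramped at state edges), and
  6–10 Hz wake/REM theta (SD 40 µV). The theta band deliberately overlaps
  the 9–16 Hz detection band at its lower edge, producing the wake
  "spindle-like events" seen in real recordings.
- **Spindles**: an inhomogeneous Poisson process over NREM at 3 min⁻¹,
  multiplied by `pre_rem_boost` (default 3.0) in the final 25 s of
  episodes that end in REM. Carrier frequency and duration are truncated
  normals (mode 12.5 Hz, SD 1.5, on 9–16 Hz; mode 0.85 s, SD 0.3, on
  0.4–1.5 s) — unimodal, tapering at the range edges as empirical spindle
  distributions do — with a duration floor of 5.5 cycles so every
  generated event is a spindle by the ≥ 5-cycle definition. The waveform
  is a sinusoid under a wax–sustain–wane envelope (quarter-sine ramps
  over 25% of the duration on each side around a gently tented middle
  whose apex position, drawn uniformly in [0.3, 0.7], encodes asymmetry);
  a pure Hann envelope was rejected because it leaves half the nominal
  duration near zero amplitude, which no visually marked spindle does.
  Events keep ≥ 1 s separation and stay fully inside their NREM episode.
- **Amplitude**: expressed as SNR = peak envelope / SD of the 9–16 Hz
  component of the spindle-free NREM background. The default operating
  point is SNR 8, the saturated regime of the detector's
  sensitivity–SNR curve (which rises from ~0.3 at SNR 3 to ~1.0 at SNR
  8 under the fixed 3 SD/1 SD thresholds), representative of thalamic
  LFP where spindles are visible by eye. Tests at SNR 2–10 exercise the
  unsaturated regime.
- **Spikes**: Poisson thinning with intensity λ₀(1 + κ·max(0, sin θ)),
  where θ is the spindle's carrier phase shifted by a configurable lag;
  κ ∈ [0, 1] controls locking strength. Accepted spikes are replaced by
  3–5-spike, < 6 ms-ISI bursts with probability `burst_p`. All draws come
  from one counter-based Philox stream keyed by the config seed (spikes
  use a jumped substream), so output is bit-reproducible across
  platforms.

What the generator does **not** emulate: K-complexes, infra-slow sigma
modulation, artifacts (movement, electrical), realistic spindle
refractory dynamics beyond the fixed gap, volume conduction between
channels, and spindle–SW phase preference unless `sw_lock_spindles` is
set. Passing tests on this generator therefore demonstrate correctness
of the pipeline's measurements under the stated statistical structure,
not field performance on real recordings; the detector's absolute
sensitivity on real data depends on the true spindle SNR distribution,
as the sensitivity–SNR curve makes explicit.

Known quantitative caveat: non-overlap and episode-edge rejection make
the realized NREM spindle rate fall ~3–8% below the configured
intensity; rate-recovery tests allow for this placement loss.

## Numerical choices and degenerate inputs

- Ties: grid search takes the first grid point; symmetry takes the first
  energy argmax; central-peak ties take the earlier peak; state ties take
  the midpoint epoch.
- Degenerate inputs warn and return empty rather than raise where the
  input is plausible (flat signal, SD = 0 baseline, no spikes); they
  raise where the request is incoherent (empty interval lists, zero
  variance in a correlation, bands beyond Nyquist).
- Hypnogram/signal length mismatches truncate to the shorter with a
  warning, never silently.
- Detection is fully deterministic: identical input and config byte-match
  across runs.

## Validation scale

The validation suite runs on desk-scale problem sizes chosen as the
package's own test conditions: a 60-minute default-condition recording
(~100–120 ground-truth spindles) for sensitivity/false-discovery, 50
one-minute randomized fixtures for bound compliance, a 25-minute
dense-spindle recording (~95 events) for coupling recovery, 4 simulated
hours of state structure (≥ 20 NREM→REM transitions) for the
pre-REM-enrichment recovery, and 1000 random trains for burst-oracle
equivalence. Scoring uses a 50%-of-the-shorter-interval overlap rule for
matching detections to ground truth, and false discoveries are counted
among NREM-labeled detections (wake/REM detections are the separately
reported spindle-like events).
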