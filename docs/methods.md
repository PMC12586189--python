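# Methods

## The measurement model

Respiratory heart-rate variability (RespHRV) is quantified from event
trains, not from raw waveforms: heartbeats (R-waves or systolic
pressure peaks) and respiratory cycles (onset, end-inspiration, end).
Instantaneous HR is the piecewise-constant tachogram `HR(t) = 60/RRᵢ`
on each inter-beat interval — piecewise-constant rather than linear
because beat timing is event-based, and because it makes the degenerate
cases (constant rate, step modulation) exact.

The triggered average resamples HR onto a respiratory-phase grid of
`n_bins = 100` bins spanning one full cycle from each end-inspiration
to the next, and averages bins across cycles. Two design points:

- **Phase normalization, two segments.** Breath periods vary (the
  generator default CV is 0.1, matching visibly irregular rodent
  breathing), so fixed-duration windows would smear the expiratory
  trough. Beyond plain per-cycle normalization, the expiratory segment
  (end-inspiration → next inspiration onset) and the inspiratory
  segment (onset → next end-inspiration) are normalized separately,
  with the junction pinned at a common phase. The inspiration onset is
  taken from the breath train, never assumed to sit at a fixed
  fraction. Single-segment normalization leaves the inspiratory peak
  jittering by the period CV across cycles, which attenuates the
  average measurably.
- **Finite-RR de-smearing.** Each tachogram value is the mean of the
  underlying rate over the beat interval containing it (IPFM makes
  this exact: `∫ m dt = 60` per interval), and beats fall at
  effectively uniform offsets relative to respiratory phase. The
  triggered average is therefore the rate profile convolved with a
  triangular kernel of half-width RR — harmonic k of the cycle profile
  is multiplied by `sinc²(k·RR/T)`. At mouse rates (RR ≈ 0.113 s
  against a 0.48 s breath) the fundamental is attenuated to ≈ 0.83,
  i.e. a naive max − min underestimates the true depth by ~17%.
  `resphrv_amplitude` inverts this per harmonic before taking
  max − min. A harmonic is corrected only while its transfer exceeds
  `1/max_gain` (default 1/3); harmonics attenuated further carry
  mostly beat-sampling artifacts and are dropped rather than
  amplified, so the cutoff adapts to the beat-to-breath ratio —
  dense-beat recordings keep more harmonics. The correction uses the
  measured mean RR and mean cycle period; `deconvolve=False` returns
  the raw excursion (and is the path used by the exact step-modulation
  identities). Consequences worth knowing: the corrected amplitude is
  *not* exactly equivariant under rescaling the HR signal, because the
  physical RR enters the correction; the raw amplitude is.

mHR is the time average of the tachogram over the epoch, which equals
the duration-weighted mean rate (total beats × 60 / total time) and is
unbiased for the IPFM mean rate.

**Cycle-count policies.** Averages are refused (`CycleShortfallError`,
CLI exit code 2) when an epoch holds fewer complete cycles than the
condition requires: 40 (freely moving), 15 (anesthetized, working
heart–brainstem preparation), 100 (stress protocol). Stimulation
epochs default to analyzing their final 30 s, where effects are maximal
and stable.

**Stability profile.** `stability_profile` computes sliding-window
RespHRV amplitudes and flags stability when their coefficient of
variation falls below a configurable bound (default 0.1). This
windowed-CV rule is this package's own heuristic, not a published
criterion.

## Event detection

- **Beats.** Local maxima above `threshold_fraction` (default 0.5) of
  a 2 s *centered* rolling-maximum amplitude estimate, separated by a
  30 ms refractory (margin above 1000 bpm, mouse scale), with
  parabolic sub-sample refinement. The fractional threshold makes
  detection gain-invariant; the centered window tracks slow amplitude
  drift while keeping both signal edges covered (a one-sided window
  leaves one edge with a noise-level estimate, and a single false beat
  splits an RR interval and corrupts the triggered average).
- **Breaths.** The signal is smoothed (20 ms), a 1 s rolling-median
  baseline is removed, and onsets are placed at upward zero crossings.
  Two scale-invariant cleanup rules: candidate cycles shorter than
  `min_cycle` merge into their successor, and candidates whose peak is
  below 25% of the median peak merge into their predecessor — the
  latter removes noise re-crossings on the expiratory decay, which
  otherwise appear as spurious short cycles and attenuate the
  triggered average. End-inspiration timing then comes from a
  matched filter: every cycle is resampled onto a phase grid
  normalized by its own period, averaged into a template, and
  re-aligned to the template by zero-normalized cross-correlation
  (offset- and gain-invariant, so baseline wander cannot bias the
  match), iterated three times. The template's absolute peak is
  located by a cubic fit, whose odd term absorbs the asymmetry of the
  inspiratory peak that biases a plain parabola. Cycle amplitude is
  intra-cycle peak minus trough of the baseline-removed signal, which
  is exact for the generator's waveform (a rolling-median reference
  sits mid-waveform on an all-positive pleth signal and would bias the
  amplitude). Onset placement inherits the mid-rise bias of
  zero-crossing detection; end-inspiration, the quantity the averaging
  consumes, does not.
- **Bursts.** Regions above baseline + `threshold_sd` × a robust
  (MAD) noise estimate over a 1 s rolling-median baseline, with
  isolated sub-blip excursions dropped before gap merging (a noise
  spike just ahead of a burst would otherwise merge in and drag the
  onset early), gaps under `min_interval` merged, and regions shorter
  than `min_duration` discarded.

Detector edge behavior: events within roughly one baseline window of
the recording edges (and cycles clipped by the recording span) carry
degraded baselines and are not guaranteed; fidelity statements in the
test suite apply to interior events.

## Nerve metrics

Respiratory modulation reuses the phase-averaging machinery on the
integrated nerve signal (cycles may come from a breath train or from
detected burst onsets); `modulation_percent` normalizes the max − min
excursion by the epoch mean (a reference-value normalization is
available via a flag, since the normalization convention is not fixed
by common usage). Synaptic drive rectifies the outward-positive
current, low-passes at 10 Hz — a Bessel filter, whose near-monotone
step response avoids the overshoot a Butterworth would add to the
per-burst maxima — and averages baseline-subtracted per-burst maxima
over the first ten consecutive bursts of the epoch (earliest-first is
deterministic; the count is configurable).

## Effect statistics

`epoch_delta` keeps full precision internally and rounds to integers
only in `report()`, mirroring how such effects are normally printed.
Group effects carry both conventions explicitly: `per_subject_mean`
(mean of per-animal deltas; the default, since printed group Δ%
values are generally consistent with this convention and not with the
delta of group means) and `group_mean_delta`. The SEM always describes
the per-subject deltas. Pearson correlation and the regression line
come from `scipy.stats.linregress` (two-sided p from the t transform
with n − 2 df). `recovery_kinetics` reports per-bin percent deltas
versus the pre-stress baseline and the first bin within the criterion
band (default ±10%; the stress fixtures in the tests use ±15% to
accommodate estimator noise at the bin length used).

## The synthetic generator

The generator emulates the study conditions, not generic signals:

| parameter | default | meaning |
|---|---|---|
| `base_frequency` | 125 cpm | awake mouse breathing rate |
| `frequency_cv` | 0.1 | cycle-period variability (gamma periods) |
| `inspiration_fraction` | 0.33 | fraction of cycle in inspiration |
| `amplitude_mean`, `amplitude_cv` | 1.0 a.u., 0.1 | per-cycle pleth peak |
| `base_hr` | 532 bpm | resting freely-moving mHR |
| `resp_mod_depth` | 13.2 bpm | resting RespHRV depth D |
| `gain` | 1.0 | multiplier on D (the modeled oxytocin effect) |
| `hr_noise_sd`, `hr_noise_tau` | 3 bpm, 0.4 s | non-respiratory HR fluctuation |
| `mhr_shift` | 0 bpm | additive rate shift (epoch overrides) |
| `resp_lag` | 0 s | cardiac–respiratory latency |

Beats are IPFM events of `m(t) = base_hr + mhr_shift +
gain·D·s(t − resp_lag) + noise`, integrated by trapezoid on a 1 kHz
grid and inverted by linear interpolation; constant-rate intervals are
exact to machine precision, and modulated beat times match a 50× finer
integration to well under 1 ms. The modulation waveform `s` is a
raised cosine over the full cycle peaking at mid-inspiration,
zero-mean with peak-to-trough 1, so the true depth *is* `gain·D`. The
HR noise is additive, zero-mean Gaussian with a short correlation time
(first-order autoregression): strictly white noise on `m(t)` would be
annihilated by the integrator (beat-time jitter ∝ √dt), making the
effective noise level grid-dependent; the correlated form has a
grid-independent beat-to-beat standard deviation equal to
`hr_noise_sd` and keeps triggered averaging unbiased. The default
cardiac–respiratory lag is zero — a convention, since only the phase
relationship's sign (HR maximal in inspiration) is established.

Rendered channels: ECG as a Mexican-hat QRS template per beat (1 kHz
minimum), plethysmography as a smooth rise to the end-inspiratory peak
and cosine decay (2 kHz, inspiration-positive), and three nerve
surrogates — phrenic-like square inspiratory bursts, cardiac-vagal-like
tonic activity with multiplicative respiratory modulation minimal in
inspiration, and inhibitory-current volleys peaking mid-inspiration.
Channel noise is white Gaussian (defaults: SNR 20 for session
rendering). Epoch parameter changes are stepwise with a continuously
running beat integrator; protocol constructors cover the 1-min
photostimulation schedule and a restraint-stress session (10 min
pre-stress, 10 min restraint with halved gain / raised rate and
breathing, 70 min recovery with immediate or delayed gain
restoration, assessment bins 25–35 and 55–65 min post stress).

What the generator does **not** emulate: ECG morphology beyond a
stereotyped QRS (no P/T waves, no ectopy), blood-pressure waveform
shape beyond systolic peaks, movement artifacts and electrode noise,
sighs and apneas, state transitions in breathing, or conductance-based
neuron dynamics. Passing tests therefore demonstrate correctness of
the quantification pipeline under controlled conditions with known
ground truth — not robustness to every artifact of real recordings.

## Problem sizes and numerical choices

The test suite and the acceptance script use 60–120 s sessions
(~125–250 breathing cycles, ~530–1060 beats) for parameter recovery,
20-seed ensembles for the stochastic claims, and ~80 min event-level
sessions (no raw-channel rendering) for the stress-recovery pattern —
sizes chosen so each recovery claim rests on at least the
policy-minimum cycle count with seconds-scale runtimes. Times are
0-based seconds; epochs are half-open `[start, end)` so every instant
and cycle belongs to exactly one epoch. All randomness flows from a
single integer seed through `numpy.random.default_rng`; sessions are
bit-reproducible for a fixed seed, and every output table embeds the
seed and a hash of the configuration.

## Known limitations

- The de-smearing correction assumes beats sample respiratory phase
  approximately uniformly; strong cardiorespiratory phase-locking
  (integer rate ratios with near-zero period variability) slows the
  convergence of the triggered average and weakens the correction's
  expectation argument.
- Amplitude recovery is validated to ~±5% at mouse rates; conditions
  with fewer than ~4 beats per breath push more harmonics below the
  recoverable-transfer cutoff and the corrected estimate degrades
  toward the fundamental-only reconstruction.
- Detected cycle onsets are zero crossings of the baseline-removed
  signal and sit systematically after the true inspiratory onset on
  all-positive waveforms; analyses that need onset-accurate timing
  should use the phrenic/burst channel instead.
- The stability flag is a windowed-CV heuristic of this package.
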