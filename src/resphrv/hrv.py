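"""Respiratory-triggered heart-rate averaging and per-epoch metrics.

The central quantity is the RespHRV amplitude: heart rate (HR) is
resampled onto a common respiratory-phase grid spanning one full cycle
from each end-inspiration to the next, averaged across cycles, and the
amplitude is the peak-to-trough excursion of that average — maximal HR
in inspiration minus minimal HR in expiration.

Because instantaneous HR derived from beat intervals is a moving average
of the underlying rate over each inter-beat interval, the triggered
average is attenuated at high breathing-to-beat frequency ratios (at
mouse rates, RR ≈ 0.11 s against a 0.48 s breath, the fundamental is
attenuated by ~9%). :func:`resphrv_amplitude` therefore applies an
optional per-harmonic 1/sinc de-smearing before taking max − min; see
the methods note for the derivation and its limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import BreathTrain, EventSeries, SampledSignal

__all__ = [
    "CycleShortfallError",
    "ConditionPolicy",
    "POLICIES",
    "TriggeredAverage",
    "EpochMetrics",
    "StabilityProfile",
    "instantaneous_hr",
    "phase_average",
    "triggered_average",
    "resphrv_amplitude",
    "epoch_metrics",
    "stability_profile",
]


class CycleShortfallError(ValueError):
    """Raised when an epoch holds fewer respiratory cycles than the
    condition policy requires for a stable triggered average."""


@dataclass(frozen=True)
class ConditionPolicy:
    """Analysis conventions for one experimental condition."""

    name: str
    min_cycles: int
    window_s: float  # default analysis window taken from the end of an epoch


#: Minimum averaged-cycle counts per condition: 40 for freely moving
#: mice, 15 for anesthetized animals and the working heart–brainstem
#: preparation, 100 for the stress/chemogenetic protocol.
POLICIES = {
    "freely_moving": ConditionPolicy("freely_moving", 40, 30.0),
    "anesthetized": ConditionPolicy("anesthetized", 15, 30.0),
    "whbp": ConditionPolicy("whbp", 15, 30.0),
    "stress": ConditionPolicy("stress", 100, 300.0),
}


def _resolve_policy(policy) -> ConditionPolicy:
    if isinstance(policy, ConditionPolicy):
        return policy
    try:
        return POLICIES[policy]
    except KeyError:
        raise ValueError(f"unknown condition policy {policy!r}; "
                         f"expected one of {sorted(POLICIES)}") from None


@dataclass(frozen=True)
class TriggeredAverage:
    """Phase-binned mean HR over respiratory cycles.

    ``mean_hr[j]`` is the across-cycle mean at phase ``phase_grid[j]``
    (bin centers on [0, 1), phase 0 = the triggering end-inspiration).
    ``mean_rr_s`` and ``mean_period_s`` carry the context needed for
    finite-RR de-smearing; they are ``None`` for averages constructed
    directly from binned values.
    """

    phase_grid: np.ndarray
    mean_hr: np.ndarray
    n_cycles: int
    trigger: str = "end_inspiration"
    mean_rr_s: float | None = None
    mean_period_s: float | None = None


@dataclass(frozen=True)
class EpochMetrics:
    label: str
    mhr: float                # bpm
    resphrv_amplitude: float  # bpm
    resp_frequency: float     # cycles per minute
    resp_amplitude: float     # a.u.
    n_cycles: int


@dataclass(frozen=True)
class StabilityProfile:
    times: np.ndarray        # window centers, s
    amplitudes: np.ndarray   # bpm
    cv: float
    stable: bool
    cv_bound: float


def instantaneous_hr(beats: EventSeries, out_rate: float = 250.0) -> SampledSignal:
    """Piecewise-constant instantaneous HR in bpm.

    ``HR(t) = 60/RRᵢ`` held constant over each inter-beat interval
    ``[bᵢ, bᵢ₊₁)``, sampled at ``out_rate`` from the first to the last
    beat. Piecewise-constant (not linear) interpolation matches the
    event-based nature of beat timing.
    """
    if len(beats) < 2:
        raise ValueError("instantaneous HR requires at least 2 beats")
    t0, t_end = beats.times[0], beats.times[-1]
    n = int(np.floor((t_end - t0) * out_rate)) + 1
    t = t0 + np.arange(n) / out_rate
    idx = np.clip(np.searchsorted(beats.times, t, "right") - 1, 0,
                  len(beats) - 2)
    hr = 60.0 / np.diff(beats.times)[idx]
    return SampledSignal(hr, out_rate, t0, "bpm")


def _cycle_triplets(breaths: BreathTrain, start: float, end: float,
                    span: tuple[float, float]):
    """(end-inspᵢ, onsetᵢ₊₁, end-inspᵢ₊₁) for consecutive cycles fully
    inside the epoch and the signal span."""
    ei = breaths.end_inspirations
    lo = max(start, span[0])
    hi = min(end, span[1])
    ok = (ei >= lo) & (ei <= hi)
    idx = np.flatnonzero(ok)
    pairs = [i for i, j in zip(idx[:-1], idx[1:]) if j == i + 1]
    if not pairs:
        return (np.empty(0),) * 3
    i = np.array(pairs)
    return ei[i], breaths.onsets[i + 1], ei[i + 1]


def phase_average(signal: SampledSignal, breaths: BreathTrain,
                  n_bins: int = 100, min_cycles: int = 1,
                  epoch: tuple[float, float] | None = None,
                  trigger: str = "end_inspiration") -> TriggeredAverage:
    """Average any sampled signal onto a respiratory-phase grid.

    Each cycle (one end-inspiration to the next) is resampled onto
    ``n_bins`` phase-bin centers by zero-order hold, then bins are
    averaged across cycles. Phase normalization (rather than fixed
    windows) keeps variable-period cycles aligned, and the expiratory
    and inspiratory segments are normalized separately — the next
    cycle's inspiration onset (taken from the breath train, not an
    assumed fixed fraction) is pinned to a common phase, so cycles with
    different inspiratory timing stay aligned at both trigger and onset.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    start, end = epoch if epoch is not None else (-np.inf, np.inf)
    ei0, on1, ei1 = _cycle_triplets(breaths, start, end,
                                    (signal.t0, signal.t_end))
    n_cyc = ei0.size
    if n_cyc < min_cycles:
        raise CycleShortfallError(
            f"epoch holds {n_cyc} complete respiratory cycles but the "
            f"policy requires at least {min_cycles}")
    phase = (np.arange(n_bins) + 0.5) / n_bins
    # common junction phase = mean expiratory fraction of the grid
    r = float(np.mean((on1 - ei0) / (ei1 - ei0)))
    expir = phase < r
    tau = np.empty((n_cyc, n_bins))
    tau[:, expir] = ei0[:, None] + (phase[expir] / r) * (on1 - ei0)[:, None]
    tau[:, ~expir] = on1[:, None] + (((phase[~expir] - r) / (1 - r))
                                     * (ei1 - on1)[:, None])
    mean_vals = signal.sample_previous(tau).mean(axis=0)
    return TriggeredAverage(phase, mean_vals, n_cyc, trigger,
                            mean_rr_s=None,
                            mean_period_s=float(np.mean(ei1 - ei0)))


def triggered_average(hr: SampledSignal, breaths: BreathTrain,
                      n_bins: int = 100, min_cycles: int = 1,
                      epoch: tuple[float, float] | None = None) -> TriggeredAverage:
    """Respiratory-triggered average of HR aligned to end-inspiration."""
    ta = phase_average(hr, breaths, n_bins, min_cycles, epoch)
    start, end = epoch if epoch is not None else (hr.t0, hr.t_end)
    seg = hr.slice(max(start, hr.t0), min(end, hr.t_end))
    mean_rr = 60.0 / float(np.mean(seg.values))
    return TriggeredAverage(ta.phase_grid, ta.mean_hr, ta.n_cycles,
                            ta.trigger, mean_rr_s=mean_rr,
                            mean_period_s=ta.mean_period_s)


def _desmear(mean_hr: np.ndarray, width_fraction: float,
             max_harmonic: int, max_gain: float) -> np.ndarray:
    """Invert the inter-beat-interval moving average in the phase domain.

    Each instantaneous-HR value is the mean of the underlying rate over
    the beat interval containing it, and beats fall at uniformly random
    offsets relative to respiratory phase, so the triggered average is
    (in expectation) the rate profile convolved with a triangular kernel
    of half-width RR — transfer sinc²(k·RR/T) on harmonic k. A harmonic
    is corrected only while its transfer stays above ``1/max_gain``;
    harmonics attenuated further than that (or beyond ``max_harmonic``)
    carry mostly beat-sampling artifacts and are dropped rather than
    amplified. The cutoff therefore adapts to the beat-to-breath rate
    ratio: dense-beat recordings keep more harmonics.
    """
    n = mean_hr.size
    spec = np.fft.rfft(mean_hr)
    for k in range(1, spec.size):
        transfer = np.sinc(k * width_fraction) ** 2
        if k > max_harmonic or transfer < 1.0 / max_gain:
            spec[k] = 0.0
        else:
            spec[k] /= transfer
    return np.fft.irfft(spec, n=n)


def resphrv_amplitude(ta: TriggeredAverage, deconvolve: bool = True,
                      max_harmonic: int = 8, max_gain: float = 3.0) -> float:
    """RespHRV amplitude: max − min of the triggered average, in bpm.

    When the average carries beat-interval context (``mean_rr_s``), the
    finite-RR smearing is inverted first (see :func:`_desmear`); pass
    ``deconvolve=False`` for the raw excursion of the binned means.
    """
    y = np.asarray(ta.mean_hr, dtype=float)
    if deconvolve and ta.mean_rr_s and ta.mean_period_s:
        y = _desmear(y, ta.mean_rr_s / ta.mean_period_s, max_harmonic, max_gain)
    return float(np.max(y) - np.min(y))


def epoch_metrics(beats: EventSeries, breaths: BreathTrain,
                  epoch: tuple[float, float], policy="freely_moving",
                  label: str = "", n_bins: int = 100,
                  out_rate: float = 250.0,
                  deconvolve: bool = True) -> EpochMetrics:
    """mHR, RespHRV amplitude and respiratory statistics for one epoch.

    mHR is the time-average of instantaneous HR over the epoch;
    respiratory frequency is the cycle-onset count scaled to per minute;
    respiratory amplitude is the mean per-cycle peak amplitude (a.u.).
    Raises :class:`CycleShortfallError` when the epoch holds fewer
    complete cycles than the condition policy requires.
    """
    pol = _resolve_policy(policy)
    start, end = epoch
    if not end > start:
        raise ValueError("epoch must have positive duration")
    hr = instantaneous_hr(beats, out_rate)
    seg = hr.slice(max(start, hr.t0), min(end, hr.t_end))
    mhr = float(np.mean(seg.values))
    ta = triggered_average(hr, breaths, n_bins, pol.min_cycles, (start, end))
    amp = resphrv_amplitude(ta, deconvolve=deconvolve)
    n_onsets = breaths.count_onsets_in(start, end)
    freq = 60.0 * n_onsets / (end - start)
    sel = (breaths.onsets >= start) & (breaths.onsets < end)
    resp_amp = float(np.mean(breaths.amplitudes[sel])) if n_onsets else 0.0
    return EpochMetrics(label or pol.name, mhr, amp, freq, resp_amp,
                        ta.n_cycles)


def stability_profile(hr: SampledSignal, breaths: BreathTrain,
                      window: float, step: float,
                      n_bins: int = 100, min_cycles: int = 15,
                      cv_bound: float = 0.1,
                      deconvolve: bool = True) -> StabilityProfile:
    """Sliding-window RespHRV amplitudes and a stability flag.

    Windowed amplitudes whose coefficient of variation falls below
    ``cv_bound`` mark the recording segment as stable. This is a
    windowed-CV heuristic of this package, not a published criterion.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    t0, t_end = hr.t0, hr.t_end
    if t0 + window > t_end:
        raise ValueError("window longer than the recording")
    starts = np.arange(t0, t_end - window + 1e-9, step)
    times, amps = [], []
    for s in starts:
        ta = triggered_average(hr, breaths, n_bins, min_cycles,
                               (s, s + window))
        times.append(s + window / 2)
        amps.append(resphrv_amplitude(ta, deconvolve=deconvolve))
    amps = np.array(amps)
    mean = float(np.mean(amps))
    cv = float(np.std(amps) / mean) if mean > 0 else np.inf
    return StabilityProfile(np.array(times), amps, cv, cv < cv_bound,
                            cv_bound)
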