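"""Synthetic cardiorespiratory recordings with known ground truth.

The generator emulates the preparations used to quantify respiratory
heart-rate variability (RespHRV) in rodents:

* a breathing rhythm with distinct inspiratory/expiratory phases
  (awake mouse ≈ 125 cycles per minute, slower under anesthesia),
* a heartbeat point process whose instantaneous rate rises during
  inspiration — an integral pulse frequency modulation (IPFM) model in
  which a beat is emitted whenever the integral of the instantaneous
  rate crosses successive integers,
* a dimensionless ``gain`` multiplying the inspiratory modulation depth
  (the oxytocinergic amplification of RespHRV is modelled as a gain
  change), and per-epoch parameter overrides implementing stimulation
  and stress protocols,
* raw channels rendered from the event trains: telemetry-style ECG,
  whole-body plethysmography, and integrated nerve / patch-clamp
  current traces with inspiratory bursts.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.signal import lfilter

from .signals import BreathTrain, EventSeries, SampledSignal

__all__ = [
    "RespParams",
    "CardiacParams",
    "Epoch",
    "EpochSchedule",
    "GroundTruth",
    "Recording",
    "generate_breath_train",
    "simulate_beats_ipfm",
    "synthesize_ecg",
    "synthesize_pleth",
    "synthesize_nerve",
    "build_session",
    "photostim_schedule",
    "stress_schedule",
    "FREELY_MOVING_RESP",
    "FREELY_MOVING_CARDIAC",
    "NERVE_KINDS",
]


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class RespParams:
    """Breathing-rhythm parameters.

    base_frequency : cycles per minute (cpm).
    frequency_cv : coefficient of variation of the cycle period.
    inspiration_fraction : fraction of the cycle spent in inspiration.
    amplitude_mean / amplitude_cv : per-cycle peak amplitude (a.u.).
    """

    base_frequency: float = 125.0
    frequency_cv: float = 0.1
    inspiration_fraction: float = 0.33
    amplitude_mean: float = 1.0
    amplitude_cv: float = 0.1

    def __post_init__(self):
        if not self.base_frequency > 0:
            raise ValueError("base_frequency must be positive")
        if not 0 < self.inspiration_fraction < 1:
            raise ValueError("inspiration_fraction must lie in (0, 1)")
        for name in ("frequency_cv", "amplitude_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.amplitude_mean < 0:
            raise ValueError("amplitude_mean must be non-negative")


@dataclass(frozen=True)
class CardiacParams:
    """Heartbeat-generator parameters.

    base_hr : mean heart rate HR0, beats per minute (bpm).
    resp_mod_depth : peak-to-trough inspiratory modulation D, bpm.
    gain : dimensionless multiplier g on D (models the OT effect).
    hr_noise_sd : sd of the non-respiratory rate fluctuation, bpm.
    hr_noise_tau : correlation time of that fluctuation, s.
    mhr_shift : additive shift of the mean rate, bpm (epoch overrides).
    resp_lag : fixed cardiac–respiratory latency, s (default 0).
    """

    base_hr: float = 532.0
    resp_mod_depth: float = 13.2
    gain: float = 1.0
    hr_noise_sd: float = 3.0
    hr_noise_tau: float = 0.4
    mhr_shift: float = 0.0
    resp_lag: float = 0.0

    def __post_init__(self):
        if not self.base_hr > 0:
            raise ValueError("base_hr must be positive")
        if self.resp_mod_depth < 0:
            raise ValueError("resp_mod_depth must be non-negative")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.hr_noise_sd < 0:
            raise ValueError("hr_noise_sd must be non-negative")
        if self.base_hr + self.mhr_shift - self.gain * self.resp_mod_depth / 2 <= 0:
            raise ValueError("modulation would drive the instantaneous rate to zero")

    @property
    def mean_rate(self) -> float:
        return self.base_hr + self.mhr_shift


#: Freely-moving mouse defaults: resting HR 532 bpm with 13.2 bpm RespHRV
#: depth, breathing at 125 cpm (group means of the telemetry cohort).
FREELY_MOVING_RESP = RespParams()
FREELY_MOVING_CARDIAC = CardiacParams()


@dataclass(frozen=True)
class Epoch:
    """A named analysis/simulation window ``[start, end)`` with parameter
    overrides applied while it is active."""

    label: str
    start: float
    end: float
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError(f"epoch {self.label!r}: end must exceed start")


@dataclass(frozen=True)
class EpochSchedule:
    epochs: tuple

    def __post_init__(self):
        eps = tuple(self.epochs)
        for a, b in zip(eps[:-1], eps[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(f"epochs {a.label!r} and {b.label!r} overlap "
                                 "or are out of order")
        object.__setattr__(self, "epochs", eps)

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self):
        return len(self.epochs)

    @property
    def duration(self) -> float:
        return self.epochs[-1].end

    def __getitem__(self, label: str) -> Epoch:
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise KeyError(label)


@dataclass(frozen=True)
class GroundTruth:
    """Per-epoch true values recorded alongside a generated session."""

    beat_times: EventSeries
    breaths: BreathTrain
    epoch_labels: tuple
    true_mhr: dict           # label -> bpm (noise-free mean rate)
    true_resphrv: dict       # label -> bpm (gain * resp_mod_depth)
    true_resp_frequency: dict  # label -> cpm


@dataclass(frozen=True)
class Recording:
    """Rendered channels of one synthetic session."""

    channels: dict          # name -> SampledSignal
    beats: EventSeries
    breaths: BreathTrain
    schedule: EpochSchedule
    seed: int


# --------------------------------------------------------------------------
# breathing


def _draw_periods(rng, n, mean_period, cv):
    if cv == 0:
        return np.full(n, mean_period)
    # gamma keeps periods positive with the requested mean and CV
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, mean_period / shape, size=n)


def _draw_amplitudes(rng, n, mean, cv):
    if cv == 0 or mean == 0:
        return np.full(n, mean)
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, mean / shape, size=n)


def generate_breath_train(resp: RespParams, duration: float,
                          seed: int | np.random.Generator = 0) -> BreathTrain:
    """Draw respiratory cycles tiling ``[0, duration]``.

    Cycle periods are gamma-distributed around ``60/base_frequency`` with
    the stated CV; end-inspiration sits at
    ``onset + inspiration_fraction · period``. The final cycle may extend
    slightly past ``duration`` so that the train covers it completely.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_period = 60.0 / resp.base_frequency
    periods = []
    total = 0.0
    while total < duration:
        n = max(8, int((duration - total) / mean_period * 1.2) + 2)
        chunk = _draw_periods(rng, n, mean_period, resp.frequency_cv)
        periods.append(chunk)
        total += float(chunk.sum())
    periods = np.concatenate(periods)
    ends = np.cumsum(periods)
    onsets = ends - periods
    keep = onsets < duration - 1e-9
    onsets, ends, periods = onsets[keep], ends[keep], periods[keep]
    amps = _draw_amplitudes(rng, onsets.size, resp.amplitude_mean, resp.amplitude_cv)
    return BreathTrain(onsets, onsets + resp.inspiration_fraction * periods,
                       ends, amps)


def _cycle_index(breaths: BreathTrain, t: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(breaths.onsets, t, "right") - 1
    return np.clip(idx, 0, breaths.n_cycles - 1)


def respiratory_waveform(breaths: BreathTrain, t: np.ndarray) -> np.ndarray:
    """Unit cardiac modulation waveform s(t).

    A raised cosine over each full cycle, peaking at mid-inspiration:
    zero-mean over the cycle and peak-to-trough exactly 1, so the
    noiseless triggered-average amplitude equals ``gain·resp_mod_depth``.
    """
    t = np.asarray(t, dtype=float)
    i = _cycle_index(breaths, t)
    u = (t - breaths.onsets[i]) / breaths.periods[i]
    fi = breaths.inspiratory_fractions[i]
    return 0.5 * np.cos(2 * np.pi * (u - fi / 2))


# --------------------------------------------------------------------------
# heartbeats (IPFM)


def _ipfm_from_rate(t: np.ndarray, m_bpm: np.ndarray) -> np.ndarray:
    """Emit beat times where the integral of ``m/60`` crosses integers."""
    if np.any(m_bpm <= 0):
        raise ValueError("instantaneous rate driven to zero or below; "
                         "reduce modulation depth or noise")
    dt = t[1] - t[0]
    increments = (m_bpm[:-1] + m_bpm[1:]) * (dt / 120.0)  # trapezoid of m/60
    integral = np.concatenate(([0.0], np.cumsum(increments)))
    n_beats = int(math.floor(integral[-1] + 1e-12))
    if n_beats == 0:
        return np.empty(0)
    targets = np.arange(1, n_beats + 1, dtype=float)
    return np.interp(targets, integral, t)


def _rate_noise(rng, n, dt, sd, tau):
    """Zero-mean Gaussian rate fluctuation with correlation time ``tau``.

    Returned at unit sd; callers scale by the (possibly epoch-dependent)
    noise sd. ``tau == 0`` degrades to white noise on the grid.
    """
    white = rng.standard_normal(n)
    if tau <= 0 or sd == 0:
        return white
    a = math.exp(-dt / tau)
    x = lfilter([math.sqrt(1 - a * a)], [1.0, -a], white)
    return x


def simulate_beats_ipfm(cardiac: CardiacParams, breaths: BreathTrain,
                        duration: float, seed: int | np.random.Generator = 0,
                        grid_hz: float = 1000.0) -> EventSeries:
    """IPFM heartbeat train driven by the respiratory modulation.

    The instantaneous rate is
    ``m(t) = base_hr + mhr_shift + gain·D·s(t − resp_lag) + noise(t)``
    with ``s`` the unit waveform of :func:`respiratory_waveform`; a beat
    is emitted whenever ``∫ m/60 dt`` crosses the next integer.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if breaths.n_cycles == 0 or breaths.ends[-1] < duration - 1e-6:
        raise ValueError("breath train must cover the requested duration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / grid_hz
    t = np.arange(0.0, duration + dt / 2, dt)
    m = cardiac.mean_rate + cardiac.gain * cardiac.resp_mod_depth * \
        respiratory_waveform(breaths, t - cardiac.resp_lag)
    if cardiac.hr_noise_sd > 0:
        m = m + cardiac.hr_noise_sd * _rate_noise(
            rng, t.size, dt, cardiac.hr_noise_sd, cardiac.hr_noise_tau)
    return EventSeries(_ipfm_from_rate(t, m), label="beats")


# --------------------------------------------------------------------------
# channel rendering


def _qrs_template(offsets: np.ndarray, width: float) -> np.ndarray:
    """Mexican-hat QRS surrogate, peak 1 at offset 0."""
    s = width / 5.0
    z = offsets / s
    return (1 - z * z) * np.exp(-0.5 * z * z)


def synthesize_ecg(beats: EventSeries, duration: float, rate: float = 1000.0,
                   qrs_amplitude: float = 1.0, qrs_width: float = 0.02,
                   noise_sd: float = 0.0,
                   seed: int | np.random.Generator = 0) -> SampledSignal:
    """Render an ECG-like trace with one stereotyped QRS per beat."""
    if rate < 1000.0:
        raise ValueError("ECG sampling rate must be at least 1000 Hz")
    if beats.times.size > 1 and np.min(np.diff(beats.times)) < qrs_width:
        raise ValueError("inter-beat interval shorter than the QRS template width")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate)) + 1
    sig = np.zeros(n)
    half = int(math.ceil(qrs_width * rate)) + 1
    for b in beats.times:
        c = int(round(b * rate))
        i0, i1 = max(0, c - half), min(n, c + half + 1)
        if i1 <= i0:
            continue
        tt = np.arange(i0, i1) / rate - b
        sig[i0:i1] += qrs_amplitude * _qrs_template(tt, qrs_width)
    if noise_sd > 0:
        sig = sig + noise_sd * rng.standard_normal(n)
    return SampledSignal(sig, rate, 0.0, "mV")


def _pleth_waveform(breaths: BreathTrain, t: np.ndarray) -> np.ndarray:
    i = _cycle_index(breaths, t)
    on, ei, en = breaths.onsets[i], breaths.end_inspirations[i], breaths.ends[i]
    amp = breaths.amplitudes[i]
    insp = t < ei
    out = np.empty_like(t)
    u = np.clip((t[insp] - on[insp]) / (ei[insp] - on[insp]), 0, 1)
    out[insp] = amp[insp] * 0.5 * (1 - np.cos(np.pi * u))
    v = np.clip((t[~insp] - ei[~insp]) / (en[~insp] - ei[~insp]), 0, 1)
    out[~insp] = amp[~insp] * 0.5 * (1 + np.cos(np.pi * v))
    return out


def synthesize_pleth(breaths: BreathTrain, duration: float, rate: float = 2000.0,
                     noise_sd: float = 0.0,
                     seed: int | np.random.Generator = 0) -> SampledSignal:
    """Whole-body plethysmography surrogate.

    Each cycle rises smoothly over inspiration to its peak amplitude at
    end-inspiration, then decays over expiration (inspiration-positive
    sign convention).
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    sig = _pleth_waveform(breaths, t)
    if noise_sd > 0:
        sig = sig + noise_sd * rng.standard_normal(n)
    return SampledSignal(sig, rate, 0.0, "a.u.")


NERVE_KINDS = ("phrenic-like", "cardiac-vagal-like", "inhibitory-current")


def synthesize_nerve(breaths: BreathTrain, duration: float, kind: str,
                     burst_amplitude: float = 1.0, tonic_level: float = 0.0,
                     mod_fraction: float = 0.0, rate: float = 3000.0,
                     noise_sd: float = 0.0,
                     seed: int | np.random.Generator = 0) -> SampledSignal:
    """Integrated nerve / current channel surrogates.

    ``phrenic-like``
        square bursts of ``burst_amplitude`` spanning each inspiration on
        a ``tonic_level`` baseline.
    ``cardiac-vagal-like``
        tonic activity with multiplicative respiratory modulation of
        fractional peak-to-trough depth ``mod_fraction``, minimal during
        inspiration (inspiratory inhibition of cardiac vagal drive).
    ``inhibitory-current``
        smooth outward-current volleys peaking at ``burst_amplitude``
        mid-inspiration, emulating the inhibitory input to cardiac vagal
        motoneurons during inspiratory bursts.
    """
    if kind not in NERVE_KINDS:
        raise ValueError(f"unknown nerve kind {kind!r}; expected one of {NERVE_KINDS}")
    if not 0 <= mod_fraction <= 1:
        raise ValueError("mod_fraction must lie in [0, 1]")
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    i = _cycle_index(breaths, t)
    on, ei = breaths.onsets[i], breaths.end_inspirations[i]
    if kind == "phrenic-like":
        sig = tonic_level + burst_amplitude * ((t >= on) & (t < ei))
    elif kind == "cardiac-vagal-like":
        # unit waveform peaks mid-inspiration; negate so the trough is there
        sig = tonic_level * (1.0 - mod_fraction * respiratory_waveform(breaths, t))
    else:  # inhibitory-current
        insp = (t >= on) & (t < ei)
        bump = np.zeros(n)
        u = (t[insp] - on[insp]) / (ei[insp] - on[insp])
        bump[insp] = 0.5 * (1 - np.cos(2 * np.pi * u))
        sig = tonic_level + burst_amplitude * bump
    sig = np.asarray(sig, dtype=float)
    if noise_sd > 0:
        sig = sig + noise_sd * rng.standard_normal(n)
    units = "pA" if kind == "inhibitory-current" else "a.u."
    return SampledSignal(sig, rate, 0.0, units)


# --------------------------------------------------------------------------
# sessions


_RESP_FIELDS = {f.name for f in fields(RespParams)}
_CARDIAC_FIELDS = {f.name for f in fields(CardiacParams)}


def _apply_overrides(resp: RespParams, cardiac: CardiacParams, overrides: dict):
    r_kw, c_kw = {}, {}
    for key, val in overrides.items():
        if key in _CARDIAC_FIELDS:
            c_kw[key] = val
        elif key in _RESP_FIELDS:
            r_kw[key] = val
        else:
            raise ValueError(f"unknown parameter override {key!r}")
    return (replace(resp, **r_kw) if r_kw else resp,
            replace(cardiac, **c_kw) if c_kw else cardiac)


def _breaths_for_schedule(schedule: EpochSchedule, resp: RespParams, rng):
    """Draw cycles sequentially, each from the epoch containing its onset."""
    onsets, eis, ends, amps = [], [], [], []
    t = 0.0
    duration = schedule.duration
    epochs = list(schedule)
    while t < duration - 1e-9:
        params = resp
        for ep in epochs:
            if ep.start - 1e-12 <= t < ep.end:
                params, _ = _apply_overrides(resp, FREELY_MOVING_CARDIAC, ep.overrides)
                break
        period = float(_draw_periods(rng, 1, 60.0 / params.base_frequency,
                                     params.frequency_cv)[0])
        amp = float(_draw_amplitudes(rng, 1, params.amplitude_mean,
                                     params.amplitude_cv)[0])
        onsets.append(t)
        eis.append(t + params.inspiration_fraction * period)
        ends.append(t + period)
        amps.append(amp)
        t += period
    return BreathTrain(np.array(onsets), np.array(eis), np.array(ends),
                       np.array(amps))


def build_session(schedule: EpochSchedule,
                  resp: RespParams = FREELY_MOVING_RESP,
                  cardiac: CardiacParams = FREELY_MOVING_CARDIAC,
                  channels=("ecg", "pleth"),
                  seed: int = 0,
                  grid_hz: float = 1000.0,
                  ecg_rate: float = 1000.0,
                  pleth_rate: float = 2000.0,
                  ecg_noise_sd: float = 0.05,
                  pleth_noise_sd: float = 0.05,
                  nerve_kwargs: dict | None = None) -> tuple:
    """Render a full multi-epoch session and its ground truth.

    Per-epoch ``overrides`` may change any :class:`RespParams` or
    :class:`CardiacParams` field (e.g. ``gain``, ``mhr_shift``,
    ``base_frequency``); the heartbeat integrator runs continuously
    across epoch boundaries, so parameter changes are stepwise but the
    beat train has no seams.
    """
    rng = np.random.default_rng(seed)
    breath_rng, beat_rng, chan_rng = (np.random.default_rng(s)
                                      for s in rng.integers(0, 2 ** 31, 3))
    duration = schedule.duration
    breaths = _breaths_for_schedule(schedule, resp, breath_rng)

    dt = 1.0 / grid_hz
    t = np.arange(0.0, duration + dt / 2, dt)
    s_wave = respiratory_waveform(breaths, t - cardiac.resp_lag)
    m = np.empty_like(t)
    noise_sd_t = np.empty_like(t)
    covered = np.zeros(t.size, dtype=bool)
    true_mhr, true_depth, true_freq = {}, {}, {}
    for ep in schedule:
        _, cp = _apply_overrides(resp, cardiac, ep.overrides)
        rp, _ = _apply_overrides(resp, cardiac, ep.overrides)
        sel = (t >= ep.start) & (t < ep.end)
        m[sel] = cp.mean_rate + cp.gain * cp.resp_mod_depth * s_wave[sel]
        noise_sd_t[sel] = cp.hr_noise_sd
        covered |= sel
        true_mhr[ep.label] = cp.mean_rate
        true_depth[ep.label] = cp.gain * cp.resp_mod_depth
        true_freq[ep.label] = rp.base_frequency
    if not covered.all():  # gaps between epochs fall back to base params
        sel = ~covered
        m[sel] = cardiac.mean_rate + cardiac.gain * cardiac.resp_mod_depth * s_wave[sel]
        noise_sd_t[sel] = cardiac.hr_noise_sd
    if np.any(noise_sd_t > 0):
        m = m + noise_sd_t * _rate_noise(beat_rng, t.size, dt,
                                         1.0, cardiac.hr_noise_tau)
    beats = EventSeries(_ipfm_from_rate(t, m), label="beats")

    rendered = {}
    for name in channels:
        sub = np.random.default_rng(chan_rng.integers(0, 2 ** 31))
        if name == "ecg":
            rendered[name] = synthesize_ecg(beats, duration, ecg_rate,
                                            noise_sd=ecg_noise_sd, seed=sub)
        elif name == "pleth":
            rendered[name] = synthesize_pleth(breaths, duration, pleth_rate,
                                              noise_sd=pleth_noise_sd, seed=sub)
        elif name in NERVE_KINDS:
            kw = dict(nerve_kwargs or {})
            rendered[name] = synthesize_nerve(breaths, duration, name,
                                              seed=sub, **kw)
        else:
            raise ValueError(f"unknown channel {name!r}")

    truth = GroundTruth(beats, breaths, tuple(ep.label for ep in schedule),
                        true_mhr, true_depth, true_freq)
    return Recording(rendered, beats, breaths, schedule, seed), truth


def photostim_schedule(pre: float = 60.0, stim: float = 60.0,
                       post: float = 60.0, gain: float = 1.5,
                       mhr_shift: float = -35.0) -> EpochSchedule:
    """Baseline / 1-min photostimulation / recovery protocol.

    Defaults mirror the freely-moving optogenetic experiment: a 60 s
    stimulation that multiplies the RespHRV depth by 1.5 and lowers the
    mean rate by 35 bpm, flanked by unstimulated epochs.
    """
    return EpochSchedule((
        Epoch("baseline", 0.0, pre),
        Epoch("stim", pre, pre + stim,
              {"gain": gain, "mhr_shift": mhr_shift}),
        Epoch("recovery", pre + stim, pre + stim + post),
    ))


def stress_schedule(delayed_recovery: bool,
                    stress_gain: float = 0.5,
                    stress_mhr_shift: float = 90.0,
                    stress_freq_factor: float = 1.4,
                    restraint_min: float = 10.0,
                    recovery_delay_min: float = 45.0) -> EpochSchedule:
    """Restraint-stress protocol with timed post-stress bins.

    Timeline (minutes): 10 pre-stress rest, 10 restraint, then 70 of
    recovery. RespHRV depth is halved during restraint; with
    ``delayed_recovery`` the gain is restored only ``recovery_delay_min``
    minutes after the restraint ends (between the 25–35 and 55–65 min
    assessment bins), otherwise within the first 10 min. Mean rate and
    respiratory frequency rise during restraint and the first minutes
    after it, and recover quickly in both variants.
    """
    m = 60.0
    t_stress_end = 20 * m
    stressed = {"gain": stress_gain, "mhr_shift": stress_mhr_shift,
                "base_frequency": FREELY_MOVING_RESP.base_frequency
                * stress_freq_factor}
    early = {"gain": stress_gain, "mhr_shift": stress_mhr_shift / 2}
    gain_back = t_stress_end + (recovery_delay_min if delayed_recovery else 10.0) * m
    eps = [
        Epoch("pre_stress", 0.0, 10 * m),
        Epoch("restraint", 10 * m, t_stress_end, stressed),
        Epoch("post_early", t_stress_end, t_stress_end + 5 * m, early),
        Epoch("post_suppressed", t_stress_end + 5 * m, gain_back,
              {"gain": stress_gain}),
        Epoch("post_recovered", gain_back, t_stress_end + 70 * m),
    ]
    return EpochSchedule(tuple(eps))
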