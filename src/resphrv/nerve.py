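"""Respiratory modulation of nerve activity and in vitro drive metrics.

Covers the three nerve-level quantifications: the respiratory modulation
of an integrated nerve signal (e.g. the cardiac vagal branch), the
synaptic drive received by cardiac vagal motoneurons during inspiratory
bursts (max envelope of inhibitory current, averaged over ten
consecutive bursts), and inspiratory-burst frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import bessel, filtfilt

from .hrv import CycleShortfallError, phase_average
from .signals import BreathTrain, BurstSeries, SampledSignal

__all__ = [
    "ModulationResult",
    "SynapticDrive",
    "respiratory_modulation",
    "synaptic_drive",
    "burst_frequency",
]


@dataclass(frozen=True)
class ModulationResult:
    modulation_amplitude: float   # signal units, max − min of the cycle average
    modulation_percent: float     # % of the epoch mean (or reference)
    n_cycles: int
    normalization: str = "epoch_mean"


@dataclass(frozen=True)
class SynapticDrive:
    per_burst_amplitudes: np.ndarray  # signal units (pA), baseline-subtracted
    mean_amplitude: float
    n_bursts: int


def _bursts_to_cycles(bursts: BurstSeries) -> BreathTrain:
    """Treat consecutive burst onsets as cycle boundaries (burst onset =
    inspiration onset; the burst peak time stands in for end-inspiration)."""
    if bursts.n_bursts < 2:
        raise ValueError("need at least 2 bursts to define cycles")
    on = bursts.onsets[:-1]
    en = bursts.onsets[1:]
    ei = np.minimum(bursts.offsets[:-1], en - 1e-9)
    return BreathTrain(on, ei, en, np.ones_like(on))


def respiratory_modulation(nerve: SampledSignal, breaths_or_bursts,
                           epoch: tuple[float, float] | None = None,
                           n_bins: int = 100, min_cycles: int = 15,
                           normalization: str = "epoch_mean",
                           reference: float | None = None) -> ModulationResult:
    """Respiratory modulation of an integrated nerve signal.

    The signal is averaged across respiratory cycles on a phase grid
    (same machinery as the HR triggered average); the modulation
    amplitude is max − min of that average, and the percent is the
    amplitude relative to the epoch mean (``normalization="epoch_mean"``,
    the default) or to a caller-supplied ``reference`` value
    (``normalization="reference"``). Both are invariant under
    multiplicative rescaling of the signal.
    """
    if isinstance(breaths_or_bursts, BurstSeries):
        cycles = _bursts_to_cycles(breaths_or_bursts)
    else:
        cycles = breaths_or_bursts
    ta = phase_average(nerve, cycles, n_bins, min_cycles, epoch)
    amp = float(np.max(ta.mean_hr) - np.min(ta.mean_hr))
    if normalization == "epoch_mean":
        start, end = epoch if epoch is not None else (nerve.t0, nerve.t_end)
        seg = nerve.slice(max(start, nerve.t0), min(end, nerve.t_end))
        ref = float(np.mean(seg.values))
    elif normalization == "reference":
        if reference is None:
            raise ValueError("normalization='reference' requires a reference value")
        ref = float(reference)
    else:
        raise ValueError("normalization must be 'epoch_mean' or 'reference'")
    if abs(ref) <= 1e-3 * amp or (ref == 0.0 and amp == 0.0):
        raise ValueError("epoch mean is (near) zero; modulation percent "
                         "undefined")
    return ModulationResult(amp, 100.0 * amp / ref, ta.n_cycles, normalization)


def synaptic_drive(current: SampledSignal, bursts: BurstSeries,
                   n_bursts: int = 10, envelope_cutoff: float = 10.0,
                   invert: bool = False,
                   baseline_window: float = 0.2) -> SynapticDrive:
    """Per-burst maximal envelope amplitude of (inhibitory) current.

    The trace is oriented so outward current is positive (``invert``
    flips an inward-negative recording), rectified, and low-pass
    filtered at ``envelope_cutoff`` (default 10 Hz, separating the
    volley envelope from spiking texture at slice time scales). For each
    of the first ``n_bursts`` consecutive bursts the amplitude is the
    envelope maximum within the burst minus the median envelope in the
    ``baseline_window`` seconds preceding its onset.
    """
    if bursts.n_bursts < n_bursts:
        raise ValueError(f"synaptic drive requires {n_bursts} consecutive "
                         f"bursts, found only {bursts.n_bursts}")
    x = -current.values if invert else current.values
    x = np.maximum(x, 0.0)
    nyq = current.rate / 2
    if not 0 < envelope_cutoff < nyq:
        raise ValueError("envelope_cutoff must lie below the Nyquist frequency")
    # Bessel rather than Butterworth: its near-monotone step response
    # avoids overshoot that would inflate the per-burst maxima
    b, a = bessel(4, envelope_cutoff / nyq)
    env = filtfilt(b, a, x)
    amps = np.empty(n_bursts)
    for k in range(n_bursts):
        on, off = bursts.onsets[k], bursts.offsets[k]
        i0 = max(0, int(np.floor((on - current.t0) * current.rate)))
        i1 = min(env.size, int(np.ceil((off - current.t0) * current.rate)) + 1)
        j0 = max(0, int(np.floor((on - baseline_window - current.t0)
                                 * current.rate)))
        baseline = float(np.median(env[j0:i0])) if i0 > j0 else 0.0
        amps[k] = max(float(np.max(env[i0:i1]) - baseline), 0.0)
    return SynapticDrive(amps, float(np.mean(amps)), n_bursts)


def burst_frequency(bursts: BurstSeries, epoch: tuple[float, float]) -> float:
    """Burst-onset count within ``[start, end)`` scaled to per minute."""
    start, end = epoch
    if not end > start:
        raise ValueError("epoch must have positive duration")
    return 60.0 * bursts.count_onsets_in(start, end) / (end - start)
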