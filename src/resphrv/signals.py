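"""Core in-memory containers for sampled signals and event trains.

All times are seconds from recording start; epochs are half-open
intervals ``[start, end)`` so that every instant belongs to exactly one
epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampledSignal",
    "EventSeries",
    "BreathTrain",
    "BurstSeries",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled channel.

    Parameters
    ----------
    values : array of float
        Sample values.
    rate : float
        Sampling rate in Hz (> 0).
    t0 : float
        Time of the first sample, seconds.
    units : str
        Physical units of the samples (e.g. ``"mV"``, ``"bpm"``, ``"a.u."``).
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self):
        arr = _as_float_array(self.values, "values")
        if arr.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("signal values must be finite")
        if not (self.rate > 0):
            raise ValueError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, ``(n − 1)/rate`` seconds."""
        return (self.values.size - 1) / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    def sample_previous(self, t) -> np.ndarray:
        """Zero-order-hold evaluation at arbitrary times.

        Returns the value of the most recent sample at or before each
        requested time (clipped to the signal span).
        """
        idx = np.floor((np.asarray(t, dtype=float) - self.t0) * self.rate).astype(int)
        idx = np.clip(idx, 0, self.values.size - 1)
        return self.values[idx]

    def slice(self, start: float, end: float) -> "SampledSignal":
        """Samples with times in ``[start, end)``."""
        i0 = max(0, int(np.ceil((start - self.t0) * self.rate - 1e-9)))
        i1 = min(self.values.size, int(np.ceil((end - self.t0) * self.rate - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start}, {end}) of signal spanning "
                             f"[{self.t0}, {self.t_end}]")
        return SampledSignal(self.values[i0:i1], self.rate,
                             self.t0 + i0 / self.rate, self.units)


@dataclass(frozen=True)
class EventSeries:
    """Ordered point events (heartbeats, burst onsets) in seconds."""

    times: np.ndarray
    label: str = ""
    marks: np.ndarray | None = None

    def __post_init__(self):
        arr = _as_float_array(self.times, "times")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValueError("event times must be strictly increasing")
        object.__setattr__(self, "times", arr)
        if self.marks is not None:
            marks = np.asarray(self.marks)
            if marks.shape != arr.shape:
                raise ValueError("marks must match times in length")
            object.__setattr__(self, "marks", marks)

    def __len__(self) -> int:
        return self.times.size

    def count_in(self, start: float, end: float) -> int:
        return int(np.searchsorted(self.times, end, "left")
                   - np.searchsorted(self.times, start, "left"))

    def slice(self, start: float, end: float) -> "EventSeries":
        i0 = np.searchsorted(self.times, start, "left")
        i1 = np.searchsorted(self.times, end, "left")
        marks = None if self.marks is None else self.marks[i0:i1]
        return EventSeries(self.times[i0:i1], self.label, marks)

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass(frozen=True)
class BreathTrain:
    """A contiguous sequence of respiratory cycles.

    Each cycle ``i`` runs ``onsets[i] → ends[i]`` with its inspiratory
    peak (end-inspiration, the averaging trigger) at
    ``end_inspirations[i]`` and peak amplitude ``amplitudes[i]`` (a.u.).
    """

    onsets: np.ndarray
    end_inspirations: np.ndarray
    ends: np.ndarray
    amplitudes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        on = _as_float_array(self.onsets, "onsets")
        ei = _as_float_array(self.end_inspirations, "end_inspirations")
        en = _as_float_array(self.ends, "ends")
        if not (on.size == ei.size == en.size):
            raise ValueError("onsets, end_inspirations, ends must have equal length")
        if self.amplitudes is None:
            amp = np.ones_like(on)
        else:
            amp = _as_float_array(self.amplitudes, "amplitudes")
            if amp.size != on.size:
                raise ValueError("amplitudes must match cycle count")
            if np.any(amp < 0):
                raise ValueError("cycle amplitudes must be non-negative")
        if on.size:
            if not (np.all(on < ei) and np.all(ei < en)):
                raise ValueError("each cycle needs onset < end_inspiration < end")
            if on.size > 1 and np.any(on[1:] < en[:-1] - 1e-9):
                raise ValueError("cycles must be ordered and non-overlapping")
        object.__setattr__(self, "onsets", on)
        object.__setattr__(self, "end_inspirations", ei)
        object.__setattr__(self, "ends", en)
        object.__setattr__(self, "amplitudes", amp)

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def n_cycles(self) -> int:
        return self.onsets.size

    @property
    def periods(self) -> np.ndarray:
        return self.ends - self.onsets

    @property
    def inspiratory_fractions(self) -> np.ndarray:
        return (self.end_inspirations - self.onsets) / self.periods

    def select(self, start: float, end: float) -> "BreathTrain":
        """Cycles lying entirely within ``[start, end)``."""
        keep = (self.onsets >= start) & (self.ends <= end + 1e-9)
        return BreathTrain(self.onsets[keep], self.end_inspirations[keep],
                           self.ends[keep], self.amplitudes[keep])

    def count_onsets_in(self, start: float, end: float) -> int:
        return int(np.searchsorted(self.onsets, end, "left")
                   - np.searchsorted(self.onsets, start, "left"))


@dataclass(frozen=True)
class BurstSeries:
    """Detected bursts: ordered, non-overlapping ``[onset, offset]`` spans."""

    onsets: np.ndarray
    offsets: np.ndarray
    peak_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        on = _as_float_array(self.onsets, "onsets")
        off = _as_float_array(self.offsets, "offsets")
        if on.size != off.size:
            raise ValueError("onsets and offsets must have equal length")
        if self.peak_values is None:
            pk = np.full_like(on, np.nan)
        else:
            pk = _as_float_array(self.peak_values, "peak_values")
            if pk.size != on.size:
                raise ValueError("peak_values must match burst count")
        if on.size:
            if not np.all(on < off):
                raise ValueError("each burst needs onset < offset")
            if on.size > 1 and np.any(on[1:] < off[:-1]):
                raise ValueError("bursts must be ordered and non-overlapping")
        object.__setattr__(self, "onsets", on)
        object.__setattr__(self, "offsets", off)
        object.__setattr__(self, "peak_values", pk)

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def n_bursts(self) -> int:
        return self.onsets.size

    def count_onsets_in(self, start: float, end: float) -> int:
        return int(np.searchsorted(self.onsets, end, "left")
                   - np.searchsorted(self.onsets, start, "left"))
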