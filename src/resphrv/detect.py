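"""Event detection: heartbeats, respiratory cycles and nerve bursts.

Detectors operate on raw sampled channels (ECG or systolic pressure for
beats, whole-body plethysmography for breaths, integrated neurograms for
bursts) and return the event containers the averaging pipeline consumes.
Thresholds are fractional/robust so that rescaling a signal does not
change the detections.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import maximum_filter1d, median_filter, uniform_filter1d
from scipy.signal import find_peaks

from .signals import BreathTrain, BurstSeries, EventSeries, SampledSignal

__all__ = ["detect_beats", "segment_breaths", "detect_bursts"]


def _rolling_median(x: np.ndarray, rate: float, window: float,
                    approx_rate: float = 200.0) -> np.ndarray:
    """Rolling-median baseline, computed on a decimated copy for speed.

    The baseline varies on the `window` time scale, so estimating it at
    ~200 Hz and interpolating back loses nothing.
    """
    step = max(1, int(round(rate / approx_rate)))
    xs = x[::step]
    size = max(3, int(round(window * rate / step)) | 1)
    base = median_filter(xs, size=size, mode="nearest")
    if step == 1:
        return base
    idx = np.arange(x.size) / step
    return np.interp(idx, np.arange(xs.size), base)


def _refine_peak(x: np.ndarray, p: int) -> float:
    """Sub-sample peak position by parabolic interpolation."""
    if p <= 0 or p >= x.size - 1:
        return float(p)
    denom = x[p - 1] - 2 * x[p] + x[p + 1]
    if denom >= 0:
        return float(p)
    delta = 0.5 * (x[p - 1] - x[p + 1]) / denom
    return p + float(np.clip(delta, -0.5, 0.5))


def _quadratic_peak(y: np.ndarray, p: int, half: int) -> float:
    """Sub-sample peak position from a least-squares parabola fitted over
    ``±half`` samples; averages noise over the whole fit window instead of
    relying on three samples."""
    i0, i1 = max(0, p - half), min(y.size, p + half + 1)
    if i1 - i0 < 5:
        return _refine_peak(y, p)
    idx = np.arange(i0, i1, dtype=float) - p
    c2, c1, _ = np.polyfit(idx, y[i0:i1], 2)
    if c2 >= 0:
        return float(p)
    vertex = -c1 / (2 * c2)
    return p + float(np.clip(vertex, -half, half))


def detect_beats(signal: SampledSignal, threshold_fraction: float = 0.5,
                 refractory: float = 0.03, polarity: str = "positive",
                 amplitude_window: float = 2.0,
                 refine: bool = True) -> EventSeries:
    """Detect R-waves or systolic pressure peaks.

    Local maxima exceeding ``threshold_fraction`` times a trailing
    rolling-maximum amplitude estimate, separated by at least
    ``refractory`` seconds. The fractional threshold tracks slow
    amplitude drift and makes detection gain-invariant; the default
    30 ms refractory leaves margin above 1000 bpm (mouse scale).
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    if not refractory > 0:
        raise ValueError("refractory must be positive")
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    distance = int(round(refractory * signal.rate))
    if distance < 1:
        raise ValueError("sampling rate too low to honor the refractory period")
    x = signal.values if polarity == "positive" else -signal.values
    if np.ptp(x) == 0:
        warnings.warn("flat signal: no beats detected", stacklevel=2)
        return EventSeries(np.empty(0), label="beats")
    win = max(1, int(round(amplitude_window * signal.rate)))
    # centered window: every sample within half a window of a QRS sees its
    # amplitude, so the estimate cannot collapse at either signal edge
    envelope = maximum_filter1d(x, size=win, mode="nearest")
    peaks, _ = find_peaks(x, distance=distance)
    keep = x[peaks] >= threshold_fraction * envelope[peaks]
    peaks = peaks[keep]
    if peaks.size == 0:
        warnings.warn("no beats exceeded the detection threshold", stacklevel=2)
        return EventSeries(np.empty(0), label="beats")
    if refine:
        pos = np.array([_refine_peak(x, p) for p in peaks])
    else:
        pos = peaks.astype(float)
    return EventSeries(signal.t0 + pos / signal.rate, label="beats")


def _template_refine_peaks(y: np.ndarray, rate: float, peaks: np.ndarray,
                           periods: np.ndarray,
                           n_passes: int = 3) -> np.ndarray:
    """Matched-filter refinement of per-cycle peak positions.

    Each cycle is resampled onto a phase grid normalized by its own
    period (so cycles of different length share one shape), the
    normalized cycles are averaged into a template, and every cycle is
    re-aligned to the template by normalized cross-correlation. The
    per-cycle timing jitter is then set by the match of a quarter-cycle
    of signal against the pooled template rather than by the noise at a
    single sample. A second pass rebuilds the template from the refined
    positions, removing the smearing that the rough (argmax) alignment
    leaves in the first-pass template.
    Returns fractional sample positions of the refined peaks.
    """
    pos = peaks.astype(float)
    for _ in range(max(1, n_passes)):
        pos = _template_pass(y, rate, pos, periods)
    return pos


def _cubic_peak(t: np.ndarray, half: int) -> float:
    """Peak position of a smooth asymmetric bump from a cubic fit around
    its argmax; the cubic term absorbs the asymmetry that biases a plain
    parabola, while the wide window averages the noise."""
    p = int(np.argmax(t))
    i0, i1 = max(0, p - half), min(t.size, p + half + 1)
    idx = np.arange(i0, i1, dtype=float) - p
    coef = np.polyfit(idx, t[i0:i1], 3)
    der = np.polyder(coef)
    roots = np.roots(der)
    roots = roots[np.isreal(roots)].real
    roots = roots[np.abs(roots) <= half]
    if roots.size == 0:
        return float(p)
    curv = np.polyval(np.polyder(der), roots)
    return p + float(roots[np.argmin(curv)])


def _template_pass(y: np.ndarray, rate: float, peaks: np.ndarray,
                   periods: np.ndarray) -> np.ndarray:
    med_period = float(np.median(periods))
    # ±0.3 of a period stays inside the cycle for inspiratory fractions
    # above ~0.3, so neighboring cycles (whose relative phase varies)
    # stay out of the match window
    m = int(0.3 * med_period * rate)          # half-width, phase samples
    du = 0.3 / m                              # phase step per grid sample
    grid = np.arange(-m, m + 1) * du          # phase offsets around peak
    lag = max(2, int(round(0.1 / du)))
    refined = peaks.astype(float)
    segs, usable = [], []
    for p, T in zip(peaks, periods):
        pos = p + grid * (T * rate)           # fractional sample positions
        if pos[0] < 0 or pos[-1] > y.size - 1:
            usable.append(False)
            continue
        usable.append(True)
        segs.append(np.interp(pos, np.arange(y.size), y))
    if len(segs) < 8:
        return refined
    template = np.mean(segs, axis=0)
    # absolute anchor: template peak from a cubic fit (a parabola drifts
    # toward the flatter expiratory side of the asymmetric peak)
    tp_u = (_cubic_peak(template, max(4, int(round(0.04 / du)))) - m) * du
    kernel = template[lag:-lag]
    kernel = kernel - kernel.mean()
    n_k = kernel.size
    ones = np.ones(n_k)
    k_seg = 0
    for i, (p, T) in enumerate(zip(peaks, periods)):
        if not usable[i]:
            continue
        seg = segs[k_seg]
        k_seg += 1
        # zero-normalized cross-correlation: invariant to the additive
        # offset and gain of each sliding window, so slow baseline wander
        # and the energy asymmetry of the cycle cannot bias the match
        corr = np.correlate(seg, kernel, "valid")
        s1 = np.correlate(seg, ones, "valid")
        s2 = np.correlate(seg * seg, ones, "valid")
        var = np.maximum(s2 - s1 * s1 / n_k, np.finfo(float).tiny)
        zncc = corr / np.sqrt(var)
        k = int(np.argmax(zncc))
        shift_u = (_refine_peak(zncc, k) - lag) * du
        refined[i] = p + (tp_u + shift_u) * T * rate
    return refined


def segment_breaths(signal: SampledSignal, smoothing: float = 0.02,
                    min_cycle: float = 0.1, baseline_window: float = 1.0,
                    min_peak_fraction: float = 0.25,
                    template_refine: bool = True,
                    invert: bool = False) -> BreathTrain:
    """Segment a plethysmography trace into respiratory cycles.

    The signal is smoothed, a 1 s rolling-median baseline is removed,
    and cycle onsets are placed at upward zero crossings. Candidate
    cycles shorter than ``min_cycle`` are merged into their successor;
    candidates whose inspiratory peak falls below ``min_peak_fraction``
    of the median peak (noise re-crossings on the expiratory decay, not
    breaths) are merged into their predecessor — both criteria are
    scale-invariant, so detections do not change with signal gain.
    Within each cycle, end-inspiration is the maximum, refined against
    the average cycle shape by cross-correlation when
    ``template_refine`` is on; the amplitude is peak minus intra-cycle
    trough. Inspiration is assumed to deflect positively; pass
    ``invert=True`` for the opposite sign convention.
    """
    if not min_cycle > 2.0 / signal.rate:
        raise ValueError("min_cycle must exceed two sample intervals")
    x = -signal.values if invert else signal.values
    if np.ptp(x) == 0:
        warnings.warn("flat signal: no respiratory cycles found", stacklevel=2)
        return BreathTrain(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    if smoothing > 0:
        w = max(1, int(round(smoothing * signal.rate)))
        x = uniform_filter1d(x, size=w, mode="nearest")
    y = x - _rolling_median(x, signal.rate, baseline_window)
    up = np.flatnonzero((y[:-1] <= 0) & (y[1:] > 0))
    if up.size < 1:
        warnings.warn("no respiratory cycles found", stacklevel=2)
        return BreathTrain(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    # linear-interpolated crossing times
    frac = -y[up] / (y[up + 1] - y[up])
    crossings = (up + frac) / signal.rate
    # merge cycles shorter than min_cycle by dropping the later crossing
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= min_cycle:
            kept.append(c)
    bounds = np.append(kept, signal.duration)
    if bounds[-1] - bounds[-2] < min_cycle:
        bounds = bounds[:-1]

    def seg_max(a, b):
        i0 = int(np.ceil(a * signal.rate))
        i1 = int(np.floor(b * signal.rate)) + 1
        return float(np.max(y[i0:i1])) if i1 - i0 >= 1 else -np.inf

    maxima = np.array([seg_max(a, b) for a, b in zip(bounds[:-1], bounds[1:])])
    med_peak = float(np.median(maxima[maxima > 0])) if np.any(maxima > 0) else 0.0
    merged = [bounds[0]]
    for k in range(1, len(bounds) - 1):
        # keep this boundary only if the segment it opens holds a real peak
        if maxima[k] >= min_peak_fraction * med_peak and maxima[k] > 0:
            merged.append(bounds[k])
    merged.append(bounds[-1])

    onsets, ends, amps, peaks = [], [], [], []
    for a, b in zip(merged[:-1], merged[1:]):
        i0, i1 = int(np.ceil(a * signal.rate)), int(np.floor(b * signal.rate)) + 1
        seg = y[i0:i1]
        if seg.size < 3 or np.max(seg) < max(min_peak_fraction * med_peak,
                                             np.finfo(float).tiny):
            continue
        onsets.append(a)
        ends.append(b)
        peaks.append(i0 + int(np.argmax(seg)))
        amps.append(float(np.max(seg) - np.min(seg)))
    if not onsets:
        warnings.warn("no respiratory cycles found", stacklevel=2)
        return BreathTrain(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    peaks = np.asarray(peaks)
    cycle_periods = np.asarray(ends) - np.asarray(onsets)
    if template_refine:
        # align on a lightly smoothed copy: heavy smoothing skews the
        # asymmetric inspiratory peak, and the pooled template supplies
        # the noise averaging instead
        # no baseline subtraction here: the zero-normalized match is
        # offset-invariant, and a rolling median spanning ~2 cycles would
        # inject its own within-cycle wobble into the alignment
        w_fine = max(1, int(round(0.25 * smoothing * signal.rate)))
        x_fine = uniform_filter1d(-signal.values if invert else signal.values,
                                  size=w_fine, mode="nearest")
        pos = _template_refine_peaks(x_fine, signal.rate, peaks,
                                     cycle_periods)
    else:
        pos = np.array([_refine_peak(y, p) for p in peaks])
    # peak must stay inside its cycle
    eps = 1.0 / signal.rate
    eis = np.clip(pos / signal.rate,
                  np.asarray(onsets) + eps, np.asarray(ends) - eps)
    return BreathTrain(signal.t0 + np.asarray(onsets), signal.t0 + eis,
                       signal.t0 + np.asarray(ends), np.asarray(amps))


def detect_bursts(signal: SampledSignal, threshold_sd: float = 3.0,
                  min_duration: float = 0.02, min_interval: float = 0.05,
                  baseline_window: float = 1.0) -> BurstSeries:
    """Detect bursts on an integrated neurogram or current trace.

    Contiguous regions exceeding baseline + ``threshold_sd`` times a
    robust (MAD-based) noise estimate, lasting at least ``min_duration``
    seconds; regions separated by gaps shorter than ``min_interval`` are
    merged. The baseline is a rolling median, insensitive to the bursts
    themselves at duty cycles below ~50%.
    """
    if threshold_sd <= 0 or min_duration <= 0 or min_interval < 0:
        raise ValueError("thresholds must be positive")
    x = signal.values
    base = _rolling_median(x, signal.rate, baseline_window)
    resid = x - base
    sd = 1.4826 * float(np.median(np.abs(resid)))
    above = resid > threshold_sd * sd
    if not np.any(above):
        return BurstSeries(np.empty(0), np.empty(0), np.empty(0))
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        stops = np.append(stops, x.size)
    # drop isolated blips (single noise excursions) before gap merging,
    # so a noise spike just ahead of a burst cannot merge in and drag
    # the onset early; genuine burst fragments are far longer
    blip = max(1, int(round(0.25 * min_duration * signal.rate)))
    keep = (stops - starts) >= blip
    starts, stops = starts[keep], stops[keep]
    if starts.size == 0:
        return BurstSeries(np.empty(0), np.empty(0), np.empty(0))
    # merge gaps shorter than min_interval
    gap = int(round(min_interval * signal.rate))
    m_starts, m_stops = [starts[0]], [stops[0]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - m_stops[-1] < gap:
            m_stops[-1] = e
        else:
            m_starts.append(s)
            m_stops.append(e)
    onsets, offsets, peaks = [], [], []
    min_len = min_duration * signal.rate
    for s, e in zip(m_starts, m_stops):
        if e - s < min_len:
            continue
        onsets.append(signal.t0 + s / signal.rate)
        offsets.append(signal.t0 + (e - 1) / signal.rate)
        peaks.append(float(np.max(x[s:e])))
    return BurstSeries(np.array(onsets), np.array(offsets), np.array(peaks))
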