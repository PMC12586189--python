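"""Pre/post effect sizes, correlation, and stress-recovery kinetics.

Two delta conventions coexist in group reporting and are kept explicit:

``per_subject_mean``
    mean over subjects of each subject's own delta (the convention that
    reproduces printed group Δ% values, and the default), and
``group_mean_delta``
    the delta computed between group means.

Deltas are held at full precision internally; :meth:`EffectResult.report`
applies the integer rounding used at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EffectResult",
    "GroupEffect",
    "CorrelationResult",
    "RecoveryResult",
    "epoch_delta",
    "group_effect",
    "pearson_regression",
    "recovery_kinetics",
]

CONVENTIONS = ("per_subject_mean", "group_mean_delta")


@dataclass(frozen=True)
class EffectResult:
    pre: float
    post: float
    delta_abs: float
    delta_percent: float | None
    convention: str = "group_mean_delta"

    def report(self) -> dict:
        """Integer-rounded values for tabular reporting."""
        out = {"delta_abs": int(round(self.delta_abs))}
        if self.delta_percent is not None:
            out["delta_percent"] = int(round(self.delta_percent))
        return out


@dataclass(frozen=True)
class GroupEffect:
    pre_mean: float
    post_mean: float
    delta: float          # in the requested unit, under the convention
    sem: float            # SEM of the per-subject deltas
    unit: str             # "absolute" | "percent"
    convention: str
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    n: int
    p_two_sided: float


@dataclass(frozen=True)
class RecoveryResult:
    bin_labels: tuple
    deltas_percent: np.ndarray   # per post-stress bin, vs pre-stress baseline
    stress_delta_percent: float | None
    recovery_bin: str | None     # first bin back within the criterion band
    criterion_band: float        # %


def epoch_delta(pre: float, post: float, unit: str = "percent",
                convention: str = "group_mean_delta") -> EffectResult:
    """Post-stimulus change relative to pre-stimulus.

    ``unit="absolute"`` gives ``post − pre``; ``unit="percent"`` gives
    ``100·(post − pre)/pre`` (requires ``pre ≠ 0``). Both are always
    populated when defined.
    """
    if unit not in ("absolute", "percent"):
        raise ValueError("unit must be 'absolute' or 'percent'")
    delta_abs = post - pre
    if pre == 0:
        if unit == "percent":
            raise ValueError("percent delta undefined for pre = 0")
        delta_pct = None
    else:
        delta_pct = 100.0 * delta_abs / pre
    return EffectResult(pre, post, delta_abs, delta_pct, convention)


def group_effect(pre, post, unit: str = "percent",
                 convention: str = "per_subject_mean") -> GroupEffect:
    """Group-level delta under either reporting convention.

    ``pre`` and ``post`` are paired per-subject values. The SEM always
    describes the spread of the per-subject deltas, whichever convention
    produced the point estimate.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    if pre.size < 2:
        raise ValueError("group effect requires at least 2 subjects")
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    if unit == "percent":
        if np.any(pre == 0):
            raise ValueError("percent delta undefined for pre = 0")
        per_subject = 100.0 * (post - pre) / pre
    elif unit == "absolute":
        per_subject = post - pre
    else:
        raise ValueError("unit must be 'absolute' or 'percent'")
    if convention == "per_subject_mean":
        delta = float(np.mean(per_subject))
    else:
        eff = epoch_delta(float(np.mean(pre)), float(np.mean(post)), unit)
        delta = eff.delta_abs if unit == "absolute" else eff.delta_percent
    return GroupEffect(float(np.mean(pre)), float(np.mean(post)), delta,
                       float(stats.sem(per_subject)), unit, convention,
                       pre.size)


def pearson_regression(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the least-squares line.

    The two-sided p-value comes from the t transform of r with n − 2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired one-dimensional arrays")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    fit = stats.linregress(x, y)
    return CorrelationResult(float(fit.rvalue), float(fit.slope),
                             float(fit.intercept), x.size,
                             float(fit.pvalue))


def recovery_kinetics(baseline: float, stress: float | None, post_bins,
                      criterion_band: float = 10.0) -> RecoveryResult:
    """Timed return of a metric to its pre-stress baseline.

    ``post_bins`` is an ordered sequence of ``(label, value)`` for the
    post-stress assessment windows (e.g. the 25–35 and 55–65 min bins).
    The recovery bin is the first whose percent delta versus baseline
    lies within ``±criterion_band``; ``None`` if the metric never
    returns.
    """
    if baseline is None or not np.isfinite(baseline) or baseline == 0:
        raise ValueError("a finite, nonzero pre-stress baseline is required")
    post_bins = list(post_bins)
    if not post_bins:
        raise ValueError("at least one post-stress bin is required")
    labels = tuple(lbl for lbl, _ in post_bins)
    deltas = np.array([100.0 * (v - baseline) / baseline for _, v in post_bins])
    stress_delta = (None if stress is None
                    else 100.0 * (stress - baseline) / baseline)
    recovery = None
    for lbl, d in zip(labels, deltas):
        if abs(d) <= criterion_band:
            recovery = lbl
            break
    return RecoveryResult(labels, deltas, stress_delta, recovery,
                          criterion_band)
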