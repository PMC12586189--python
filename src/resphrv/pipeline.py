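"""End-to-end session pipeline: simulate → detect → metrics → effects.

The pipeline is deterministic for a fixed configuration and seed; the
seed and a hash of the configuration are embedded in every output
table so runs can be matched to their provenance.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import synth
from .detect import detect_beats, segment_breaths
from .effects import epoch_delta
from .hrv import POLICIES, epoch_metrics
from .io import SessionConfig, config_hash

__all__ = ["simulate_session", "analyze_session", "run_pipeline"]

log = logging.getLogger("resphrv")


def _schedule_from_config(config: SessionConfig) -> synth.EpochSchedule:
    if not config.epochs:
        raise ValueError("configuration defines no epochs")
    return synth.EpochSchedule(tuple(
        synth.Epoch(label, start, end, dict(overrides))
        for label, start, end, overrides in config.epochs))


def simulate_session(config: SessionConfig):
    """Render the configured session (channels + ground truth)."""
    schedule = _schedule_from_config(config)
    resp = synth.RespParams(**config.resp)
    cardiac = synth.CardiacParams(**config.cardiac)
    return synth.build_session(
        schedule, resp, cardiac, channels=config.channels, seed=config.seed,
        grid_hz=config.grid_hz, ecg_noise_sd=config.ecg_noise_sd,
        pleth_noise_sd=config.pleth_noise_sd)


def analyze_session(beats, breaths, config: SessionConfig) -> pd.DataFrame:
    """Per-epoch metrics table under the configured condition policy.

    Stimulation-style epochs are analyzed over the final ``window_s``
    seconds of the epoch (default from the condition policy, e.g. the
    last 30 s of a 1-min stimulation); shorter epochs use their full
    extent.
    """
    policy = POLICIES[config.condition]
    window = config.window_s if config.window_s is not None else policy.window_s
    rows = []
    chash = config_hash(config)
    for label, start, end, _ in config.epochs:
        a_start = max(start, end - window)
        log.info("epoch %s: analysis window [%.1f, %.1f) s, policy %s "
                 "(min %d cycles)", label, a_start, end, policy.name,
                 policy.min_cycles)
        m = epoch_metrics(beats, breaths, (a_start, end), policy, label)
        log.info("epoch %s: %d cycles averaged", label, m.n_cycles)
        rows.append({
            "label": m.label, "window_start_s": a_start, "window_end_s": end,
            "mhr_bpm": m.mhr, "resphrv_bpm": m.resphrv_amplitude,
            "resp_frequency_cpm": m.resp_frequency,
            "resp_amplitude_au": m.resp_amplitude, "n_cycles": m.n_cycles,
            "condition": policy.name, "seed": config.seed,
            "config_hash": chash,
        })
    return pd.DataFrame(rows)


def _effects_table(metrics: pd.DataFrame, config: SessionConfig) -> pd.DataFrame:
    chash = config_hash(config)
    rows = []
    by_label = metrics.set_index("label")
    for pre_label, post_label in config.pairs:
        for col, unit in (("mhr_bpm", "absolute"),
                          ("resphrv_bpm", "percent"),
                          ("resp_frequency_cpm", "percent"),
                          ("resp_amplitude_au", "percent")):
            pre = float(by_label.loc[pre_label, col])
            post = float(by_label.loc[post_label, col])
            eff = epoch_delta(pre, post, unit)
            rows.append({
                "pre": pre_label, "post": post_label, "metric": col,
                "pre_value": pre, "post_value": post,
                "delta_abs": eff.delta_abs,
                "delta_percent": eff.delta_percent,
                "convention": eff.convention, "seed": config.seed,
                "config_hash": chash,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: SessionConfig):
    """Simulate the configured session, re-detect events from the
    rendered channels, and return (metrics, effects) tables."""
    recording, truth = simulate_session(config)
    if "ecg" in recording.channels:
        beats = detect_beats(recording.channels["ecg"])
        log.info("detected %d beats from the ECG channel", len(beats))
    else:
        beats = recording.beats
        log.info("no ECG channel rendered; using generator beat times")
    if "pleth" in recording.channels:
        breaths = segment_breaths(recording.channels["pleth"])
        log.info("segmented %d respiratory cycles from plethysmography",
                 breaths.n_cycles)
    else:
        breaths = recording.breaths
        log.info("no pleth channel rendered; using generator breath train")
    metrics = analyze_session(beats, breaths, config)
    effects = _effects_table(metrics, config) if config.pairs else pd.DataFrame()
    return metrics, effects
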