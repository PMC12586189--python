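"""Delimited-text file formats and session configuration.

Signals are stored one channel per file: ``#`` header lines carrying
``rate_hz``, ``units`` and ``t0``, then one sample value per line.
Event and cycle tables are tab-separated with a commented header row.
Text formats are deliberately chosen over binary for inspectability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .signals import BreathTrain, EventSeries, SampledSignal

__all__ = [
    "ParseError",
    "read_signal",
    "write_signal",
    "read_events",
    "write_events",
    "read_breaths",
    "write_breaths",
    "SessionConfig",
    "load_config",
    "config_hash",
]


class ParseError(ValueError):
    """Malformed file; carries the offending path and line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def write_signal(signal: SampledSignal, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate_hz={signal.rate!r}\n")
        fh.write(f"# units={signal.units}\n")
        fh.write(f"# t0={signal.t0!r}\n")
        np.savetxt(fh, signal.values, fmt="%.17g")


def read_signal(path) -> SampledSignal:
    path = Path(path)
    meta = {}
    values = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ParseError(path, lineno,
                                     f"malformed header line {line!r}")
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            else:
                try:
                    values.append(float(line))
                except ValueError:
                    raise ParseError(path, lineno,
                                     f"not a number: {line!r}") from None
    if "rate_hz" not in meta:
        raise ParseError(path, 1, "missing required header 'rate_hz'")
    try:
        rate = float(meta["rate_hz"])
        t0 = float(meta.get("t0", 0.0))
    except ValueError as exc:
        raise ParseError(path, 1, f"bad header value: {exc}") from None
    return SampledSignal(np.asarray(values), rate, t0, meta.get("units", ""))


def write_events(events: EventSeries, path) -> None:
    path = Path(path)
    marks = events.marks if events.marks is not None else np.zeros(len(events))
    with path.open("w") as fh:
        fh.write(f"# label={events.label}\n")
        fh.write("# columns=time_s\tmark\n")
        for t, mk in zip(events.times, marks):
            fh.write(f"{float(t)!r}\t{mk}\n")


def read_events(path) -> EventSeries:
    path = Path(path)
    label = ""
    times, marks = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("label="):
                    label = body[len("label="):]
                continue
            parts = line.split("\t")
            try:
                times.append(float(parts[0]))
            except ValueError:
                raise ParseError(path, lineno,
                                 f"not a time value: {parts[0]!r}") from None
            marks.append(parts[1] if len(parts) > 1 else "0")
    return EventSeries(np.asarray(times, dtype=float), label,
                       np.asarray(marks))


_BREATH_COLS = ("onset_s", "end_inspiration_s", "end_s", "amplitude")


def write_breaths(breaths: BreathTrain, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# columns=" + "\t".join(_BREATH_COLS) + "\n")
        for row in zip(breaths.onsets, breaths.end_inspirations,
                       breaths.ends, breaths.amplitudes):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_breaths(path) -> BreathTrain:
    path = Path(path)
    cols = [[], [], [], []]
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(path, lineno,
                                 f"expected 4 columns, got {len(parts)}")
            try:
                for c, p in zip(cols, parts):
                    c.append(float(p))
            except ValueError:
                raise ParseError(path, lineno,
                                 f"not a number in row: {line!r}") from None
    return BreathTrain(*[np.asarray(c) for c in cols])


# --------------------------------------------------------------------------
# session configuration


@dataclass(frozen=True)
class SessionConfig:
    """Configuration of one simulated/analyzed session.

    ``condition`` selects the cycle-count policy and default analysis
    window (freely_moving | anesthetized | whbp | stress); ``epochs``
    are ``(label, start, end, overrides)`` mappings; ``pairs`` names the
    (pre, post) epoch pairs for the effects table. The seed is recorded
    in every output table.
    """

    condition: str = "freely_moving"
    seed: int = 0
    resp: dict = field(default_factory=dict)
    cardiac: dict = field(default_factory=dict)
    channels: tuple = ("ecg", "pleth")
    epochs: tuple = ()
    pairs: tuple = ()
    window_s: float | None = None
    grid_hz: float = 1000.0
    ecg_noise_sd: float = 0.05
    pleth_noise_sd: float = 0.05

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "seed": self.seed,
            "resp": dict(self.resp),
            "cardiac": dict(self.cardiac),
            "channels": list(self.channels),
            "epochs": [list(e[:3]) + [dict(e[3])] for e in self.epochs],
            "pairs": [list(p) for p in self.pairs],
            "window_s": self.window_s,
            "grid_hz": self.grid_hz,
            "ecg_noise_sd": self.ecg_noise_sd,
            "pleth_noise_sd": self.pleth_noise_sd,
        }


def load_config(path) -> SessionConfig:
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    epochs = tuple(
        (e["label"], float(e["start"]), float(e["end"]),
         dict(e.get("overrides", {})))
        for e in raw.get("epochs", ()))
    pairs = tuple(tuple(p) for p in raw.get("pairs", ()))
    kwargs = {k: raw[k] for k in
              ("condition", "seed", "resp", "cardiac", "window_s",
               "grid_hz", "ecg_noise_sd", "pleth_noise_sd") if k in raw}
    if "channels" in raw:
        kwargs["channels"] = tuple(raw["channels"])
    return SessionConfig(epochs=epochs, pairs=pairs, **kwargs)


def config_hash(config: SessionConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
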