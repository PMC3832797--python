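"""Patch-clamp spike-train analysis: detection, rate time course, suppression.

Layer III interneurons fire spontaneously at roughly 8–10 Hz; a 1 s
stimulus train roughly halves that rate for several seconds.  This module
detects action potentials in voltage traces, bins them into rate time
courses and quantifies the suppression as the percent reduction of the
mean firing rate between a window before the train and a window after it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Trace
from .errors import FormatError, ValidationError


@dataclass
class SpikeTrain:
    """Spike times of one recording, with the stimulus-train timing."""

    times_s: np.ndarray
    duration_s: float
    train_onset_s: float
    train_duration_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValidationError("spike times must be a 1-D array")
        if len(self.times_s):
            if np.any(np.diff(self.times_s) <= 0):
                raise ValidationError("spike times must be strictly increasing")
            if self.times_s[0] < 0 or self.times_s[-1] > self.duration_s:
                raise ValidationError("spike times outside [0, duration]")
        if self.duration_s <= 0 or self.train_duration_s <= 0:
            raise ValidationError("durations must be positive")
        if not 0 <= self.train_onset_s <= self.duration_s:
            raise ValidationError("train onset outside the recording")

    @property
    def train_offset_s(self) -> float:
        return self.train_onset_s + self.train_duration_s

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class RateTimecourse:
    """Firing rate per contiguous time bin."""

    edges_s: np.ndarray
    rate_hz: np.ndarray

    def __post_init__(self) -> None:
        self.edges_s = np.asarray(self.edges_s, dtype=float)
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        if len(self.edges_s) != len(self.rate_hz) + 1:
            raise ValidationError("need one more bin edge than rate values")
        if np.any(np.diff(self.edges_s) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(self.rate_hz < 0):
            raise ValidationError("rates must be nonnegative")


def detect_spikes(
    voltage: Trace,
    threshold_mV: float = -20.0,
    refractory_ms: float = 2.0,
    train_onset_s: float = 0.0,
    train_duration_s: float = 1.0,
    sampling_rtol: float = 1e-3,
) -> SpikeTrain:
    """Threshold-crossing spike detector with a refractory window.

    A spike is registered at each sample where the voltage crosses
    ``threshold_mV`` upward; subsequent crossings within ``refractory_ms``
    are ignored.  The trace must be uniformly sampled (relative tolerance
    ``sampling_rtol``).
    """
    if len(voltage) < 2:
        raise ValidationError("voltage trace too short for spike detection")
    dt = np.diff(voltage.time_s)
    if np.max(np.abs(dt - dt.mean())) > sampling_rtol * dt.mean():
        raise FormatError("voltage trace is not uniformly sampled")
    v = voltage.values
    above = v >= threshold_mV
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    refractory_s = refractory_ms / 1000.0
    accepted: list[float] = []
    last = -np.inf
    for i in crossings:
        t = float(voltage.time_s[i])
        if t - last >= refractory_s:
            accepted.append(t)
            last = t
    duration = float(voltage.time_s[-1] - voltage.time_s[0])
    times = np.asarray(accepted) - float(voltage.time_s[0])
    return SpikeTrain(
        times_s=times,
        duration_s=duration,
        train_onset_s=train_onset_s,
        train_duration_s=train_duration_s,
    )


def rate_timecourse(train: SpikeTrain, bin_s: float = 1.0) -> RateTimecourse:
    """Spike counts per bin divided by the bin width."""
    if bin_s <= 0:
        raise ValidationError("bin_s must be > 0")
    edges = np.arange(0.0, train.duration_s + 1e-9, bin_s)
    if edges[-1] < train.duration_s - 1e-9:
        edges = np.append(edges, train.duration_s)
    counts, _ = np.histogram(train.times_s, bins=edges)
    widths = np.diff(edges)
    return RateTimecourse(edges_s=edges, rate_hz=counts / widths)


def pre_post_reduction(train: SpikeTrain, window_s: float = 5.0) -> float | None:
    """Percent reduction of the firing rate across the stimulus train.

    Compares the mean rate in the ``window_s`` seconds before train onset
    with the ``window_s`` seconds after train offset:
    ``100 * (rate_pre - rate_post) / rate_pre``.  ``None`` when the
    pre-train rate is zero (reduction undefined).
    """
    if window_s <= 0:
        raise ValidationError("window_s must be > 0")
    pre_start = train.train_onset_s - window_s
    post_end = train.train_offset_s + window_s
    if pre_start < -1e-9 or post_end > train.duration_s + 1e-9:
        raise ValidationError(
            f"{window_s} s windows around the train exceed the recording "
            f"[0, {train.duration_s}] s"
        )
    t = train.times_s
    n_pre = int(np.sum((t >= pre_start) & (t < train.train_onset_s)))
    n_post = int(np.sum((t >= train.train_offset_s) & (t < post_end)))
    rate_pre = n_pre / window_s
    rate_post = n_post / window_s
    if rate_pre == 0:
        return None
    return 100.0 * (rate_pre - rate_post) / rate_pre


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_spike_csv(train: SpikeTrain, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# duration_s={train.duration_s:.9g}\n")
        fh.write(f"# train_onset_s={train.train_onset_s:.9g}\n")
        fh.write(f"# train_duration_s={train.train_duration_s:.9g}\n")
        pd.DataFrame({"spike_time_s": train.times_s}).to_csv(
            fh, index=False, float_format="%.9g"
        )
    return path


def read_spike_csv(path: str | Path) -> SpikeTrain:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = float(value)
    for key in ("duration_s", "train_onset_s", "train_duration_s"):
        if key not in header:
            raise FormatError(f"{path}: missing '# {key}=...' header line")
    table = pd.read_csv(path, comment="#")
    if "spike_time_s" not in table.columns:
        raise FormatError(f"{path}: expected a 'spike_time_s' column")
    return SpikeTrain(
        times_s=table["spike_time_s"].to_numpy(),
        duration_s=header["duration_s"],
        train_onset_s=header["train_onset_s"],
        train_duration_s=header["train_duration_s"],
    )


__all__ = [
    "SpikeTrain",
    "RateTimecourse",
    "detect_spikes",
    "rate_timecourse",
    "pre_post_reduction",
    "write_spike_csv",
    "read_spike_csv",
]
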