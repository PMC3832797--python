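"""Forward generator for the three-region feed-forward disinhibition circuit.

The generator emulates a VSDI recording of a piriform-cortex slice: a 1 s
pulse train on the lateral olfactory tract depolarizes layer II pyramidal
cells, excites the dorsal endopiriform nucleus (DEn) about 50 ms later, and
hyperpolarizes the interneuron-rich layer III about 200 ms after the layer II
onset (disinhibition).  Responses grow sigmoidally with train frequency;
experimental-epilepsy (kindled) parameters steepen the gain, and cutting the
slice below layer II silences the DEn and converts the layer III response to
a feed-forward excitation.

Model
-----
Each region's noiseless ΔF/F is a separable product of a spatial mask and a
temporal kernel,

    dff_r(t) = polarity * A_r(f) * (1 - exp(-(t - t_on)/tau_rise))
                                  * exp(-(t - t_on)/tau_decay),   t >= t_on,

with region onsets ``t_on`` = stimulus onset + layer II latency (+ Lag 1 for
the DEn, + Lag 2 for layer III).  The frequency gain ``A_r(f)`` follows the
same Hill sigmoid the analysis fits, anchored so that the response at 20 Hz
(the normalization reference) is ``base_amplitude_percent`` and the response
at 80 Hz is ``top_fold`` times larger; see :func:`normalized_gain`.

Camera counts follow the dye convention — depolarization *dims* the dye —
with a common-mode exponential bleach and optional per-pixel Gaussian noise:

    counts = F0 * (1 - dff/100) * exp(-t/tau_bleach) + noise.

With noise enabled, counts are rounded to integers as a real camera would
produce; at zero noise the counts stay continuous so that parameter-recovery
tests are limited only by the analysis, not by quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .data_model import (
    MovieMeta,
    RawMovie,
    RegionSet,
    StimProtocol,
)
from .errors import ValidationError
from .spikes import SpikeTrain

CONDITIONS = ("control", "kindled", "cut")

#: The gain curve is anchored at the normalization frequency ...
GAIN_REF_HZ = 20.0
#: ... and at the frequency where the paper-style fold change is read off.
GAIN_TOP_HZ = 80.0


@dataclass(frozen=True)
class RegionGain:
    """Frequency gain of one region.

    ``top_fold`` is the response at 80 Hz relative to the 20 Hz response;
    ``f_half`` and ``hill`` shape the underlying sigmoid; ``polarity`` is +1
    for depolarizing and -1 for hyperpolarizing regions;
    ``base_amplitude_percent`` is the |ΔF/F| of the 20 Hz response.
    """

    top_fold: float
    f_half: float
    hill: float
    polarity: int
    base_amplitude_percent: float

    def __post_init__(self) -> None:
        if self.f_half <= 0 or self.hill <= 0:
            raise ValidationError("f_half and hill must be > 0")
        if self.polarity not in (-1, 1):
            raise ValidationError("polarity must be +1 or -1")
        if self.top_fold < 0 or self.base_amplitude_percent < 0:
            raise ValidationError("gains and amplitudes must be nonnegative")


@dataclass(frozen=True)
class SpikeModel:
    """Spontaneous layer III firing and its post-train suppression.

    The baseline rate of each cell is drawn uniformly from
    ``baseline_rate_range_hz``.  During the train the rate drops to
    ``suppressed_rate_hz`` and afterwards relaxes back exponentially with
    ``recovery_tau_s``; the defaults place the 5 s post-train average near
    4 Hz (a 62 % reduction from a 9 Hz baseline) with recovery to within
    20 % of baseline by the 20 s sweep end.
    """

    baseline_rate_range_hz: tuple[float, float] = (8.0, 10.0)
    suppressed_rate_hz: float = 1.5
    recovery_tau_s: float = 8.0

    def __post_init__(self) -> None:
        lo, hi = self.baseline_rate_range_hz
        if not 0 < lo <= hi:
            raise ValidationError("baseline rate range must be positive and ordered")
        if self.suppressed_rate_hz < 0:
            raise ValidationError("suppressed rate must be >= 0")
        if self.suppressed_rate_hz > lo:
            raise ValidationError("suppressed rate must not exceed the baseline")
        if self.recovery_tau_s <= 0:
            raise ValidationError("recovery_tau_s must be > 0")


@dataclass(frozen=True)
class CircuitParams:
    """Ground-truth parameters of one simulated slice."""

    condition: str
    gains: Mapping[str, RegionGain]
    onset_latency_ms: float = 20.0
    lag1_ms: float = 50.0
    lag2_ms: float = 200.0
    rise_tau_ms: float = 100.0
    decay_tau_s: float = 4.0
    bleach_tau_s: float | None = 100.0
    noise_sd_percent: float = 0.3
    f0_counts: float = 3000.0
    frame_shape: tuple[int, int] = (64, 64)
    frame_interval_ms: float = 5.0
    pixel_size_um: float = 25.0
    spike_model: SpikeModel = field(default_factory=SpikeModel)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}")
        if set(self.gains) != {"layerII", "DEn", "layerIII"}:
            raise ValidationError("gains must cover layerII, DEn and layerIII")
        if not self.lag1_ms < self.lag2_ms:
            raise ValidationError("lag1 must be shorter than lag2")
        if self.rise_tau_ms <= 0 or self.decay_tau_s <= 0:
            raise ValidationError("kinetic time constants must be > 0")
        if self.bleach_tau_s is not None and self.bleach_tau_s <= 0:
            raise ValidationError("bleach_tau_s must be > 0 (or None for no bleach)")
        if self.noise_sd_percent < 0:
            raise ValidationError("noise_sd_percent must be >= 0")
        if self.f0_counts <= 0:
            raise ValidationError("f0_counts must be > 0")


@dataclass
class GroundTruth:
    """Noiseless components and true quantities of one generated movie."""

    region_traces: dict[str, np.ndarray]
    onsets_ms: dict[str, float | None]
    latencies_ms: dict[str, float]
    normalized_gain: dict[str, float]
    amplitudes_percent: dict[str, float]
    peak_percent: dict[str, float]
    frequency_hz: float
    seed: int
    amplitude_scale: float = 1.0


_DEFAULT_GAINS: dict[str, dict[str, RegionGain]] = {
    "control": {
        "layerII": RegionGain(3.5, 40.0, 3.0, +1, 1.0),
        "DEn": RegionGain(5.0, 40.0, 3.0, +1, 0.6),
        "layerIII": RegionGain(2.5, 20.0, 3.0, -1, 0.5),
    },
    "kindled": {
        "layerII": RegionGain(6.0, 40.0, 3.0, +1, 1.0),
        "DEn": RegionGain(10.0, 40.0, 3.0, +1, 0.6),
        "layerIII": RegionGain(4.5, 20.0, 3.0, -1, 0.5),
    },
    # Cutting below layer II removes the layer II -> DEn drive: the DEn is
    # silent, layer III flips to a (smaller) feed-forward excitation driven
    # directly from layer II, and the layer II response itself shrinks.
    "cut": {
        "layerII": RegionGain(2.0, 40.0, 3.0, +1, 0.6),
        "DEn": RegionGain(0.0, 40.0, 3.0, +1, 0.0),
        "layerIII": RegionGain(2.0, 40.0, 3.0, +1, 0.3),
    },
}


def default_params(condition: str = "control") -> CircuitParams:
    """Documented default parameters for a condition.

    ======== ========== ====== ===== ======== ================
    region   condition  top    f_half hill    base amplitude
    ======== ========== ====== ===== ======== ================
    layerII  control    3.5    40    3        1.0 %
    layerII  kindled    6.0    40    3        1.0 %
    layerII  cut        2.0    40    3        0.6 %
    DEn      control    5.0    40    3        0.6 %
    DEn      kindled    10.0   40    3        0.6 %
    DEn      cut        0      --    --       0
    layerIII control    2.5    20    3        0.5 % (hyperpol.)
    layerIII kindled    4.5    20    3        0.5 % (hyperpol.)
    layerIII cut        2.0    40    3        0.3 % (depol.)
    ======== ========== ====== ===== ======== ================

    Timing defaults: layer II onset latency 20 ms after stimulus onset,
    Lag 1 = 50 ms (DEn), Lag 2 = 200 ms (layer III); rise tau 100 ms, decay
    tau 4 s, bleach tau 100 s, per-pixel noise SD 0.3 % of F0 = 3000 counts,
    64x64 frame at 5 ms/frame and 25 um/pixel.
    """
    if condition not in CONDITIONS:
        raise ValidationError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    return CircuitParams(condition=condition, gains=dict(_DEFAULT_GAINS[condition]))


# ---------------------------------------------------------------------------
# gain curve
# ---------------------------------------------------------------------------


def _logistic(f: float, f_half: float, hill: float) -> float:
    return 1.0 / (1.0 + (f_half / f) ** hill)


def gain_curve_params(gain: RegionGain) -> tuple[float, float]:
    """Floor and plateau (relative to the 20 Hz response) of the gain sigmoid.

    The normalized gain is ``G(f) = b + (T - b) * s(f)`` with
    ``s(f) = 1 / (1 + (f_half/f)**hill)``.  ``b`` and ``T`` are solved from
    the two anchors ``G(20) = 1`` and ``G(80) = top_fold``.  When the anchors
    are infeasible with a nonnegative floor (a midpoint at 20 Hz caps the
    80/20 ratio at 2), the floor is clamped to 0 and only the 20 Hz anchor is
    kept, so the realized fold is the largest the sigmoid admits.
    """
    s20 = _logistic(GAIN_REF_HZ, gain.f_half, gain.hill)
    s80 = _logistic(GAIN_TOP_HZ, gain.f_half, gain.hill)
    det = s80 - s20
    if abs(det) < 1e-12:
        raise ValidationError("degenerate gain sigmoid (anchors coincide)")
    # [[1-s20, s20], [1-s80, s80]] @ [b, T] = [1, top_fold]
    b = (s80 - gain.top_fold * s20) / det
    t = ((1 - s20) * gain.top_fold - (1 - s80)) / det
    if b < 0:
        b, t = 0.0, 1.0 / s20
    return b, t


def normalized_gain(gain: RegionGain, frequency_hz: float) -> float:
    """Programmed response at ``frequency_hz`` relative to the 20 Hz response."""
    if frequency_hz <= 0:
        raise ValidationError("frequency must be > 0")
    if gain.top_fold == 0:
        return 0.0
    b, t = gain_curve_params(gain)
    return b + (t - b) * _logistic(frequency_hz, gain.f_half, gain.hill)


def amplitude_percent(gain: RegionGain, frequency_hz: float) -> float:
    """|ΔF/F| drive of the region at ``frequency_hz`` (percent)."""
    return gain.base_amplitude_percent * normalized_gain(gain, frequency_hz)


# ---------------------------------------------------------------------------
# spatial layout
# ---------------------------------------------------------------------------

# horizontal bands as fractions of the frame height; the gaps keep the bands
# disjoint after 3x3 binning
_BAND_FRACTIONS = {
    "layerII": (0.09, 0.28),
    "DEn": (0.375, 0.565),
    "layerIII": (0.655, 0.845),
    "reference": (0.89, 1.0),
}


def default_regions(shape: tuple[int, int] = (64, 64)) -> RegionSet:
    """Four horizontal bands: layer II, DEn, layer III and the reference."""
    h, w = shape
    labels = np.zeros((h, w), dtype=np.int32)
    names: dict[str, int] = {}
    for i, (name, (lo, hi)) in enumerate(_BAND_FRACTIONS.items(), start=1):
        r0, r1 = int(math.floor(lo * h)), int(math.floor(hi * h))
        labels[r0:r1, :] = i
        names[name] = i
    return RegionSet(labels=labels, names=names)


# ---------------------------------------------------------------------------
# movie generation
# ---------------------------------------------------------------------------


def _kernel(t_rel_s: np.ndarray, rise_tau_s: float, decay_tau_s: float) -> np.ndarray:
    k = (1.0 - np.exp(-t_rel_s / rise_tau_s)) * np.exp(-t_rel_s / decay_tau_s)
    return np.where(t_rel_s >= 0, k, 0.0)


def _kernel_peak(rise_tau_s: float, decay_tau_s: float) -> tuple[float, float]:
    """Peak time (s after onset) and peak value of the response kernel."""
    t_peak = rise_tau_s * math.log1p(decay_tau_s / rise_tau_s)
    k_peak = (1.0 - math.exp(-t_peak / rise_tau_s)) * math.exp(-t_peak / decay_tau_s)
    return t_peak, k_peak


def _criterion_crossing(
    rise_tau_s: float, decay_tau_s: float, criterion: float = 0.2
) -> float:
    """Time (s after onset) at which the kernel reaches ``criterion`` of its peak."""
    t_peak, k_peak = _kernel_peak(rise_tau_s, decay_tau_s)
    target = criterion * k_peak

    def f(x: float) -> float:
        return (1.0 - math.exp(-x / rise_tau_s)) * math.exp(-x / decay_tau_s) - target

    return float(brentq(f, 1e-9, t_peak))


def generate_movie(
    params: CircuitParams,
    protocol: StimProtocol | None = None,
    seed: int = 0,
    amplitude_scale: float = 1.0,
) -> tuple[RawMovie, GroundTruth]:
    """Simulate one VSDI recording.

    ``amplitude_scale`` multiplies every region's drive; it models
    slice-to-slice differences in dye loading and cancels in the normalized
    analysis.  The same ``(params, protocol, seed, amplitude_scale)`` always
    reproduces the identical movie.
    """
    if protocol is None:
        protocol = StimProtocol()
    freq = protocol.effective_frequency_hz
    if freq <= 0:
        raise ValidationError("protocol frequency must be > 0")
    h, w = params.frame_shape
    dt_s = params.frame_interval_ms / 1000.0
    n_frames = int(round(protocol.record_duration_s / dt_s))
    times = np.arange(n_frames) * dt_s
    regions = default_regions((h, w))

    rise_tau_s = params.rise_tau_ms / 1000.0
    latencies = {
        "layerII": params.onset_latency_ms,
        "DEn": params.onset_latency_ms + params.lag1_ms,
        "layerIII": params.onset_latency_ms + params.lag2_ms,
    }

    dff = np.zeros((n_frames, h, w), dtype=np.float32)
    region_traces: dict[str, np.ndarray] = {}
    onsets: dict[str, float | None] = {}
    gains: dict[str, float] = {}
    amplitudes: dict[str, float] = {}
    peaks: dict[str, float] = {}
    crossing_s = _criterion_crossing(rise_tau_s, params.decay_tau_s)
    _, k_peak = _kernel_peak(rise_tau_s, params.decay_tau_s)
    for name, gain in params.gains.items():
        t_on = protocol.stim_onset_s + latencies[name] / 1000.0
        amp = amplitude_percent(gain, freq) * amplitude_scale
        trace = gain.polarity * amp * _kernel(times - t_on, rise_tau_s, params.decay_tau_s)
        region_traces[name] = trace
        dff[:, regions.mask(name)] = trace[:, None]
        gains[name] = normalized_gain(gain, freq)
        amplitudes[name] = amp
        peaks[name] = amp * k_peak
        onsets[name] = (
            None if amp == 0 else latencies[name] + crossing_s * 1000.0
        )

    bleach = (
        np.exp(-times / params.bleach_tau_s)
        if params.bleach_tau_s is not None
        else np.ones_like(times)
    )
    if params.noise_sd_percent > 0:
        # camera path: float32 is ample for ~3000-count frames, and the
        # counts are quantized to integers as a real sensor would deliver
        counts = (
            np.float32(params.f0_counts)
            * (np.float32(1.0) - dff / np.float32(100.0))
            * bleach.astype(np.float32)[:, None, None]
        )
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(size=counts.shape, dtype=np.float32)
        counts += np.float32(params.noise_sd_percent / 100.0 * params.f0_counts) * noise
        counts = np.clip(np.rint(counts), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    else:
        # idealized diagnostic path: continuous counts, no quantization
        counts = (
            params.f0_counts
            * (1.0 - dff.astype(np.float64) / 100.0)
            * bleach[:, None, None]
        )

    meta = MovieMeta(
        frame_interval_ms=params.frame_interval_ms,
        pixel_size_um=params.pixel_size_um,
        shape=(n_frames, h, w),
        protocol=protocol,
    )
    truth = GroundTruth(
        region_traces=region_traces,
        onsets_ms=onsets,
        latencies_ms=latencies,
        normalized_gain=gains,
        amplitudes_percent=amplitudes,
        peak_percent=peaks,
        frequency_hz=freq,
        seed=seed,
        amplitude_scale=amplitude_scale,
    )
    return RawMovie(meta=meta, frames=counts), truth


def simulate_slice(
    params: CircuitParams,
    frequencies: Sequence[float],
    seed: int,
    protocol: StimProtocol | None = None,
    loading_sd: float = 0.2,
) -> dict[float, tuple[RawMovie, GroundTruth]]:
    """Simulate one slice stimulated at several frequencies.

    A single lognormal dye-loading factor (sigma ``loading_sd``) scales all
    of the slice's recordings, emulating the slice-to-slice amplitude
    variability that motivates normalization to the 20 Hz response.
    """
    if protocol is None:
        protocol = StimProtocol()
    rng = np.random.default_rng(seed)
    scale = float(np.exp(rng.normal(0.0, loading_sd)))
    out: dict[float, tuple[RawMovie, GroundTruth]] = {}
    for freq in frequencies:
        movie_seed = int(rng.integers(0, 2**31 - 1))
        proto = replace(protocol, frequency_hz=float(freq))
        out[float(freq)] = generate_movie(
            params, proto, seed=movie_seed, amplitude_scale=scale
        )
    return out


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

#: Patch-clamp sweeps leave enough pre-train baseline for a 5 s window.
PATCH_PROTOCOL = StimProtocol(
    baseline_duration_s=5.0,
    train_duration_s=1.0,
    frequency_hz=60.0,
    record_duration_s=20.0,
)


def spike_rate(
    t_s: np.ndarray,
    baseline_hz: float,
    model: SpikeModel,
    protocol: StimProtocol,
) -> np.ndarray:
    """Programmed instantaneous firing rate of one layer III cell."""
    t_s = np.asarray(t_s, dtype=float)
    onset, offset = protocol.stim_onset_s, protocol.stim_offset_s
    rate = np.full_like(t_s, baseline_hz)
    rate[(t_s >= onset) & (t_s < offset)] = model.suppressed_rate_hz
    after = t_s >= offset
    rate[after] = baseline_hz - (baseline_hz - model.suppressed_rate_hz) * np.exp(
        -(t_s[after] - offset) / model.recovery_tau_s
    )
    return rate


def generate_spike_trains(
    params: CircuitParams,
    n: int,
    seed: int = 0,
    protocol: StimProtocol | None = None,
) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson spontaneous firing with post-train suppression.

    Each train draws its baseline rate uniformly from the spike model's
    range and is sampled by thinning a homogeneous Poisson process at the
    baseline rate.  Deterministic per ``seed``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if protocol is None:
        protocol = PATCH_PROTOCOL
    model = params.spike_model
    rng = np.random.default_rng(seed)
    duration = protocol.record_duration_s
    trains: list[SpikeTrain] = []
    for _ in range(n):
        lo, hi = model.baseline_rate_range_hz
        baseline = float(rng.uniform(lo, hi))
        n_hom = rng.poisson(baseline * duration)
        candidate = np.sort(rng.uniform(0.0, duration, size=n_hom))
        keep = rng.uniform(size=n_hom) * baseline <= spike_rate(
            candidate, baseline, model, protocol
        )
        times = np.unique(candidate[keep])
        trains.append(
            SpikeTrain(
                times_s=times,
                duration_s=duration,
                train_onset_s=protocol.stim_onset_s,
                train_duration_s=protocol.train_duration_s,
            )
        )
    return trains


__all__ = [
    "CONDITIONS",
    "GAIN_REF_HZ",
    "GAIN_TOP_HZ",
    "PATCH_PROTOCOL",
    "RegionGain",
    "SpikeModel",
    "CircuitParams",
    "GroundTruth",
    "default_params",
    "gain_curve_params",
    "normalized_gain",
    "amplitude_percent",
    "default_regions",
    "generate_movie",
    "simulate_slice",
    "spike_rate",
    "generate_spike_trains",
]
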