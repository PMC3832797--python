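"""Per-response measurements: magnitude, polarity, onset, lags, rate of rise.

All measurements operate on region or stripe traces extracted from a
processed :class:`~vsdikit.data_model.DffMovie`.  An undefined measurement
(no detectable response, degenerate geometry) is reported as ``None`` —
never silently as zero.

Definitions
-----------
magnitude
    Signed value of the extremum of largest absolute deviation from the
    pre-stimulus baseline mean within the response window (earliest frame
    wins ties).  Polarity is the sign of that extremum; it is ``"none"``
    when the extremum does not exceed ``k`` baseline standard deviations.
onset
    First time at or after stimulus onset at which the absolute deviation
    reaches ``criterion`` (default 20 %) of the peak deviation and stays
    there for ``persistence`` consecutive frames, reported in ms relative
    to stimulus onset.
Lag 1 / Lag 2
    DEn onset minus layer II onset, and layer III onset minus layer II
    onset.  In the intact circuit both are positive and Lag 1 < Lag 2.
rate of rise
    Slope of the least-squares line through the samples between the 20 %
    and 80 % crossings of the peak deviation, in percent ΔF/F per second
    (negative for hyperpolarizing responses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    RESPONSE_REGIONS,
    DffMovie,
    RegionSet,
    Stripe,
    Trace,
)
from .errors import NormalizationError, ValidationError

POLARITIES = ("excitatory", "inhibitory", "none")


@dataclass
class ResponseMeasure:
    """One region's response to one stimulation frequency."""

    slice_id: str
    region: str
    frequency_hz: float
    magnitude: float
    polarity: str
    normalized_magnitude: float | None = None
    onset_ms: float | None = None
    rate_of_rise: float | None = None

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValidationError(f"polarity must be one of {POLARITIES}")


@dataclass(frozen=True)
class LagPair:
    """Onset lags of DEn and layer III relative to layer II, in ms."""

    lag1_ms: float | None
    lag2_ms: float | None

    @property
    def defined(self) -> bool:
        return self.lag1_ms is not None and self.lag2_ms is not None


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------


def _movie_regions(dff: DffMovie, regions: RegionSet) -> RegionSet:
    """Map a native-resolution region set onto the movie's (binned) grid."""
    if regions.shape == dff.values.shape[1:]:
        return regions
    binned = regions.binned(dff.meta.bin_factor)
    if binned.shape != dff.values.shape[1:]:
        raise ValidationError(
            f"region map shape {regions.shape} matches neither the movie "
            f"({dff.values.shape[1:]}) nor its unbinned grid"
        )
    return binned


def extract_region_trace(dff: DffMovie, regions: RegionSet, name: str) -> Trace:
    """Unweighted mean ΔF/F over the named region, frame by frame."""
    rs = _movie_regions(dff, regions)
    if name not in rs.names:
        raise ValidationError(f"region {name!r} is empty after binning")
    mask = rs.mask(name)
    pixels = dff.values[:, mask]
    if pixels.shape[1] == 0:
        raise ValidationError(f"region {name!r} is empty after binning")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(pixels, axis=1)
    return Trace(
        time_s=dff.times_s(),
        values=values,
        units="percent_dff",
        provenance={"region": name},
    )


def extract_stripe_profile(dff: DffMovie, stripe: Stripe) -> Trace:
    """Mean ΔF/F over the stripe's 10 pixels, frame by frame."""
    if not stripe.in_frame(dff.values.shape[1:]):
        raise ValidationError("stripe extends outside the movie frame")
    rows = [r for r, _ in stripe.coords]
    cols = [c for _, c in stripe.coords]
    pixels = dff.values[:, rows, cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(pixels, axis=1)
    return Trace(
        time_s=dff.times_s(),
        values=values,
        units="percent_dff",
        provenance={"stripe": str(list(stripe.coords))},
    )


# ---------------------------------------------------------------------------
# scalar measurements
# ---------------------------------------------------------------------------


def _baseline_stats(trace: Trace, before_s: float) -> tuple[float, float]:
    sel = trace.time_s < before_s - 1e-12
    baseline = trace.values[sel]
    baseline = baseline[~np.isnan(baseline)]
    if baseline.size < 2:
        raise ValidationError("trace has fewer than 2 baseline samples")
    return float(baseline.mean()), float(baseline.std(ddof=0))


def response_magnitude(
    trace: Trace,
    window: tuple[float, float],
    polarity_k: float = 3.0,
) -> tuple[float, str]:
    """Signed peak deviation from baseline within the window, with polarity.

    ``window`` starts at stimulus onset; baseline statistics come from the
    samples before it.  The extremum of largest absolute deviation is
    signed; its polarity is ``"none"`` when it does not exceed
    ``polarity_k`` baseline standard deviations.
    """
    start, end = window
    if start >= end:
        raise ValidationError(f"empty response window {window}")
    t = trace.time_s
    if start < t[0] - 1e-12 or end > t[-1] + trace_dt(trace) + 1e-9:
        raise ValidationError(
            f"response window {window} lies outside the recording "
            f"[{t[0]:.3f}, {t[-1]:.3f}] s"
        )
    bl_mean, bl_sd = _baseline_stats(trace, start)
    sel = (t >= start - 1e-12) & (t <= end + 1e-12)
    dev = trace.values[sel] - bl_mean
    dev = np.where(np.isnan(dev), 0.0, dev)
    idx = int(np.argmax(np.abs(dev)))  # argmax returns the earliest maximum
    magnitude = float(dev[idx])
    # 1e-9 % ΔF/F is numerical zero: guards the degenerate noise-free case
    # where the baseline SD is itself zero up to float rounding
    if abs(magnitude) < max(polarity_k * bl_sd, 1e-9):
        polarity = "none"
    elif magnitude > 0:
        polarity = "excitatory"
    else:
        polarity = "inhibitory"
    return magnitude, polarity


def trace_dt(trace: Trace) -> float:
    if len(trace) < 2:
        return 0.0
    return float(trace.time_s[1] - trace.time_s[0])


def estimate_onset(
    trace: Trace,
    stim_onset_s: float,
    criterion: float = 0.20,
    persistence: int = 2,
    window: tuple[float, float] | None = None,
) -> float | None:
    """Time for the response to reach ``criterion`` of its peak deviation.

    Returns the onset in ms relative to ``stim_onset_s``, or ``None`` when
    the trace never crosses the threshold for ``persistence`` consecutive
    frames.  The measure is invariant to positive rescaling of the trace and
    shifts with it in time.
    """
    if not 0.0 < criterion < 1.0:
        raise ValidationError("criterion must lie strictly between 0 and 1")
    if persistence < 1:
        raise ValidationError("persistence must be >= 1")
    t = trace.time_s
    if stim_onset_s < t[0] or stim_onset_s > t[-1]:
        raise ValidationError("stimulus onset lies outside the recording")
    if window is None:
        window = (stim_onset_s, float(t[-1]))
    bl_mean, _ = _baseline_stats(trace, stim_onset_s)
    sel = (t >= window[0] - 1e-12) & (t <= window[1] + 1e-12)
    idx = np.flatnonzero(sel)
    dev = np.abs(trace.values[idx] - bl_mean)
    dev = np.where(np.isnan(dev), 0.0, dev)
    peak = dev.max() if dev.size else 0.0
    if peak <= 0:
        return None
    threshold = criterion * peak
    above = dev >= threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persistence:
            first = i - persistence + 1
            return float((t[idx[first]] - stim_onset_s) * 1000.0)
    return None


def lags(
    onset_layerII_ms: float | None,
    onset_DEn_ms: float | None,
    onset_layerIII_ms: float | None,
) -> LagPair:
    """Lag 1 = DEn - layer II onset, Lag 2 = layer III - layer II onset."""
    if onset_layerII_ms is None:
        return LagPair(lag1_ms=None, lag2_ms=None)
    lag1 = None if onset_DEn_ms is None else onset_DEn_ms - onset_layerII_ms
    lag2 = None if onset_layerIII_ms is None else onset_layerIII_ms - onset_layerII_ms
    return LagPair(lag1_ms=lag1, lag2_ms=lag2)


def rate_of_rise(
    trace: Trace,
    stim_onset_s: float,
    window: tuple[float, float] | None = None,
) -> float | None:
    """Least-squares slope between the 20 % and 80 % peak-deviation crossings.

    Reported in percent ΔF/F per second, signed like the response (negative
    for hyperpolarizing responses).  ``None`` when fewer than two samples lie
    between the crossings (e.g. a step sampled too coarsely).
    """
    t = trace.time_s
    if window is None:
        window = (stim_onset_s, float(t[-1]))
    bl_mean, _ = _baseline_stats(trace, stim_onset_s)
    sel = (t >= window[0] - 1e-12) & (t <= window[1] + 1e-12)
    idx = np.flatnonzero(sel)
    dev = trace.values[idx] - bl_mean
    dev = np.where(np.isnan(dev), 0.0, dev)
    if dev.size == 0:
        return None
    peak_i = int(np.argmax(np.abs(dev)))
    peak = dev[peak_i]
    if peak == 0:
        return None
    sign = 1.0 if peak > 0 else -1.0
    rect = sign * dev  # rising and positive regardless of polarity
    mag = rect[peak_i]
    lo = np.flatnonzero(rect >= 0.2 * mag)
    if lo.size == 0:
        return None
    i20 = lo[0]
    hi = np.flatnonzero(rect[i20:] >= 0.8 * mag)
    if hi.size == 0:
        return None
    i80 = i20 + hi[0]
    if i80 - i20 + 1 < 2:
        return None
    seg = slice(i20, i80 + 1)
    slope = np.polyfit(t[idx[seg]], rect[seg], 1)[0]
    return float(sign * slope)


def normalize_to_reference(
    measures: Iterable[ResponseMeasure], ref_freq: float = 20.0
) -> list[ResponseMeasure]:
    """Divide each magnitude by |magnitude at ``ref_freq``| of its slice/region.

    The reference entry maps to exactly +1 or -1.  A missing or zero
    reference raises :class:`NormalizationError` naming the group.
    """
    measures = list(measures)
    groups: dict[tuple[str, str], float] = {}
    for m in measures:
        if np.isclose(m.frequency_hz, ref_freq):
            groups[(m.slice_id, m.region)] = m.magnitude
    out = []
    for m in measures:
        key = (m.slice_id, m.region)
        if key not in groups:
            raise NormalizationError(
                f"no {ref_freq:g} Hz reference response for slice "
                f"{m.slice_id!r}, region {m.region!r}"
            )
        ref = groups[key]
        if ref == 0:
            raise NormalizationError(
                f"zero {ref_freq:g} Hz reference response for slice "
                f"{m.slice_id!r}, region {m.region!r}"
            )
        if np.isclose(m.frequency_hz, ref_freq):
            normalized = float(np.sign(m.magnitude))
        else:
            normalized = m.magnitude / abs(ref)
        out.append(replace(m, normalized_magnitude=normalized))
    return out


# ---------------------------------------------------------------------------
# movie-level driver and result tables
# ---------------------------------------------------------------------------


def measure_movie(
    dff: DffMovie,
    regions: RegionSet,
    slice_id: str = "slice",
    criterion: float = 0.20,
    persistence: int = 2,
    polarity_k: float = 3.0,
    response_window_s: float = 10.0,
    region_names: Sequence[str] | None = None,
) -> tuple[list[ResponseMeasure], LagPair]:
    """Measure every response region of one processed movie.

    The response window runs from stimulus onset to ``response_window_s``
    later (clipped to the recording end).  Returns the per-region measures
    and the movie's lag pair.
    """
    protocol = dff.meta.protocol
    t_end = float(dff.times_s()[-1])
    window = (protocol.stim_onset_s, min(protocol.stim_onset_s + response_window_s, t_end))
    names = list(region_names) if region_names is not None else [
        n for n in RESPONSE_REGIONS if n in regions.names
    ]
    onsets: dict[str, float | None] = {}
    out: list[ResponseMeasure] = []
    for name in names:
        trace = extract_region_trace(dff, regions, name)
        magnitude, polarity = response_magnitude(trace, window, polarity_k=polarity_k)
        onset = estimate_onset(
            trace,
            protocol.stim_onset_s,
            criterion=criterion,
            persistence=persistence,
            window=window,
        )
        rise = rate_of_rise(trace, protocol.stim_onset_s, window=window)
        onsets[name] = onset
        out.append(
            ResponseMeasure(
                slice_id=slice_id,
                region=name,
                frequency_hz=protocol.effective_frequency_hz,
                magnitude=magnitude,
                polarity=polarity,
                onset_ms=onset,
                rate_of_rise=rise,
            )
        )
    pair = lags(
        onsets.get("layerII"), onsets.get("DEn"), onsets.get("layerIII")
    )
    return out, pair


RESULT_COLUMNS = [
    "slice_id",
    "region",
    "frequency_hz",
    "magnitude",
    "normalized_magnitude",
    "polarity",
    "onset_ms",
    "lag1_ms",
    "lag2_ms",
    "rate_of_rise",
]


def measures_to_frame(
    measures: Iterable[ResponseMeasure],
    lag_pairs: dict[tuple[str, float], LagPair] | None = None,
) -> pd.DataFrame:
    """Tabulate measures; lags (keyed by slice and frequency) repeat per row."""
    rows = []
    for m in measures:
        pair = None
        if lag_pairs is not None:
            pair = lag_pairs.get((m.slice_id, m.frequency_hz))
        rows.append(
            {
                "slice_id": m.slice_id,
                "region": m.region,
                "frequency_hz": m.frequency_hz,
                "magnitude": m.magnitude,
                "normalized_magnitude": m.normalized_magnitude,
                "polarity": m.polarity,
                "onset_ms": m.onset_ms,
                "lag1_ms": None if pair is None else pair.lag1_ms,
                "lag2_ms": None if pair is None else pair.lag2_ms,
                "rate_of_rise": m.rate_of_rise,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.9g")
    return path


__all__ = [
    "POLARITIES",
    "ResponseMeasure",
    "LagPair",
    "extract_region_trace",
    "extract_stripe_profile",
    "response_magnitude",
    "estimate_onset",
    "lags",
    "rate_of_rise",
    "normalize_to_reference",
    "measure_movie",
    "measures_to_frame",
    "write_results_csv",
    "RESULT_COLUMNS",
]
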