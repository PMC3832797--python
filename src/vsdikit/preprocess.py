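"""Raw counts -> bleach-corrected, sign-conventioned, binned ΔF/F.

The processing chain is ``compute_dff -> bleach_correct -> bin_pixels``.  The
dye dims as the membrane depolarizes, so with the default sign inversion a
depolarization appears as a positive ΔF/F and a hyperpolarization as negative,
matching conventional electrophysiological display.

Photobleaching is removed by subtracting, frame by frame, the mean ΔF/F trace
of a user-designated reference region that does not respond to the stimulus.
This removes any common-mode signal (bleaching, lamp drift) exactly, at the
cost of adding the reference region's noise to every pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data_model import DffMovie, RawMovie, RegionSet, Trace
from .errors import DataQualityError, StateError, ValidationError


@dataclass(frozen=True)
class Calibration:
    """Conversion between percent ΔF/F and membrane potential.

    Derived from a high-K⁺ depolarization experiment: perfusing 80 mM K⁺
    depolarizes cells from rest (about -70 mV) to about 0 mV and dims the dye
    by ``source_total_percent``; the ratio gives percent per 10 mV.
    """

    percent_per_10mV: float
    source_total_percent: float
    source_span_mV: float

    def __post_init__(self) -> None:
        expected = self.source_total_percent / (self.source_span_mV / 10.0)
        if abs(self.percent_per_10mV - expected) > 1e-9:
            raise ValidationError(
                "inconsistent calibration: percent_per_10mV must equal "
                "source_total_percent / (source_span_mV / 10)"
            )


def calibrate(total_percent: float, span_mV: float) -> Calibration:
    """Build a :class:`Calibration` from a total ΔF over a voltage span.

    ``calibrate(6.3, 70)`` — a 6.3 % fluorescence change over a 70 mV
    depolarization — yields 0.9 % per 10 mV.
    """
    if span_mV <= 0:
        raise ValidationError("span_mV must be > 0")
    return Calibration(
        percent_per_10mV=total_percent / (span_mV / 10.0),
        source_total_percent=total_percent,
        source_span_mV=span_mV,
    )


def dff_to_mV(trace: Trace, cal: Calibration) -> Trace:
    """Convert a sign-inverted percent ΔF/F trace to mV of depolarization."""
    if cal.percent_per_10mV == 0:
        raise ValidationError("cannot convert with a zero calibration slope")
    return Trace(
        time_s=trace.time_s,
        values=trace.values * (10.0 / cal.percent_per_10mV),
        units="mV",
        provenance=dict(trace.provenance),
    )


def mV_to_dff(trace: Trace, cal: Calibration) -> Trace:
    """Inverse of :func:`dff_to_mV`."""
    if cal.percent_per_10mV == 0:
        raise ValidationError("cannot convert with a zero calibration slope")
    return Trace(
        time_s=trace.time_s,
        values=trace.values * (cal.percent_per_10mV / 10.0),
        units="percent_dff",
        provenance=dict(trace.provenance),
    )


def compute_dff(
    raw: RawMovie,
    baseline_window: tuple[float, float] | None = None,
    invert: bool = True,
    max_invalid_fraction: float = 0.05,
) -> DffMovie:
    """Per-pixel fractional fluorescence change relative to the baseline epoch.

    The background F0 of each pixel is its mean count over the baseline
    window (by default the whole pre-stimulus epoch) and
    ``value(t) = 100 * (F(t) - F0) / F0``, multiplied by -1 when ``invert``
    is set.  Pixels with F0 = 0 are flagged invalid (NaN), not divided; if
    more than ``max_invalid_fraction`` of pixels are invalid the movie is
    rejected as unusable.
    """
    protocol = raw.meta.protocol
    if baseline_window is None:
        baseline_window = (0.0, protocol.baseline_duration_s)
    start, end = baseline_window
    if end > protocol.stim_onset_s + 1e-9:
        raise ValidationError(
            f"baseline window {baseline_window} overlaps the stimulus "
            f"(onset at {protocol.stim_onset_s} s)"
        )
    if start < 0 or end <= start:
        raise ValidationError(f"invalid baseline window {baseline_window}")
    # frames whose start time falls inside the window
    times = raw.times_s()
    sel = (times >= start - 1e-12) & (times < end - 1e-12)
    if sel.sum() < 2:
        raise ValidationError("baseline window must contain at least 2 frames")

    frames = raw.frames.astype(np.float64, copy=False)
    f0 = frames[sel].mean(axis=0)
    invalid = f0 <= 0
    if invalid.mean() > max_invalid_fraction:
        raise DataQualityError(
            f"{invalid.mean():.1%} of pixels have a zero baseline "
            f"(limit {max_invalid_fraction:.1%})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 100.0 * (frames - f0) / f0
    if invert:
        values = -values
    values[:, invalid] = np.nan
    return DffMovie(
        meta=raw.meta,
        values=values,
        sign_inverted=invert,
        bleach_corrected=False,
        invalid=invalid,
    )


def reference_trace(dff: DffMovie, regions: RegionSet) -> np.ndarray:
    """Mean ΔF/F trace of the reference region (invalid pixels excluded)."""
    if "reference" not in regions.names:
        raise ValidationError("region set does not define a 'reference' region")
    if regions.shape != dff.values.shape[1:]:
        raise ValidationError(
            f"region map shape {regions.shape} does not match movie spatial "
            f"shape {dff.values.shape[1:]}"
        )
    mask = regions.mask("reference")
    pixels = dff.values[:, mask]
    if pixels.shape[1] == 0:
        raise ValidationError("reference region is empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ref = np.nanmean(pixels, axis=1)
    if np.isnan(ref).any():
        raise DataQualityError("reference region has frames with no valid pixel")
    return ref


def bleach_correct(dff: DffMovie, regions: RegionSet) -> DffMovie:
    """Subtract the reference region's mean trace from every pixel.

    After correction the reference region's own mean trace is identically
    zero, so any signal shared by the whole frame (photobleaching, lamp
    drift) is removed exactly.  Applying the correction twice is refused.
    """
    if dff.bleach_corrected:
        raise StateError("movie is already bleach-corrected")
    ref = reference_trace(dff, regions)
    values = dff.values - ref[:, None, None]
    return DffMovie(
        meta=dff.meta,
        values=values,
        sign_inverted=dff.sign_inverted,
        bleach_corrected=True,
        invalid=dff.invalid,
    )


def bin_pixels(dff: DffMovie, factor: int = 3) -> DffMovie:
    """Average non-overlapping ``factor x factor`` pixel blocks per frame.

    Trailing rows/columns that do not fill a block are dropped.  Invalid
    (NaN) pixels are excluded from each block mean; a block with no valid
    pixel stays NaN.  The pixel size is scaled by ``factor``.
    """
    if factor < 1:
        raise ValidationError("bin factor must be >= 1")
    if factor == 1:
        return dff
    t, h, w = dff.values.shape
    hb, wb = h // factor, w // factor
    if hb == 0 or wb == 0:
        raise ValidationError(
            f"bin factor {factor} exceeds the spatial extent {h}x{w}"
        )
    blocks = dff.values[:, : hb * factor, : wb * factor].reshape(
        t, hb, factor, wb, factor
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(blocks, axis=(2, 4))
    invalid = np.isnan(values).all(axis=0)
    meta = replace(
        dff.meta,
        shape=(t, hb, wb),
        pixel_size_um=dff.meta.pixel_size_um * factor,
        bin_factor=dff.meta.bin_factor * factor,
    )
    return DffMovie(
        meta=meta,
        values=values,
        sign_inverted=dff.sign_inverted,
        bleach_corrected=dff.bleach_corrected,
        invalid=invalid,
    )


def preprocess_movie(
    raw: RawMovie,
    regions: RegionSet,
    baseline_window: tuple[float, float] | None = None,
    invert: bool = True,
    bin_factor: int = 3,
    max_invalid_fraction: float = 0.05,
) -> DffMovie:
    """Full chain: ΔF/F, bleach correction, spatial binning."""
    dff = compute_dff(
        raw,
        baseline_window=baseline_window,
        invert=invert,
        max_invalid_fraction=max_invalid_fraction,
    )
    dff = bleach_correct(dff, regions)
    return bin_pixels(dff, factor=bin_factor)


__all__ = [
    "Calibration",
    "calibrate",
    "dff_to_mV",
    "mV_to_dff",
    "compute_dff",
    "reference_trace",
    "bleach_correct",
    "bin_pixels",
    "preprocess_movie",
]
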