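"""Core data types and file I/O for VSDI movies, regions, stripes and traces.

The on-disk layout is deliberately tool-agnostic: movies are multi-frame
16-bit unsigned TIFF stacks with a JSON sidecar carrying acquisition metadata
and the stimulation protocol; region sets are either a label TIFF plus a JSON
name map or a pure-JSON polygon file; traces are two-column CSV with a units
header line.

Conventions
-----------
Frames are indexed ``(t, row, col)``, 0-based, origin at the top-left corner;
the physical position of a pixel is ``index * pixel_size_um``.  Time zero is
the first frame of the recording and the stimulus train starts at the end of
the pre-stimulus baseline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

#: The anatomical regions the analysis knows about.  ``reference`` marks the
#: stimulus-unresponsive area used for photobleaching correction.
REGION_NAMES = ("layerII", "DEn", "layerIII", "reference")

RESPONSE_REGIONS = ("layerII", "DEn", "layerIII")

#: Number of pixels in a quantification stripe (covers 250 um at 25 um/pixel).
STRIPE_LENGTH = 10


# ---------------------------------------------------------------------------
# protocol and metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimProtocol:
    """Timing of one recording: a pre-stimulus baseline followed by a pulse train.

    Parameters
    ----------
    baseline_duration_s:
        Length of the background-activity epoch recorded before the stimulus.
    train_duration_s:
        Length of the stimulus train.
    frequency_hz:
        Pulse rate of the train.  When ``n_pulses`` is set the effective
        frequency is ``n_pulses / train_duration_s`` instead (fixed-pulse-count
        protocols).
    pulse_width_ms:
        Width of each square pulse.
    n_pulses:
        Optional fixed pulse count overriding ``frequency_hz``.
    record_duration_s:
        Total sweep length, baseline included.
    """

    baseline_duration_s: float = 2.0
    train_duration_s: float = 1.0
    frequency_hz: float = 40.0
    pulse_width_ms: float = 2.0
    n_pulses: int | None = None
    record_duration_s: float = 20.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValidationError("frequency_hz must be > 0")
        if self.baseline_duration_s < 0 or self.train_duration_s <= 0:
            raise ValidationError("baseline and train durations must be positive")
        if self.pulse_width_ms <= 0:
            raise ValidationError("pulse_width_ms must be > 0")
        if self.baseline_duration_s + self.train_duration_s > self.record_duration_s:
            raise ValidationError(
                "baseline + train duration exceeds the recording duration"
            )
        if self.n_pulses is not None and self.n_pulses < 1:
            raise ValidationError("n_pulses must be >= 1 when given")

    @property
    def effective_frequency_hz(self) -> float:
        """Pulse rate actually delivered (``n_pulses`` takes precedence)."""
        if self.n_pulses is not None:
            return self.n_pulses / self.train_duration_s
        return self.frequency_hz

    @property
    def stim_onset_s(self) -> float:
        return self.baseline_duration_s

    @property
    def stim_offset_s(self) -> float:
        return self.baseline_duration_s + self.train_duration_s

    def to_dict(self) -> dict:
        return {
            "baseline_duration_s": self.baseline_duration_s,
            "train_duration_s": self.train_duration_s,
            "frequency_hz": self.frequency_hz,
            "pulse_width_ms": self.pulse_width_ms,
            "n_pulses": self.n_pulses,
            "record_duration_s": self.record_duration_s,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StimProtocol":
        required = (
            "baseline_duration_s",
            "train_duration_s",
            "frequency_hz",
            "record_duration_s",
        )
        for key in required:
            if key not in d:
                raise ValidationError(f"protocol metadata missing field {key!r}")
        return cls(
            baseline_duration_s=float(d["baseline_duration_s"]),
            train_duration_s=float(d["train_duration_s"]),
            frequency_hz=float(d["frequency_hz"]),
            pulse_width_ms=float(d.get("pulse_width_ms", 2.0)),
            n_pulses=None if d.get("n_pulses") is None else int(d["n_pulses"]),
            record_duration_s=float(d["record_duration_s"]),
        )


@dataclass(frozen=True)
class MovieMeta:
    """Acquisition metadata attached to every movie.

    ``bin_factor`` tracks how many raw camera pixels each current pixel edge
    represents (1 for unbinned data); ``pixel_size_um`` always refers to the
    current grid.
    """

    frame_interval_ms: float
    pixel_size_um: float
    shape: tuple[int, int, int]
    protocol: StimProtocol
    bin_factor: int = 1

    def __post_init__(self) -> None:
        if self.frame_interval_ms <= 0:
            raise ValidationError("frame_interval_ms must be > 0")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValidationError(f"shape must be three positive integers, got {shape}")
        if self.bin_factor < 1:
            raise ValidationError("bin_factor must be >= 1")
        # Partial recordings are allowed, but the baseline epoch must be covered.
        covered_s = shape[0] * self.frame_interval_ms / 1000.0
        if covered_s + 1e-9 < self.protocol.baseline_duration_s:
            raise ValidationError(
                "recording shorter than the pre-stimulus baseline "
                f"({covered_s:.3f} s < {self.protocol.baseline_duration_s:.3f} s)"
            )

    @property
    def n_frames(self) -> int:
        return self.shape[0]

    def times_s(self) -> np.ndarray:
        """Frame timestamps in seconds (frame start times)."""
        return np.arange(self.n_frames) * (self.frame_interval_ms / 1000.0)

    def to_dict(self) -> dict:
        return {
            "frame_interval_ms": self.frame_interval_ms,
            "pixel_size_um": self.pixel_size_um,
            "shape": list(self.shape),
            "bin_factor": self.bin_factor,
            "protocol": self.protocol.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MovieMeta":
        for key in ("frame_interval_ms", "pixel_size_um", "shape", "protocol"):
            if key not in d:
                raise ValidationError(f"movie metadata missing field {key!r}")
        return cls(
            frame_interval_ms=float(d["frame_interval_ms"]),
            pixel_size_um=float(d["pixel_size_um"]),
            shape=tuple(int(s) for s in d["shape"]),
            protocol=StimProtocol.from_dict(d["protocol"]),
            bin_factor=int(d.get("bin_factor", 1)),
        )


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------


@dataclass
class RawMovie:
    """Camera output: nonnegative fluorescence counts, ``T x H x W``."""

    meta: MovieMeta
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a T x H x W array")
        if self.frames.shape != self.meta.shape:
            raise ValidationError(
                f"frame array shape {self.frames.shape} does not match "
                f"metadata shape {self.meta.shape}"
            )
        if self.frames.size == 0:
            raise ValidationError("movie has no frames")
        if np.nanmin(self.frames) < 0:
            raise ValidationError("fluorescence counts must be nonnegative")

    def times_s(self) -> np.ndarray:
        return self.meta.times_s()


@dataclass
class DffMovie:
    """Fractional fluorescence change in percent, ``T x H x W``.

    With ``sign_inverted`` set (the default analysis convention) depolarization
    is positive and hyperpolarization negative, i.e. the raw dye dimming has
    been multiplied by -1.  Pixels flagged in ``invalid`` (zero baseline) hold
    NaN and are excluded from every downstream average.
    """

    meta: MovieMeta
    values: np.ndarray
    sign_inverted: bool = True
    bleach_corrected: bool = False
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("values must be a T x H x W array")
        if self.values.shape != self.meta.shape:
            raise ValidationError(
                f"value array shape {self.values.shape} does not match "
                f"metadata shape {self.meta.shape}"
            )
        if self.invalid is not None:
            self.invalid = np.asarray(self.invalid, dtype=bool)
            if self.invalid.shape != self.values.shape[1:]:
                raise ValidationError("invalid mask must match the spatial shape")

    def times_s(self) -> np.ndarray:
        return self.meta.times_s()


# ---------------------------------------------------------------------------
# regions and stripes
# ---------------------------------------------------------------------------


@dataclass
class RegionSet:
    """Named anatomical regions as a label image.

    ``labels`` is an ``H x W`` integer map (0 = background) and ``names`` maps
    region names (a subset of :data:`REGION_NAMES`) to label values.  A label
    map is disjoint by construction; polygon input is rasterized by pixel-center
    inclusion and checked for overlap.
    """

    labels: np.ndarray
    names: dict[str, int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label map must be integer-valued")
        for name, label in self.names.items():
            if name not in REGION_NAMES:
                raise ValidationError(
                    f"unknown region name {name!r}; expected one of {REGION_NAMES}"
                )
            if label <= 0:
                raise ValidationError("region labels must be positive integers")
            if not (self.labels == label).any():
                raise ValidationError(f"region {name!r} is empty")
        labels = list(self.names.values())
        if len(set(labels)) != len(labels):
            raise ValidationError("two region names share one label value")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, name: str) -> np.ndarray:
        if name not in self.names:
            raise ValidationError(f"region {name!r} not defined in this RegionSet")
        return self.labels == self.names[name]

    def binned(self, factor: int) -> "RegionSet":
        """Region set on the grid produced by ``factor x factor`` pixel binning.

        A binned pixel belongs to a region only when every covered source pixel
        carries that region's label, so binned traces never mix regions.
        """
        if factor == 1:
            return self
        h, w = self.labels.shape
        hb, wb = h // factor, w // factor
        if hb == 0 or wb == 0:
            raise ValidationError("bin factor larger than the label map")
        blocks = self.labels[: hb * factor, : wb * factor].reshape(
            hb, factor, wb, factor
        )
        first = blocks[:, :1, :, :1]
        uniform = (blocks == first).all(axis=(1, 3))
        binned = np.where(uniform, blocks[:, 0, :, 0], 0)
        names = {n: l for n, l in self.names.items() if (binned == l).any()}
        if not names:
            raise ValidationError("no region survives binning")
        return RegionSet(labels=binned, names=names)

    @classmethod
    def from_polygons(
        cls,
        polygons: Mapping[str, Sequence[Sequence[float]]],
        shape: tuple[int, int],
    ) -> "RegionSet":
        """Rasterize ``name -> [(row, col), ...]`` polygons by center inclusion."""
        from matplotlib.path import Path as MplPath

        h, w = shape
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        points = np.column_stack([cols.ravel(), rows.ravel()])
        labels = np.zeros((h, w), dtype=np.int32)
        names: dict[str, int] = {}
        for i, (name, verts) in enumerate(polygons.items(), start=1):
            if len(verts) < 3:
                raise ValidationError(f"polygon for {name!r} needs >= 3 vertices")
            path = MplPath([(c, r) for r, c in verts])
            inside = path.contains_points(points).reshape(h, w)
            if not inside.any():
                raise ValidationError(f"polygon for {name!r} covers no pixel center")
            if (labels[inside] != 0).any():
                raise ValidationError(f"polygon for {name!r} overlaps another region")
            labels[inside] = i
            names[name] = i
        return cls(labels=labels, names=names)


@dataclass(frozen=True)
class Stripe:
    """An ordered chain of exactly 10 pixel coordinates (nominally 250 um)."""

    coords: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        coords = tuple((int(r), int(c)) for r, c in self.coords)
        object.__setattr__(self, "coords", coords)
        if len(coords) != STRIPE_LENGTH:
            raise ValidationError(
                f"a stripe must contain exactly {STRIPE_LENGTH} pixels, "
                f"got {len(coords)}"
            )
        for (r0, c0), (r1, c1) in zip(coords, coords[1:]):
            cheb = max(abs(r1 - r0), abs(c1 - c0))
            if cheb != 1:
                raise ValidationError(
                    "consecutive stripe pixels must be 4- or 8-adjacent "
                    f"(offending pair: {(r0, c0)} -> {(r1, c1)})"
                )

    def in_frame(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return all(0 <= r < h and 0 <= c < w for r, c in self.coords)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """A 1-D time series with units and provenance.

    ``units`` is a free-form label; the package uses ``"percent_dff"`` for
    optical traces and ``"mV"`` for voltage.
    """

    time_s: np.ndarray
    values: np.ndarray
    units: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("trace time and values must be 1-D")
        if len(self.time_s) != len(self.values):
            raise ValidationError("trace time and values differ in length")
        if len(self.time_s) and np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("trace time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_UINT16_MAX = np.iinfo(np.uint16).max


def read_movie(tiff_path: str | Path, meta_path: str | Path) -> RawMovie:
    """Read a TIFF stack and its JSON sidecar into a :class:`RawMovie`."""
    tiff_path, meta_path = Path(tiff_path), Path(meta_path)
    with open(meta_path) as fh:
        meta = MovieMeta.from_dict(json.load(fh))
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:  # single-frame stacks come back squeezed
        frames = frames[None, ...]
    if frames.shape != meta.shape:
        raise FormatError(
            f"TIFF shape {frames.shape} does not match metadata shape {meta.shape}"
        )
    return RawMovie(meta=meta, frames=frames)


def write_movie(
    movie: RawMovie, tiff_path: str | Path, meta_path: str | Path
) -> tuple[Path, Path]:
    """Write a movie as 16-bit TIFF plus JSON sidecar (lossless for counts)."""
    tiff_path, meta_path = Path(tiff_path), Path(meta_path)
    frames = np.asarray(movie.frames)
    if frames.size == 0:
        raise ValidationError("refusing to write an empty movie")
    if np.nanmax(frames) > _UINT16_MAX or np.nanmin(frames) < 0:
        raise FormatError(
            f"counts outside the 16-bit range [0, {_UINT16_MAX}] cannot be "
            "written losslessly"
        )
    if not np.issubdtype(frames.dtype, np.integer):
        rounded = np.rint(frames)
        if not np.allclose(frames, rounded, rtol=0, atol=1e-6):
            raise FormatError("non-integer counts cannot be written to 16-bit TIFF")
        frames = rounded
    tifffile.imwrite(tiff_path, frames.astype(np.uint16), photometric="minisblack")
    with open(meta_path, "w") as fh:
        json.dump(movie.meta.to_dict(), fh, indent=1)
    return tiff_path, meta_path


def read_regions(
    path: str | Path, names_path: str | Path | None = None
) -> RegionSet:
    """Read a region set.

    Two encodings are accepted: a label TIFF plus a JSON name map
    (``read_regions("regions.tif", "regions.json")``), or a single JSON file
    with ``{"shape": [H, W], "polygons": {name: [[row, col], ...]}}``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json" and names_path is None:
        with open(path) as fh:
            spec = json.load(fh)
        if "polygons" not in spec or "shape" not in spec:
            raise FormatError("polygon region file needs 'shape' and 'polygons'")
        return RegionSet.from_polygons(spec["polygons"], tuple(spec["shape"]))
    if names_path is None:
        raise ValidationError("label-image regions need a JSON name map path")
    labels = tifffile.imread(path)
    with open(names_path) as fh:
        names = {str(k): int(v) for k, v in json.load(fh).items()}
    return RegionSet(labels=labels.astype(np.int32), names=names)


def write_regions(
    regions: RegionSet, path: str | Path, names_path: str | Path
) -> tuple[Path, Path]:
    path, names_path = Path(path), Path(names_path)
    tifffile.imwrite(path, regions.labels.astype(np.uint16), photometric="minisblack")
    with open(names_path, "w") as fh:
        json.dump(regions.names, fh, indent=1)
    return path, names_path


_UNITS_RE = re.compile(r"^#\s*units\s*=\s*(\S+)\s*$")


def write_trace_csv(trace: Trace, path: str | Path) -> Path:
    """Write a trace as CSV with a ``# units=...`` header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# units={trace.units}\n")
        for key, value in sorted(trace.provenance.items()):
            fh.write(f"# {key}={value}\n")
        pd.DataFrame({"time_s": trace.time_s, "value": trace.values}).to_csv(
            fh, index=False, float_format="%.12g"
        )
    return path


def read_trace_csv(path: str | Path) -> Trace:
    path = Path(path)
    units = None
    provenance: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _UNITS_RE.match(line)
            if m:
                units = m.group(1)
            else:
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    provenance[key.strip()] = value.strip()
    if units is None:
        raise ValidationError(f"{path}: missing '# units=...' header line")
    table = pd.read_csv(path, comment="#")
    if not {"time_s", "value"} <= set(table.columns):
        raise FormatError(f"{path}: expected columns 'time_s' and 'value'")
    return Trace(
        time_s=table["time_s"].to_numpy(),
        values=table["value"].to_numpy(),
        units=units,
        provenance=provenance,
    )


__all__ = [
    "REGION_NAMES",
    "RESPONSE_REGIONS",
    "STRIPE_LENGTH",
    "StimProtocol",
    "MovieMeta",
    "RawMovie",
    "DffMovie",
    "RegionSet",
    "Stripe",
    "Trace",
    "read_movie",
    "write_movie",
    "read_regions",
    "write_regions",
    "read_trace_csv",
    "write_trace_csv",
]
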