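"""Shared fixtures: small deterministic movies, regions and traces."""

import numpy as np
import pytest

from vsdikit.data_model import MovieMeta, RawMovie, RegionSet, StimProtocol, Trace


def make_protocol(**kwargs) -> StimProtocol:
    defaults = dict(
        baseline_duration_s=1.0,
        train_duration_s=1.0,
        frequency_hz=40.0,
        record_duration_s=6.0,
    )
    defaults.update(kwargs)
    return StimProtocol(**defaults)


def make_movie(
    frames: np.ndarray,
    frame_interval_ms: float = 10.0,
    protocol: StimProtocol | None = None,
) -> RawMovie:
    frames = np.asarray(frames)
    if protocol is None:
        # baseline 0 so arbitrarily short stacks satisfy baseline coverage
        protocol = StimProtocol(
            baseline_duration_s=0.0,
            train_duration_s=1.0,
            frequency_hz=40.0,
            record_duration_s=6.0,
        )
    meta = MovieMeta(
        frame_interval_ms=frame_interval_ms,
        pixel_size_um=25.0,
        shape=frames.shape,
        protocol=protocol,
    )
    return RawMovie(meta=meta, frames=frames)


def make_trace(values, dt_s: float = 0.01, units: str = "percent_dff") -> Trace:
    values = np.asarray(values, dtype=float)
    return Trace(
        time_s=np.arange(len(values)) * dt_s, values=values, units=units
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_regions():
    """A 12x12 region set: three response bands and a reference band."""
    labels = np.zeros((12, 12), dtype=np.int32)
    labels[0:3, :] = 1
    labels[3:6, :] = 2
    labels[6:9, :] = 3
    labels[9:12, :] = 4
    return RegionSet(
        labels=labels,
        names={"layerII": 1, "DEn": 2, "layerIII": 3, "reference": 4},
    )
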