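"""ΔF/F computation, bleach correction, binning and voltage calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsdikit.errors import (
    DataQualityError,
    FormatError,
    StateError,
    ValidationError,
)
from vsdikit.preprocess import (
    bin_pixels,
    bleach_correct,
    calibrate,
    compute_dff,
    dff_to_mV,
    mV_to_dff,
    preprocess_movie,
)
from vsdikit.data_model import Trace

from conftest import make_movie, make_protocol


def movie_with_baseline(frames, frame_interval_ms=10.0, baseline_s=1.0):
    return make_movie(
        frames,
        frame_interval_ms=frame_interval_ms,
        protocol=make_protocol(baseline_duration_s=baseline_s),
    )


class TestComputeDff:
    def test_constant_movie_is_identically_zero(self):
        movie = movie_with_baseline(np.full((300, 4, 4), 500.0))
        dff = compute_dff(movie)
        assert np.all(dff.values == 0.0)

    def test_dimming_becomes_positive_when_inverted(self):
        frames = np.full((300, 2, 2), 100.0)
        frames[150:] = 90.0  # 10 % dimming after stimulus
        dff = compute_dff(movie_with_baseline(frames), invert=True)
        assert np.allclose(dff.values[150:], 10.0)
        assert np.allclose(dff.values[:100], 0.0)

    def test_high_potassium_calibration_scenario(self):
        # a 6.3 % fluorescence decrease reads out as a +6.3 % plateau,
        # which the 0.9 %-per-10 mV calibration maps to a 70 mV depolarization
        frames = np.full((300, 2, 2), 1000.0)
        frames[150:] = 1000.0 * (1 - 0.063)
        dff = compute_dff(movie_with_baseline(frames), invert=True)
        plateau = dff.values[200:, 0, 0].mean()
        assert plateau == pytest.approx(6.3, abs=1e-9)
        cal = calibrate(6.3, 70.0)
        trace = Trace(
            time_s=dff.times_s(), values=dff.values[:, 0, 0], units="percent_dff"
        )
        assert dff_to_mV(trace, cal).values[-1] == pytest.approx(70.0, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        frames = rng.uniform(100, 200, size=(120, 3, 3))
        base = compute_dff(movie_with_baseline(frames))
        scaled = compute_dff(movie_with_baseline(frames * scale))
        assert np.allclose(base.values, scaled.values, rtol=1e-9, atol=1e-9)

    def test_baseline_overlapping_stimulus_rejected(self):
        movie = movie_with_baseline(np.full((300, 2, 2), 100.0))
        with pytest.raises(ValidationError, match="overlap"):
            compute_dff(movie, baseline_window=(0.0, 1.5))

    def test_zero_baseline_pixels_flagged_not_divided(self):
        frames = np.full((300, 4, 4), 100.0)
        frames[:, 0, 0] = 0.0
        dff = compute_dff(movie_with_baseline(frames), max_invalid_fraction=0.1)
        assert np.isnan(dff.values[:, 0, 0]).all()
        assert dff.invalid[0, 0]
        assert np.isfinite(dff.values[:, 1:, :]).all()

    def test_too_many_dead_pixels_rejected(self):
        frames = np.zeros((300, 4, 4))
        frames[:, 2:, :] = 100.0
        with pytest.raises(DataQualityError):
            compute_dff(movie_with_baseline(frames), max_invalid_fraction=0.05)


class TestBleachCorrect:
    def test_common_mode_decay_removed_exactly(self, simple_regions):
        t = np.arange(300) * 0.01
        decay = 100.0 * np.exp(-t / 50.0)
        frames = np.tile(decay[:, None, None], (1, 12, 12))
        dff = compute_dff(movie_with_baseline(frames))
        corrected = bleach_correct(dff, simple_regions)
        assert np.nanmax(np.abs(corrected.values)) < 1e-6

    def test_reference_trace_mean_zero_after_correction(self, simple_regions, rng):
        frames = rng.uniform(100, 200, size=(300, 12, 12))
        dff = compute_dff(movie_with_baseline(frames))
        corrected = bleach_correct(dff, simple_regions)
        ref = corrected.values[:, simple_regions.mask("reference")].mean(axis=1)
        assert np.abs(ref).max() < 1e-9

    def test_double_correction_refused(self, simple_regions, rng):
        frames = rng.uniform(100, 200, size=(300, 12, 12))
        corrected = bleach_correct(
            compute_dff(movie_with_baseline(frames)), simple_regions
        )
        with pytest.raises(StateError):
            bleach_correct(corrected, simple_regions)

    def test_missing_reference_region_rejected(self, rng):
        from vsdikit.data_model import RegionSet

        labels = np.ones((12, 12), dtype=np.int32)
        regions = RegionSet(labels=labels, names={"layerII": 1})
        frames = rng.uniform(100, 200, size=(300, 12, 12))
        with pytest.raises(ValidationError, match="reference"):
            bleach_correct(compute_dff(movie_with_baseline(frames)), regions)


class TestBinPixels:
    def test_uniform_frame_unchanged(self):
        movie = movie_with_baseline(np.full((120, 9, 9), 100.0))
        dff = bin_pixels(compute_dff(movie), factor=3)
        assert dff.values.shape == (120, 3, 3)
        assert np.all(dff.values == 0.0)
        assert dff.meta.pixel_size_um == 75.0
        assert dff.meta.bin_factor == 3

    def test_factor_one_is_identity(self):
        dff = compute_dff(movie_with_baseline(np.full((120, 5, 5), 10.0)))
        assert bin_pixels(dff, factor=1) is dff

    def test_matches_block_mean_oracle(self, rng):
        frames = rng.uniform(50, 150, size=(120, 9, 9))
        dff = compute_dff(movie_with_baseline(frames))
        binned = bin_pixels(dff, factor=3)
        for t in (0, 60, 119):
            for i in range(3):
                for j in range(3):
                    block = dff.values[t, 3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
                    assert binned.values[t, i, j] == pytest.approx(
                        block.mean(), abs=1e-12
                    )

    def test_partial_blocks_dropped(self, rng):
        frames = rng.uniform(50, 150, size=(120, 10, 11))
        binned = bin_pixels(compute_dff(movie_with_baseline(frames)), factor=3)
        assert binned.values.shape == (120, 3, 3)

    def test_frame_mean_preserved_when_divisible(self, rng):
        frames = rng.uniform(50, 150, size=(120, 9, 9))
        dff = compute_dff(movie_with_baseline(frames))
        binned = bin_pixels(dff, factor=3)
        assert binned.values[50].mean() == pytest.approx(
            dff.values[50].mean(), rel=1e-12
        )

    def test_oversized_factor_rejected(self):
        dff = compute_dff(movie_with_baseline(np.full((120, 4, 4), 10.0)))
        with pytest.raises(ValidationError):
            bin_pixels(dff, factor=5)


class TestCalibration:
    @pytest.mark.parametrize(
        "total,span,expected", [(6.3, 70.0, 0.9), (0.0, 70.0, 0.0), (9.0, 90.0, 1.0)]
    )
    def test_percent_per_10mV(self, total, span, expected):
        assert calibrate(total, span).percent_per_10mV == pytest.approx(
            expected, abs=1e-12
        )

    def test_nonpositive_span_rejected(self):
        with pytest.raises(ValidationError):
            calibrate(6.3, 0.0)

    def test_mV_round_trip(self):
        cal = calibrate(6.3, 70.0)
        trace = Trace(
            time_s=np.arange(5) * 0.01,
            values=np.array([0.0, 0.9, 1.8, 4.5, 6.3]),
            units="percent_dff",
        )
        back = mV_to_dff(dff_to_mV(trace, cal), cal)
        assert np.allclose(back.values, trace.values, atol=1e-9)
        assert dff_to_mV(trace, cal).values[1] == pytest.approx(10.0, abs=1e-9)

    def test_zero_slope_rejected(self):
        cal = calibrate(0.0, 70.0)
        trace = Trace(time_s=[0.0, 0.1], values=[0.0, 1.0], units="percent_dff")
        with pytest.raises(ValidationError):
            dff_to_mV(trace, cal)


class TestFullChain:
    def test_recovers_generator_plateaus_at_zero_noise(self):
        from dataclasses import replace as dc_replace

        from vsdikit.quantify import measure_movie
        from vsdikit.synthetic import default_params, default_regions, generate_movie

        params = dc_replace(default_params("control"), noise_sd_percent=0.0)
        regions = default_regions(params.frame_shape)
        movie, truth = generate_movie(params, seed=3)
        dff = preprocess_movie(movie, regions)
        measures, _ = measure_movie(dff, regions)
        for m in measures:
            expected = truth.peak_percent[m.region]
            assert abs(m.magnitude) == pytest.approx(expected, rel=0.02)
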