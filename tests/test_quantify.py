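"""Trace extraction and per-response measurements against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsdikit.data_model import RegionSet, Stripe, Trace
from vsdikit.errors import NormalizationError, ValidationError
from vsdikit.preprocess import compute_dff
from vsdikit.quantify import (
    ResponseMeasure,
    estimate_onset,
    extract_region_trace,
    extract_stripe_profile,
    lags,
    normalize_to_reference,
    rate_of_rise,
    response_magnitude,
)

from conftest import make_movie, make_protocol, make_trace


def random_dff(rng, shape=(120, 12, 12)):
    frames = rng.uniform(50, 150, size=shape)
    movie = make_movie(
        frames, protocol=make_protocol(baseline_duration_s=0.5),
        frame_interval_ms=10.0,
    )
    return compute_dff(movie)


class TestRegionTrace:
    def test_single_pixel_region_equals_pixel_series(self, rng):
        dff = random_dff(rng)
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[4, 7] = 1
        regions = RegionSet(labels=labels, names={"layerII": 1})
        trace = extract_region_trace(dff, regions, "layerII")
        assert np.array_equal(trace.values, dff.values[:, 4, 7])

    def test_uniform_movie_gives_uniform_series(self, simple_regions):
        t = np.linspace(100, 120, 120)
        frames = np.tile(t[:, None, None], (1, 12, 12))
        dff = compute_dff(
            make_movie(frames, protocol=make_protocol(baseline_duration_s=0.5))
        )
        trace = extract_region_trace(dff, simple_regions, "DEn")
        assert np.allclose(trace.values, dff.values[:, 0, 0], atol=1e-12)

    def test_matches_loop_oracle_on_random_masks(self, rng):
        for _ in range(5):
            dff = random_dff(rng)
            labels = (rng.uniform(size=(12, 12)) < 0.3).astype(np.int32)
            if not labels.any():
                continue
            regions = RegionSet(labels=labels, names={"layerIII": 1})
            trace = extract_region_trace(dff, regions, "layerIII")
            oracle = [
                np.mean([dff.values[t, r, c]
                         for r in range(12) for c in range(12) if labels[r, c]])
                for t in range(dff.values.shape[0])
            ]
            assert np.allclose(trace.values, oracle, rtol=0, atol=1e-12)

    def test_empty_region_after_binning_rejected(self, rng):
        from vsdikit.preprocess import bin_pixels

        dff = random_dff(rng)
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[0, 0] = 1  # a single pixel never survives 3x3 binning
        regions = RegionSet(labels=labels, names={"layerII": 1})
        binned = bin_pixels(dff, factor=3)
        with pytest.raises(ValidationError):
            extract_region_trace(binned, regions, "layerII")


class TestStripeProfile:
    def test_uniform_region_equals_pixel_series(self, rng):
        t = np.linspace(100, 130, 120)
        frames = np.tile(t[:, None, None], (1, 12, 12))
        dff = compute_dff(
            make_movie(frames, protocol=make_protocol(baseline_duration_s=0.5))
        )
        stripe = Stripe(tuple((5, c) for c in range(10)))
        profile = extract_stripe_profile(dff, stripe)
        assert np.allclose(profile.values, dff.values[:, 0, 0], atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        dff = random_dff(rng)
        stripe = Stripe(tuple((3 + i % 2, 1 + i) for i in range(10)))
        profile = extract_stripe_profile(dff, stripe)
        oracle = [
            np.mean([dff.values[t, r, c] for r, c in stripe.coords])
            for t in range(dff.values.shape[0])
        ]
        assert np.allclose(profile.values, oracle, rtol=0, atol=1e-12)

    def test_out_of_frame_stripe_rejected(self, rng):
        dff = random_dff(rng)
        stripe = Stripe(tuple((11, 3 + c) for c in range(10)))
        with pytest.raises(ValidationError):
            extract_stripe_profile(dff, stripe)


class TestResponseMagnitude:
    def test_flat_trace_has_no_polarity(self):
        trace = make_trace(np.zeros(200))
        magnitude, polarity = response_magnitude(trace, window=(1.0, 1.9))
        assert magnitude == 0.0
        assert polarity == "none"

    def test_largest_absolute_deviation_wins(self):
        values = np.zeros(200)
        values[120] = 2.0
        values[140] = -0.5
        magnitude, polarity = response_magnitude(
            make_trace(values), window=(1.0, 1.9)
        )
        assert magnitude == 2.0
        assert polarity == "excitatory"

    def test_hyperpolarizing_deviation_is_inhibitory(self):
        values = np.zeros(200)
        values[120] = -2.0
        magnitude, polarity = response_magnitude(
            make_trace(values), window=(1.0, 1.9)
        )
        assert magnitude == -2.0
        assert polarity == "inhibitory"

    def test_window_outside_recording_rejected(self):
        with pytest.raises(ValidationError):
            response_magnitude(make_trace(np.zeros(100)), window=(1.0, 5.0))


def ramp_trace(onset_delay_s=0.1, rise_s=0.5, peak=1.0, stim_onset_s=1.0, dt=0.005):
    """Baseline, then a linear ramp to ``peak`` that holds to the end."""
    t = np.arange(0, 3.0, dt)
    values = np.zeros_like(t)
    start = stim_onset_s + onset_delay_s
    ramp = (t - start) / rise_s * peak
    values = np.clip(np.where(t >= start, ramp, 0.0), None, peak) if peak > 0 else \
        np.clip(np.where(t >= start, ramp, 0.0), peak, None)
    return Trace(time_s=t, values=values, units="percent_dff")


class TestEstimateOnset:
    def test_linear_ramp_crosses_20_percent_at_200_ms(self):
        # ramp starts 100 ms after the stimulus and rises over 500 ms, so 20 %
        # of the peak is reached 100 ms into the ramp
        trace = ramp_trace()
        onset = estimate_onset(trace, stim_onset_s=1.0)
        assert onset == pytest.approx(200.0, abs=5.01)  # within one 5 ms frame

    def test_hyperpolarizing_mirror_has_same_onset(self):
        up = ramp_trace(peak=1.0)
        down = ramp_trace(peak=-1.0)
        assert estimate_onset(up, 1.0) == estimate_onset(down, 1.0)

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(10):
            values = np.concatenate(
                [rng.normal(0, 0.05, 100), rng.normal(0, 0.05, 100) + rng.uniform(0, 2)]
            )
            trace = make_trace(values, dt_s=0.01)
            onset = estimate_onset(trace, stim_onset_s=1.0, persistence=2)
            # oracle: scan every frame for the first sustained crossing
            bl = values[:100].mean()
            dev = np.abs(values[100:] - bl)
            thr = 0.2 * dev.max()
            expected = None
            for i in range(len(dev) - 1):
                if dev[i] >= thr and dev[i + 1] >= thr:
                    expected = (trace.time_s[100 + i] - 1.0) * 1000.0
                    break
            assert (onset is None) == (expected is None)
            if onset is not None:
                assert onset == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        shift=st.floats(0.0, 1.0),
        scale=st.floats(0.01, 100.0),
    )
    def test_shift_equivariance_and_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(42)
        values = np.concatenate(
            [rng.normal(0, 0.05, 100), rng.normal(0, 0.05, 100) + 1.0]
        )
        base = estimate_onset(make_trace(values, dt_s=0.01), 1.0)
        shifted = Trace(
            time_s=np.arange(200) * 0.01 + shift, values=values * scale,
            units="percent_dff",
        )
        assert estimate_onset(shifted, 1.0 + shift) == pytest.approx(base, abs=1e-6)

    def test_criterion_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            estimate_onset(make_trace(np.zeros(100)), 0.5, criterion=1.5)


class TestLags:
    def test_subtraction(self):
        pair = lags(100.0, 150.0, 300.0)
        assert (pair.lag1_ms, pair.lag2_ms) == (50.0, 200.0)

    def test_identical_onsets_give_zero(self):
        pair = lags(80.0, 80.0, 80.0)
        assert (pair.lag1_ms, pair.lag2_ms) == (0.0, 0.0)

    def test_undefined_onset_propagates(self):
        assert not lags(None, 150.0, 300.0).defined
        pair = lags(100.0, None, 300.0)
        assert pair.lag1_ms is None and pair.lag2_ms == 200.0


class TestRateOfRise:
    def test_linear_ramp_slope(self):
        trace = ramp_trace(onset_delay_s=0.0, rise_s=1.0, peak=1.0)
        slope = rate_of_rise(trace, stim_onset_s=1.0)
        assert slope == pytest.approx(1.0, abs=1e-6)

    def test_step_response_undefined(self):
        values = np.zeros(400)
        values[250:] = 1.0
        assert rate_of_rise(make_trace(values, dt_s=0.005), 1.0) is None

    def test_hyperpolarizing_slope_is_negative(self):
        trace = ramp_trace(onset_delay_s=0.0, rise_s=1.0, peak=-1.0)
        assert rate_of_rise(trace, 1.0) == pytest.approx(-1.0, abs=1e-6)

    def test_monotone_in_drive_amplitude(self):
        slopes = []
        for peak in (0.5, 1.0, 2.0, 4.0):
            slopes.append(rate_of_rise(ramp_trace(peak=peak), 1.0))
        assert slopes == sorted(slopes)


class TestNormalization:
    @staticmethod
    def measure(freq, magnitude, slice_id="s1", region="layerII"):
        return ResponseMeasure(
            slice_id=slice_id, region=region, frequency_hz=freq,
            magnitude=magnitude, polarity="excitatory" if magnitude > 0 else "inhibitory",
        )

    def test_divides_by_reference_magnitude(self):
        out = normalize_to_reference(
            [self.measure(20, 0.5), self.measure(40, 1.5)]
        )
        assert [m.normalized_magnitude for m in out] == [1.0, 3.0]

    def test_reference_maps_to_signed_unity(self):
        out = normalize_to_reference(
            [self.measure(20, -0.4), self.measure(80, -0.8)]
        )
        assert out[0].normalized_magnitude == -1.0
        assert out[1].normalized_magnitude == pytest.approx(-2.0)

    def test_zero_reference_rejected_with_group_named(self):
        with pytest.raises(NormalizationError, match="s1.*layerII|layerII.*s1"):
            normalize_to_reference([self.measure(20, 0.0), self.measure(40, 1.0)])

    def test_missing_reference_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_to_reference([self.measure(40, 1.0)])
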