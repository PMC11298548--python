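"""Unit and property tests for the calcium-trace analytics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliasync import calcium
from gliasync.errors import DataError, ParameterError, UndefinedCorrelationError


def make_trace(values, dt=0.25, roi="roi_0"):
    return calcium.FluorescenceTrace(np.asarray(values, float), dt, roi)


def make_dff(values, noise_sd=1.0, dt=0.25, roi="roi_0"):
    return calcium.DffTrace(np.asarray(values, float), baseline=1.0, noise_sd=noise_sd,
                            frame_interval=dt, roi_id=roi)


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def interpolated_percentile(values, q):
    """Independent linear-interpolation percentile oracle."""
    xs = sorted(values)
    pos = q / 100 * (len(xs) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


class TestBaseline:
    def test_constant_trace(self):
        assert calcium.compute_baseline(make_trace([7.5] * 10)) == 7.5

    def test_arithmetic_ramp(self):
        trace = make_trace(np.arange(101.0))
        assert calcium.compute_baseline(trace, 35) == pytest.approx(35.0)

    @pytest.mark.parametrize("q", [10, 35, 50, 77.7])
    def test_matches_interpolation_oracle(self, q):
        values = [1.0, 2.0, 3.0, 4.0]
        got = calcium.compute_baseline(make_trace(values), q)
        assert 1.0 <= got <= 4.0
        assert got == pytest.approx(interpolated_percentile(values, q), abs=1e-12)

    def test_nonfinite_frame_named(self):
        with pytest.raises(DataError, match="frame 2"):
            calcium.compute_baseline(np.array([1.0, 2.0, np.nan, 3.0]))

    @pytest.mark.parametrize("q", [0, 100, -5])
    def test_percentile_bounds(self, q):
        with pytest.raises(ParameterError):
            calcium.compute_baseline(make_trace([1, 2, 3]), q)


# ---------------------------------------------------------------------------
# dF/F and noise SD
# ---------------------------------------------------------------------------

class TestDff:
    def test_flat_at_baseline_is_zero(self):
        trace = make_trace([5.0] * 20)
        dff = calcium.compute_dff(trace, f0=5.0)
        assert np.allclose(dff.values, 0.0)

    def test_double_baseline_frame_is_one(self):
        values = np.full(20, 5.0)
        values[7] = 10.0
        dff = calcium.compute_dff(make_trace(values), f0=5.0)
        assert dff.values[7] == pytest.approx(1.0)

    def test_ramp_matches_direct_formula(self):
        values = np.linspace(2.0, 6.0, 50)
        f0 = 3.0
        dff = calcium.compute_dff(make_trace(values), f0=f0)
        assert np.allclose(dff.values, (values - f0) / f0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ParameterError):
            calcium.compute_dff(make_trace([1.0, 2.0]), f0=0.0)

    def test_half_sample_noise_sd_unbiased_on_gaussian(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 0.4, size=200_000)
        est = calcium.estimate_noise_sd(x, "half_sample")
        assert est == pytest.approx(0.4, rel=0.02)

    def test_full_noise_sd_is_plain_std(self):
        x = np.arange(10.0)
        assert calcium.estimate_noise_sd(x, "full") == pytest.approx(np.std(x))

    def test_half_sample_ignores_transient_frames(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 0.1, size=5000)
        x[:200] += 3.0  # large transients inflate the full-trace SD only
        assert calcium.estimate_noise_sd(x, "half_sample") == pytest.approx(0.1, rel=0.05)
        assert calcium.estimate_noise_sd(x, "full") > 0.3


# ---------------------------------------------------------------------------
# transient detection
# ---------------------------------------------------------------------------

class TestDetectTransients:
    def test_all_zero_is_empty(self):
        assert calcium.detect_transients(make_dff(np.zeros(100), noise_sd=0.1)) == []

    def test_rectangular_pulse(self):
        values = np.zeros(50)
        values[10:15] = 1.0  # height 10 x noise_sd
        events = calcium.detect_transients(make_dff(values, noise_sd=0.1))
        assert len(events) == 1
        ev = events[0]
        assert (ev.onset_frame, ev.offset_frame) == (10, 15)
        assert ev.peak == pytest.approx(1.0)
        assert ev.power == pytest.approx(1.0)

    def test_min_duration_rejects_single_frame_spike(self):
        values = np.zeros(50)
        values[20] = 5.0
        assert calcium.detect_transients(make_dff(values, noise_sd=0.1)) == []
        got = calcium.detect_transients(make_dff(values, noise_sd=0.1), min_duration_frames=1)
        assert len(got) == 1

    def test_translation_covariance(self):
        rng = np.random.default_rng(2)
        base = np.zeros(200)
        for onset in (20, 90, 150):
            base[onset:onset + 6] = 1.0 + 0.05 * rng.standard_normal(6)
        shifted = np.roll(base, 13)
        ev0 = calcium.detect_transients(make_dff(base, noise_sd=0.05))
        ev1 = calcium.detect_transients(make_dff(shifted, noise_sd=0.05))
        assert [e.onset_frame + 13 for e in ev0] == [e.onset_frame for e in ev1]

    def test_events_disjoint_and_ordered(self):
        values = np.zeros(100)
        for onset in (5, 30, 70):
            values[onset:onset + 4] = 2.0
        events = calcium.detect_transients(make_dff(values, noise_sd=0.1))
        assert len(events) == 3
        for a, b in zip(events, events[1:]):
            assert a.offset_frame <= b.onset_frame

    def test_requires_positive_noise_sd(self):
        with pytest.raises(ParameterError):
            calcium.detect_transients(make_dff(np.zeros(10), noise_sd=0.0))


class TestFrequencyAndPower:
    def test_zero_events(self):
        assert calcium.transient_frequency([], 300.0) == 0.0

    def test_direct_division(self):
        events = [calcium.TransientEvent(i, i + 2, 1.0, 1.0) for i in range(0, 60, 10)]
        assert calcium.transient_frequency(events, 300.0) == pytest.approx(0.02)

    def test_nonpositive_duration(self):
        with pytest.raises(ParameterError):
            calcium.transient_frequency([], 0.0)

    @pytest.mark.parametrize(
        "segment,expected",
        [([1.0, 2.0, 3.0], 14.0 / 3.0), ([0.0, 0.0], 0.0), ([2.5] * 7, 6.25)],
    )
    def test_power_examples(self, segment, expected):
        assert calcium.transient_power(np.array(segment)) == pytest.approx(expected)

    def test_power_empty_segment(self):
        with pytest.raises(DataError):
            calcium.transient_power(np.array([]))

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=30),
        st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_power_scale_law(self, segment, c):
        x = np.array(segment)
        assert calcium.transient_power(c * x) == pytest.approx(
            c**2 * calcium.transient_power(x), rel=1e-9, abs=1e-12
        )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

finite_vectors = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=2, max_size=40
).map(lambda xs: np.array(xs))


class TestCorrelations:
    def test_pearson_examples(self):
        x = np.array([1.0, 2.0, 3.0])
        assert calcium.pearson_correlation(x, x) == pytest.approx(1.0)
        assert calcium.pearson_correlation(x, -x) == pytest.approx(-1.0)
        assert calcium.pearson_correlation(x, np.array([3.0, 2.0, 1.0])) == pytest.approx(-1.0)

    def test_pearson_constant_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            calcium.pearson_correlation(np.array([1.0, 1.0]), np.array([1.0, 2.0]))

    def test_cosine_examples(self):
        assert calcium.cosine_correlation(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        got = calcium.cosine_correlation(np.array([1.0, 2.0]), np.array([2.0, 1.0]))
        assert got == pytest.approx(0.8)

    def test_cosine_zero_norm_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            calcium.cosine_correlation(np.zeros(3), np.ones(3))

    @given(finite_vectors)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_cosine_self_and_scaling(self, x):
        if np.linalg.norm(x) == 0:
            return
        assert calcium.cosine_correlation(x, x) == pytest.approx(1.0)
        assert calcium.cosine_correlation(x, 3.7 * x) == pytest.approx(1.0)
        assert calcium.cosine_correlation(x, -x) == pytest.approx(-1.0)

    @given(finite_vectors, finite_vectors)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_cosine_bounded(self, x, y):
        n = min(x.size, y.size)
        x, y = x[:n], y[:n]
        if np.linalg.norm(x) == 0 or np.linalg.norm(y) == 0:
            return
        assert -1.0 <= calcium.cosine_correlation(x, y) <= 1.0

    @given(finite_vectors, finite_vectors)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mean_zero_cosine_equals_pearson(self, x, y):
        n = min(x.size, y.size)
        x = x[:n] - x[:n].mean()
        y = y[:n] - y[:n].mean()
        if np.linalg.norm(x) < 1e-9 or np.linalg.norm(y) < 1e-9:
            return
        rc = calcium.cosine_correlation(x, y)
        rp = calcium.pearson_correlation(x, y)
        assert rc == pytest.approx(rp, abs=1e-12)


class TestPairwiseSynchrony:
    def test_identical_traces(self):
        data = np.tile(np.array([0.0, 1.0, 0.5, 0.2]), (4, 1))
        sync = calcium.pairwise_synchrony(data)
        iu = np.triu_indices(4, 1)
        assert np.allclose(sync.values[iu], 1.0)
        assert sync.mean_offdiagonal() == pytest.approx(1.0)

    def test_three_rois_three_pairs(self):
        rng = np.random.default_rng(0)
        sync = calcium.pairwise_synchrony(rng.normal(size=(3, 50)))
        iu = np.triu_indices(3, 1)
        assert np.isfinite(sync.values[iu]).sum() == 3

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        sync = calcium.pairwise_synchrony(rng.normal(size=(10, 558)))
        assert abs(sync.mean_offdiagonal()) < 0.1

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(4)
        sync = calcium.pairwise_synchrony(rng.normal(size=(5, 100)))
        assert np.allclose(sync.values, sync.values.T)
        assert np.allclose(np.diag(sync.values), 1.0)

    def test_undefined_pair_excluded_and_counted(self):
        data = np.vstack([np.zeros(20), np.ones(20), np.full(20, 0.5)])
        sync = calcium.pairwise_synchrony(data)
        assert sync.n_undefined_pairs == 2  # both pairs involving the zero trace
        assert sync.mean_offdiagonal() == pytest.approx(1.0)  # the remaining pair


class TestStandardize:
    def test_direct_division(self):
        out = calcium.standardize_to_pre({"Pre": 0.4, "POD2": 0.2})
        values = {o.session: o.standardized for o in out}
        assert values == {"Pre": pytest.approx(1.0), "POD2": pytest.approx(0.5)}

    def test_all_equal_sessions(self):
        out = calcium.standardize_to_pre({"Pre": 0.3, "POD4": 0.3, "POD7": 0.3})
        assert all(o.standardized == pytest.approx(1.0) for o in out)

    def test_single_session(self):
        out = calcium.standardize_to_pre({"Pre": 0.42})
        assert out[0].standardized == pytest.approx(1.0)

    def test_difference_mode(self):
        out = calcium.standardize_to_pre({"Pre": 0.4, "POD2": 0.1}, mode="difference")
        assert {o.session: o.standardized for o in out}["POD2"] == pytest.approx(-0.3)

    def test_zero_pre_rejected(self):
        with pytest.raises(ParameterError):
            calcium.standardize_to_pre({"Pre": 0.0, "POD2": 0.2})

    def test_missing_pre_rejected(self):
        with pytest.raises(ParameterError):
            calcium.standardize_to_pre({"POD2": 0.2}, pre_label="Pre")
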