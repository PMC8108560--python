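import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sig

from sleeptes import (
    CleanSegmentSet,
    PSGRecord,
    WelchSpec,
    mark_clean_segments,
    relative_band_power,
    region_band_power,
    taper_concatenate,
    welch_band_power,
)
from sleeptes.psg_io import RegionMap, default_region_map

RATE = 64.0


def _record(data, names=None):
    data = np.atleast_2d(data)
    names = names or [f"CH{i}" for i in range(data.shape[0])]
    return PSGRecord(data, RATE, names)


class TestCleanSegments:
    def test_clean_record_returns_full_intervals(self):
        rec = _record(np.zeros((2, int(600 * RATE))))
        segs = mark_clean_segments(rec, [(0.0, 60.0), (120.0, 180.0)])
        assert segs.intervals == [(0.0, 60.0), (120.0, 180.0)]
        assert segs.total_s == 120.0

    def test_burst_splits_interval_complement_oracle(self):
        n = int(120 * RATE)
        data = np.zeros((1, n))
        # 2-s artifact burst at [40, 42) s
        data[0, int(40 * RATE):int(42 * RATE)] = 500.0
        segs = mark_clean_segments(_record(data), [(0.0, 120.0)], threshold_uv=300.0)
        assert segs.intervals == [(0.0, 40.0), (42.0, 120.0)]
        assert segs.total_s == 118.0

    def test_sub_5s_fragments_dropped(self):
        n = int(60 * RATE)
        data = np.zeros((1, n))
        data[0, int(3 * RATE):int(4 * RATE)] = 500.0  # leaves a 3-s head fragment
        segs = mark_clean_segments(_record(data), [(0.0, 60.0)])
        assert segs.intervals == [(4.0, 60.0)]

    def test_any_channel_over_threshold_contaminates(self):
        n = int(60 * RATE)
        data = np.zeros((2, n))
        data[1, int(20 * RATE):int(25 * RATE)] = 500.0
        segs = mark_clean_segments(_record(data), [(0.0, 60.0)])
        assert segs.intervals == [(0.0, 20.0), (25.0, 60.0)]

    def test_threshold_is_inclusive(self):
        data = np.full((1, int(30 * RATE)), 300.0)
        segs = mark_clean_segments(_record(data), [(0.0, 30.0)], threshold_uv=300.0)
        assert segs.total_s == 30.0

    def test_segment_set_validation(self):
        with pytest.raises(ValueError, match="shorter"):
            CleanSegmentSet([(0.0, 3.0)])
        with pytest.raises(ValueError, match="disjoint"):
            CleanSegmentSet([(0.0, 10.0), (5.0, 15.0)])

    @given(st.lists(st.integers(min_value=5, max_value=110), min_size=0,
                    max_size=4, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_total_time_oracle_with_random_bursts(self, burst_starts):
        """Accounting oracle: a sample-resolution boolean mask gives the
        same kept-time total as the interval scan."""
        n = int(120 * RATE)
        data = np.zeros((1, n))
        clean = np.ones(n, bool)
        for s in burst_starts:
            i0, i1 = int(s * RATE), int((s + 1) * RATE)
            data[0, i0:i1] = 400.0
            clean[i0:i1] = False
        segs = mark_clean_segments(_record(data), [(0.0, 120.0)])
        # oracle: run lengths of the clean mask, keeping runs >= 5 s
        edges = np.flatnonzero(np.diff(np.r_[0, clean.view(np.int8), 0]))
        kept = sum(b - a for a, b in zip(edges[::2], edges[1::2])
                   if b - a >= 5 * RATE)
        assert segs.total_s * RATE == kept


class TestTaperConcatenate:
    def test_interior_unchanged_edges_attenuated(self):
        rec = _record(np.ones((1, int(40 * RATE))))
        segs = CleanSegmentSet([(0.0, 20.0), (20.0, 40.0)])
        out = taper_concatenate(rec, segs)
        n = int(20 * RATE)
        assert out.shape == (1, 2 * n)
        # Tukey alpha=0.2: the central 80% of each segment is exactly 1
        core = out[0, int(0.15 * n):int(0.85 * n)]
        assert np.all(core == 1.0)
        assert out[0, 0] == 0.0 and out[0, n] == 0.0  # both segment heads

    def test_constant_signal_window_sum_closed_form(self):
        """sum of a Tukey(alpha) window approaches N(1 - alpha/2)."""
        n_s = 50
        rec = _record(np.ones((1, int(n_s * RATE))))
        segs = CleanSegmentSet([(0.0, float(n_s))])
        out = taper_concatenate(rec, segs)
        n = out.shape[1]
        alpha = WelchSpec().tukey_alpha
        assert out.sum() == pytest.approx(n * (1 - alpha / 2), rel=1e-3)

    def test_empty_segment_set(self):
        rec = _record(np.ones((3, int(10 * RATE))))
        out = taper_concatenate(rec, CleanSegmentSet([]))
        assert out.shape == (3, 0)


class TestWelchBandPower:
    def test_zero_signal_zero_power(self):
        assert welch_band_power(np.zeros(int(60 * RATE)), RATE) == 0.0

    def test_on_bin_sinusoid_parseval(self):
        """A sinusoid on an exact Welch bin: integrating the one-sided PSD
        over frequency recovers the mean-square power A²/2."""
        spec = WelchSpec()
        nperseg = spec.nperseg(RATE)
        f_bin = 2 * RATE / nperseg  # the in-band bin
        assert 0.5 <= f_bin <= 1.0
        t = np.arange(int(300 * RATE)) / RATE
        a = 40.0
        x = a * np.sin(2 * np.pi * f_bin * t)
        from sleeptes.spectral import band_power_spectrum

        f, pxx = band_power_spectrum(x, RATE, spec)
        df = f[1] - f[0]
        assert pxx.sum() * df == pytest.approx(a**2 / 2, rel=0.02)
        # and the power is concentrated at that bin
        assert f[np.argmax(pxx)] == pytest.approx(f_bin)

    def test_white_noise_density_level(self):
        """One-sided PSD of white noise is flat at sigma^2 / (rate/2)."""
        rng = np.random.default_rng(0)
        sigma = 25.0
        x = rng.normal(0, sigma, int(3600 * RATE))
        p = welch_band_power(x, RATE)
        assert p == pytest.approx(sigma**2 / (RATE / 2), rel=0.1)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 20, int(60 * RATE))
        base = welch_band_power(x, RATE)
        assert welch_band_power(c * x, RATE) == pytest.approx(c * c * base, rel=1e-9)

    def test_signal_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_band_power(np.zeros(100), RATE)

    def test_band_without_bins_rejected(self):
        x = np.zeros(int(30 * RATE))
        with pytest.raises(ValueError, match="band"):
            welch_band_power(x, RATE, WelchSpec(band=(0.41, 0.6)))


class TestRegionPower:
    def _region_record(self, scales=None):
        rm = default_region_map()
        chans = [c for cs in rm.regions.values() for c in cs]
        rng = np.random.default_rng(3)
        base = rng.normal(0, 20, int(120 * RATE))
        scales = scales or {}
        data = np.stack([scales.get(c, 1.0) * base for c in chans])
        return _record(data, chans), rm

    def test_identical_channels_give_identical_regions(self):
        rec, rm = self._region_record()
        segs = CleanSegmentSet([(0.0, 120.0)])
        powers = region_band_power(rec, rm, segs)
        vals = list(powers.values())
        assert len(powers) == 10
        assert np.allclose(vals, vals[0])

    def test_scaling_one_region_scales_only_it(self):
        rm = default_region_map()
        target = "Medial Frontal"
        scales = {c: 3.0 for c in rm.regions[target]}
        rec, rm = self._region_record(scales)
        segs = CleanSegmentSet([(0.0, 120.0)])
        powers = region_band_power(rec, rm, segs)
        others = [v for k, v in powers.items() if k != target]
        assert powers[target] == pytest.approx(9.0 * others[0], rel=1e-9)
        assert np.allclose(others, others[0])

    def test_missing_channel_named(self):
        rec, rm = self._region_record()
        rec.channel_names[0] = "BOGUS"
        with pytest.raises(KeyError):
            region_band_power(rec, rm, CleanSegmentSet([(0.0, 120.0)]))


class TestRelativePower:
    def test_identity_is_zero_doubling_is_100(self):
        pre = {"A": 2.0, "B": 5.0}
        assert relative_band_power(pre, pre) == {"A": 0.0, "B": 0.0}
        post = {"A": 4.0, "B": 10.0}
        assert relative_band_power(pre, post) == {"A": 100.0, "B": 100.0}

    def test_amplitude_scale_r_gives_r2_minus_1(self):
        """End-to-end sensitivity: scaling the post-window signal by r
        yields a relative band power of (r^2 - 1) x 100%."""
        rng = np.random.default_rng(11)
        x = rng.normal(0, 20, int(120 * RATE))
        r = 2.5043  # corresponds to +527.2%
        pre = {"X": welch_band_power(x, RATE)}
        post = {"X": welch_band_power(r * x, RATE)}
        rel = relative_band_power(pre, post)
        assert rel["X"] == pytest.approx((r**2 - 1) * 100.0, rel=1e-9)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            relative_band_power({"A": 0.0}, {"A": 1.0})

    def test_region_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            relative_band_power({"A": 1.0}, {"B": 1.0})
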