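"""Speckle statistics: histograms, JSD, TAI, speckle size, attenuation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage
from scipy.spatial.distance import jensenshannon
from scipy.stats import rayleigh

from histophantom.metrics import (
    ProbabilityHistogram,
    envelope_histogram,
    estimate_attenuation,
    fd_bin_width,
    jsd,
    jsd_map,
    speckle_size,
    tai,
)


class TestEnvelopeHistogram:
    def test_constant_roi_single_bin(self):
        h = envelope_histogram(np.full((10, 10), 2.5))
        assert np.count_nonzero(h.masses) == 1
        assert h.masses.max() == pytest.approx(1.0)

    def test_rayleigh_matches_closed_form(self):
        rng = np.random.default_rng(0)
        n = 100_000
        env = rng.rayleigh(1.0, n)
        ref = np.percentile(env, 99)
        h = envelope_histogram(env.reshape(200, 500), bin_width=0.05)
        cdf = rayleigh.cdf(h.bin_edges * ref)
        expected = np.diff(cdf)
        expected[-1] += 1.0 - cdf[-1]  # top bin absorbs the clipped tail
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(h.masses - expected) <= 3 * sigma + 1e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        env = rng.rayleigh(1.0, (64, 64))
        h1 = envelope_histogram(env)
        h2 = envelope_histogram(env * 37.2)
        assert np.allclose(h1.masses, h2.masses)
        assert np.allclose(h1.bin_edges, h2.bin_edges)


class TestFdBinWidth:
    def test_uniform_closed_form(self):
        # uniform(0,1): IQR/p99 of the normalized sample ~ 0.5/0.99
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 1000)
        w = fd_bin_width(x)
        assert w == pytest.approx(2 * 0.5 / 0.99 * 1000 ** (-1 / 3), rel=0.08)

    def test_monotone_in_n(self):
        rng = np.random.default_rng(1)
        widths = [
            fd_bin_width(rng.rayleigh(1.0, n)) for n in (500, 5_000, 50_000)
        ]
        assert widths[0] > widths[1] > widths[2]

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError):
            fd_bin_width(np.full(100, 1.0))


def _hist(masses):
    masses = np.asarray(masses, dtype=float)
    edges = np.arange(masses.size + 1) * 0.1
    return ProbabilityHistogram(edges, masses / masses.sum())


class TestJsd:
    def test_identity(self):
        p = _hist([0.2, 0.3, 0.5])
        assert jsd(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_one(self):
        assert jsd(_hist([1, 0]), _hist([0, 1])) == pytest.approx(1.0)

    def test_hand_value(self):
        assert jsd(_hist([1, 0]), _hist([1, 1])) == pytest.approx(0.3113,
                                                                  abs=5e-5)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=10, max_size=10),
        st.lists(st.floats(0.0, 1.0), min_size=10, max_size=10),
    )
    def test_axioms_against_library_oracle(self, a, b):
        a, b = np.asarray(a) + 1e-6, np.asarray(b) + 1e-6
        p, q = _hist(a), _hist(b)
        d_pq = jsd(p, q)
        d_qp = jsd(q, p)
        assert 0.0 <= d_pq <= 1.0 + 1e-12
        assert d_pq == pytest.approx(d_qp, abs=1e-12)
        oracle = jensenshannon(a / a.sum(), b / b.sum(), base=2) ** 2
        assert d_pq == pytest.approx(float(oracle), abs=1e-9)


class TestJsdMap:
    def test_identical_images_all_zero(self):
        rng = np.random.default_rng(0)
        img = rng.rayleigh(1.0, (100, 100))
        res = jsd_map(img[:50, :50], np.tile(img[:50, :50], (2, 2)), (50, 50))
        assert np.allclose(res["values"][0], 0.0, atol=1e-12)
        assert res["values"].min() == pytest.approx(0.0, abs=1e-12)

    def test_zero_overlap_tile_count(self):
        rng = np.random.default_rng(1)
        area = rng.rayleigh(1.0, (100, 130))
        res = jsd_map(area[:30, :30], area, (30, 30), overlap=0.0)
        assert len(res["values"]) == (100 // 30) * (130 // 30)

    def test_median_invariant_to_tile_order(self):
        rng = np.random.default_rng(2)
        area = rng.rayleigh(1.0, (90, 90))
        res = jsd_map(area[:30, :30], area, (30, 30))
        assert res["median"] == pytest.approx(
            float(np.median(res["values"][::-1]))
        )


class TestTai:
    def test_vertical_stripes_fully_anisotropic(self):
        img = np.tile(np.sin(np.arange(128) * 0.5)[None, :], (128, 1))
        res = tai(img, 197.4, 50.0, prefilter=False)
        assert res[0].tai == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_isotropic(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((256, 256))
        res = tai(img, 197.4, 50.0, prefilter=False)
        assert res[0].tai < 0.05

    def test_rotation_90_invariance(self):
        rng = np.random.default_rng(1)
        img = ndimage.gaussian_filter(rng.standard_normal((128, 128)), (1, 4))
        for a, b in zip(
            tai(img, 197.4, 50.0), tai(np.rot90(img), 197.4, 50.0)
        ):
            assert a.tai == pytest.approx(b.tai, abs=1e-6)

    def test_constant_roi_flagged_zero(self):
        res = tai(np.full((64, 64), 3.0), 197.4, 50.0, prefilter=False)
        assert res[0].tai == 0.0 and res[0].degenerate

    def test_offset_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        img = ndimage.gaussian_filter(rng.standard_normal((96, 96)), (1, 3))
        base = tai(img, 197.4, 50.0)
        shifted = tai(img + 17.0, 197.4, 50.0)
        scaled = tai(img * 4.0, 197.4, 50.0)
        for x, y, z in zip(base, shifted, scaled):
            assert x.tai == pytest.approx(y.tai, abs=1e-9)
            assert x.tai == pytest.approx(z.tai, abs=1e-9)

    def test_tai_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            img = rng.standard_normal((64, 64))
            for r in tai(img, 197.4, 50.0):
                assert 0.0 <= r.tai <= 1.0


class TestSpeckleSize:
    def test_white_noise_delta_correlated(self):
        rng = np.random.default_rng(0)
        env = rng.random((128, 128)) + 0.5
        ax_um, lat_um = speckle_size(env, 10.0)
        assert 5.0 <= ax_um <= 20.0  # ~1 pixel FWHM
        assert 5.0 <= lat_um <= 20.0

    @pytest.mark.parametrize("sig_ax,sig_lat", [(2.0, 5.0), (4.0, 4.0)])
    def test_gaussian_psf_closed_form(self, sig_ax, sig_lat):
        rng = np.random.default_rng(1)
        field = ndimage.gaussian_filter(
            rng.standard_normal((512, 512)), (sig_ax, sig_lat)
        )
        ax_um, lat_um = speckle_size(field, 10.0)
        # autocovariance of filtered noise is Gaussian with sigma*sqrt(2)
        exp_ax = 2.355 * sig_ax * np.sqrt(2) * 10.0
        exp_lat = 2.355 * sig_lat * np.sqrt(2) * 10.0
        assert ax_um == pytest.approx(exp_ax, rel=0.10)
        assert lat_um == pytest.approx(exp_lat, rel=0.10)
        if sig_ax == sig_lat:
            assert ax_um == pytest.approx(lat_um, rel=0.05)

    def test_variance_shrinks_with_roi_size(self):
        rng = np.random.default_rng(2)
        small, large = [], []
        for _ in range(6):
            field = ndimage.gaussian_filter(
                rng.standard_normal((256, 256)), 2.0
            )
            small.append(speckle_size(field[:64, :64], 10.0)[0])
            large.append(speckle_size(field, 10.0)[0])
        assert np.var(large) < np.var(small)


class TestAttenuation:
    def _rf(self, alpha_db_mhz_cm, f0_hz=7.6e6, c=1540.0, seed=0):
        rng = np.random.default_rng(seed)
        dt = 1 / 31.25e6
        n_t, n_el = 1600, 64
        t = np.arange(n_t) * dt
        z_cm = c * t / 2 * 100
        atten_db = 2.0 * alpha_db_mhz_cm * (f0_hz / 1e6) * z_cm  # round trip
        amp = 10 ** (-atten_db / 20)
        rf = rng.standard_normal((n_t, n_el)) * amp[:, None]
        return rf, dt

    def test_recovers_imposed_decay(self):
        rf, dt = self._rf(0.29)
        est = estimate_attenuation(rf, dt, 1540.0, 7.6e6)
        assert est == pytest.approx(0.29, rel=0.10)

    def test_lossless_near_zero(self):
        rf, dt = self._rf(0.0)
        est = estimate_attenuation(rf, dt, 1540.0, 7.6e6)
        assert abs(est) < 0.02

    def test_linearity_in_attenuation(self):
        rf1, dt = self._rf(0.2, seed=3)
        rf2, _ = self._rf(0.4, seed=3)
        e1 = estimate_attenuation(rf1, dt, 1540.0, 7.6e6)
        e2 = estimate_attenuation(rf2, dt, 1540.0, 7.6e6)
        assert e2 == pytest.approx(2 * e1, rel=0.05)
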