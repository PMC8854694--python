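"""Phasor-FLIM pipeline: binning, thresholding, transform, ROI statistics."""

import numpy as np
import pytest

from epiquant import flim as fl
from epiquant.synth import FlimSimConfig, generate_flim_stack, \
    monoexp_bin_probabilities
from conftest import rect

PERIOD_NS = 50.0  # 20 MHz


def monoexp_stack(tau_ns, shape=(4, 4), photons=1e6, n_bins=256):
    probs = monoexp_bin_probabilities(tau_ns, PERIOD_NS, n_bins)
    decay = photons * probs[:, None, None] * np.ones((1,) + shape)
    return fl.FlimStack(decay=decay)


class TestBinPixels:
    def test_factor_one_is_identity(self):
        st = monoexp_stack(4.0, shape=(6, 6))
        out = fl.bin_pixels(st, 1)
        assert np.array_equal(out.decay, st.decay)

    def test_pixel_size_scales(self):
        st = monoexp_stack(4.0, shape=(10, 10))
        st.pixel_size_nm = 135.0
        assert fl.bin_pixels(st, 5).pixel_size_nm == pytest.approx(675.0)

    def test_photon_conservation_and_partial_blocks(self):
        rng = np.random.default_rng(0)
        decay = rng.poisson(5.0, size=(16, 11, 7))
        st = fl.FlimStack(decay=decay)
        out = fl.bin_pixels(st, 3)
        assert out.decay.shape == (16, 3, 2)
        retained = decay[:, :9, :6]
        assert out.decay.sum() == retained.sum()

    def test_factor_exceeding_image_rejected(self):
        st = monoexp_stack(4.0, shape=(4, 4))
        with pytest.raises(ValueError, match="exceeds"):
            fl.bin_pixels(st, 5)


class TestThreshold:
    def test_zero_threshold_removes_nothing(self):
        st = monoexp_stack(4.0, photons=100)
        out = fl.threshold_background(st, 0)
        assert out.mask.all()

    def test_uniform_image_fully_removed(self):
        st = monoexp_stack(4.0, photons=30)
        out = fl.threshold_background(st, 50)
        assert not out.mask.any()

    def test_exactly_background_pixels_removed(self):
        cfg = FlimSimConfig(image_shape=(20, 20),
                            regions=[(rect(-0.5, -0.5, 19.4, 9.4), 4.0)],
                            photons_per_pixel_mean=5000,
                            background_count_level=20, seed=1)
        st, truth = generate_flim_stack(cfg)
        out = fl.threshold_background(st, 500)
        assert np.array_equal(~out.mask, truth["background_mask"])


class TestPhasorTransform:
    def test_delta_decay_at_origin_phase(self):
        decay = np.zeros((256, 1, 1))
        decay[0] = 1000.0
        ph = fl.phasor_transform(fl.FlimStack(decay=decay))
        # all photons in the first bin: phasor at the bin-centre phase,
        # modulation 1 (the tau = 0 limit)
        assert np.hypot(ph.G[0, 0], ph.S[0, 0]) == pytest.approx(1.0)
        assert fl.lifetime_map(ph).tau[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_long_lifetime_limit_near_origin(self):
        st = monoexp_stack(1e5)  # effectively uniform over the period
        with pytest.warns(UserWarning, match="aliasing"):
            generate_flim_stack(FlimSimConfig(
                image_shape=(2, 2),
                regions=[(rect(-0.5, -0.5, 1.4, 1.4), 1e5)],
                photons_per_pixel_mean=10))
        ph = fl.phasor_transform(st)
        assert abs(ph.G[0, 0]) < 1e-3 and abs(ph.S[0, 0]) < 1e-3

    def test_monoexp_matches_continuous_closed_form(self):
        # fine binning -> discrete transform converges to G = 1/(1+(wt)^2),
        # S = wt/(1+(wt)^2)
        tau = 4.0
        st = monoexp_stack(tau, shape=(1, 1), n_bins=8192)
        ph = fl.phasor_transform(st)
        wt = 2 * np.pi / PERIOD_NS * tau
        assert ph.G[0, 0] == pytest.approx(1 / (1 + wt**2), rel=1e-5)
        assert ph.S[0, 0] == pytest.approx(wt / (1 + wt**2), rel=1e-5)

    def test_mixture_lies_on_segment_at_intensity_fraction(self):
        """A two-component decay's phasor is the intensity-weighted convex
        combination of the component phasors (linearity of the transform)."""
        f = 0.3
        s1 = monoexp_stack(1.0, shape=(1, 1), photons=f * 1e6)
        s2 = monoexp_stack(5.0, shape=(1, 1), photons=(1 - f) * 1e6)
        mix = fl.FlimStack(decay=s1.decay + s2.decay)
        z = [fl.phasor_transform(s) for s in (s1, s2, mix)]
        g_expect = f * z[0].G + (1 - f) * z[1].G
        s_expect = f * z[0].S + (1 - f) * z[1].S
        assert z[2].G[0, 0] == pytest.approx(g_expect[0, 0], rel=1e-12)
        assert z[2].S[0, 0] == pytest.approx(s_expect[0, 0], rel=1e-12)

    def test_unmasked_zero_pixel_rejected(self):
        decay = np.zeros((256, 2, 2))
        decay[0, 0, 0] = 10.0
        with pytest.raises(ValueError, match="zero total counts"):
            fl.phasor_transform(fl.FlimStack(decay=decay))

    def test_simulated_phasors_inside_universal_semicircle(self):
        cfg = FlimSimConfig(image_shape=(12, 12),
                            regions=[(rect(-0.5, -0.5, 11.4, 11.4), 4.83)],
                            photons_per_pixel_mean=2e4, seed=5)
        st, _ = generate_flim_stack(cfg)
        ph = fl.phasor_transform(fl.threshold_background(st, 50))
        radius = np.hypot(ph.G - 0.5, ph.S)
        assert np.nanmax(radius) <= 0.5 + 0.02  # shot-noise tolerance
        assert np.nanmin(ph.S) >= -0.02

    def test_reference_calibration_round_trip(self):
        st = monoexp_stack(4.0, shape=(1, 1))
        measured = fl.phasor_transform(st)
        factor = fl.calibration_factor(
            complex(measured.G[0, 0], measured.S[0, 0]), 4.0,
            rep_rate=20e6)
        cal = fl.phasor_transform(st, calibration=factor)
        wt = 2 * np.pi / PERIOD_NS * 4.0
        assert cal.G[0, 0] == pytest.approx(1 / (1 + wt**2), rel=1e-12)


class TestMedianFilter:
    def test_window_one_is_identity(self):
        st = monoexp_stack(4.0, shape=(5, 5))
        ph = fl.phasor_transform(st)
        out = fl.median_filter_phasor(ph, 1)
        assert np.array_equal(out.G, ph.G)

    def test_constant_image_unchanged(self):
        st = monoexp_stack(4.0, shape=(7, 7))
        ph = fl.phasor_transform(st)
        out = fl.median_filter_phasor(ph, 5)
        assert np.allclose(out.G, ph.G) and np.allclose(out.S, ph.S)

    def test_single_outlier_replaced_by_constant(self):
        st = monoexp_stack(4.0, shape=(5, 5))
        ph = fl.phasor_transform(st)
        g0 = ph.G[0, 0]
        ph.G[2, 2] = 0.99
        out = fl.median_filter_phasor(ph, 5)
        assert out.G[2, 2] == pytest.approx(g0)

    def test_undefined_pixels_stay_undefined(self):
        st = monoexp_stack(4.0, shape=(5, 5))
        ph = fl.phasor_transform(st)
        ph.G[1, 1] = np.nan
        out = fl.median_filter_phasor(ph, 3)
        assert np.isnan(out.G[1, 1])
        assert np.isfinite(out.G[0, 0])

    def test_even_window_rejected(self):
        st = monoexp_stack(4.0, shape=(5, 5))
        with pytest.raises(ValueError, match="odd"):
            fl.median_filter_phasor(fl.phasor_transform(st), 4)


class TestLifetimeMap:
    @pytest.mark.parametrize("tau", [0.5, 2.8, 4.0, 4.83, 7.0])
    def test_noiseless_round_trip(self, tau):
        st = monoexp_stack(tau)
        lt = fl.lifetime_map(fl.phasor_transform(st))
        assert np.nanmean(lt.tau) == pytest.approx(tau, rel=0.005)

    def test_naive_phase_ratio_option(self):
        st = monoexp_stack(4.0)
        ph = fl.phasor_transform(st)
        lt = fl.lifetime_map(ph, method="phase_naive")
        # tau = S/(wG) carries a small discretization bias only
        assert np.nanmean(lt.tau) == pytest.approx(4.0, rel=2e-3)

    def test_modulation_method(self):
        st = monoexp_stack(4.0, n_bins=4096)
        lt = fl.lifetime_map(fl.phasor_transform(st), method="modulation")
        assert np.nanmean(lt.tau) == pytest.approx(4.0, rel=2e-3)

    def test_nonpositive_g_undefined(self):
        ph = fl.PhasorImage(G=np.array([[-0.1]]), S=np.array([[0.2]]),
                            intensity=np.array([[100.0]]), rep_rate=20e6,
                            n_bins=256)
        assert np.isnan(fl.lifetime_map(ph).tau[0, 0])

    def test_binning_then_transform_equals_blocksum_transform(self):
        rng = np.random.default_rng(2)
        decay = rng.poisson(10.0, size=(64, 6, 6)).astype(float)
        st = fl.FlimStack(decay=decay)
        a = fl.phasor_transform(fl.threshold_background(fl.bin_pixels(st, 3), 1))
        manual = decay.reshape(64, 2, 3, 2, 3).sum(axis=(2, 4))
        b = fl.phasor_transform(
            fl.threshold_background(fl.FlimStack(decay=manual), 1))
        assert np.allclose(a.G, b.G) and np.allclose(a.S, b.S)


class TestRoiMeanLifetime:
    def make_lifetime(self, values):
        tau = np.asarray(values, float)
        return fl.LifetimeImage(tau=tau, intensity=np.full(tau.shape, 100.0))

    def test_uniform_roi(self):
        lt = self.make_lifetime(np.full((10, 10), 4.83))
        rois = fl.RoiSet({"r": rect(1, 1, 8, 8)})
        res = fl.roi_mean_lifetime(lt, rois).iloc[0]
        assert res["mean_ns"] == pytest.approx(4.83)
        assert res["sd_ns"] == pytest.approx(0.0)

    def test_window_excludes_out_of_range_pixels(self):
        tau = np.full((3, 3), np.nan)
        tau[0, :] = [2.0, 4.0, 8.0]
        lt = fl.LifetimeImage(tau=tau)
        rois = fl.RoiSet({"r": rect(-0.5, -0.5, 2.4, 2.4)},
                         lifetime_window=(2.8, 7.0))
        res = fl.roi_mean_lifetime(lt, rois).iloc[0]
        assert res["mean_ns"] == pytest.approx(4.0)
        assert res["n_pixels"] == 1
        assert res["n_excluded_window"] == 2

    def test_empty_roi_reported_undefined(self):
        lt = self.make_lifetime(np.full((10, 10), 20.0))  # outside window
        rois = fl.RoiSet({"r": rect(1, 1, 5, 5)})
        res = fl.roi_mean_lifetime(lt, rois).iloc[0]
        assert np.isnan(res["mean_ns"]) and res["n_pixels"] == 0

    def test_polygon_matches_point_in_polygon_oracle(self):
        from matplotlib.path import Path

        rng = np.random.default_rng(4)
        tau = rng.uniform(3.0, 6.0, size=(30, 30))
        ang = np.sort(rng.uniform(0, 2 * np.pi, 7))
        poly = np.column_stack([15 + 10 * np.sin(ang), 15 + 10 * np.cos(ang)])
        lt = fl.LifetimeImage(tau=tau)
        res = fl.roi_mean_lifetime(lt, fl.RoiSet({"r": poly})).iloc[0]
        rr, cc = np.mgrid[0:30, 0:30]
        # polygon2mask tests pixel centres; replicate with matplotlib.path
        inside = Path(poly).contains_points(
            np.column_stack([rr.ravel(), cc.ravel()])).reshape(30, 30)
        oracle = tau[inside]
        oracle = oracle[(oracle >= 2.8) & (oracle <= 7.0)]
        assert res["n_pixels"] == oracle.size
        assert res["mean_ns"] == pytest.approx(oracle.mean(), rel=1e-12)

    def test_translation_invariance_with_roi(self):
        rng = np.random.default_rng(6)
        tau = rng.uniform(3.0, 6.0, size=(20, 40))
        shifted = np.roll(tau, (0, 7), axis=(0, 1))
        r0 = fl.roi_mean_lifetime(fl.LifetimeImage(tau=tau),
                                  fl.RoiSet({"r": rect(2, 2, 15, 15)}))
        r1 = fl.roi_mean_lifetime(fl.LifetimeImage(tau=shifted),
                                  fl.RoiSet({"r": rect(2, 9, 15, 22)}))
        assert r0.iloc[0]["mean_ns"] == pytest.approx(r1.iloc[0]["mean_ns"])


class TestRender:
    def test_clipping_at_range_ends_and_midpoint(self):
        lt = fl.LifetimeImage(tau=np.array([[3.0, 3.75, 4.25, 4.75, 5.5]]))
        rgb = fl.render_lifetime(lt, display_range=(3.75, 4.75))
        assert np.allclose(rgb[0, 0], rgb[0, 1])  # below range == low end
        assert np.allclose(rgb[0, 3], rgb[0, 4])  # above range == high end
        import matplotlib
        mid = matplotlib.colormaps["rainbow"](0.5)[:3]
        assert np.allclose(rgb[0, 2], mid)

    def test_undefined_pixels_black(self):
        lt = fl.LifetimeImage(tau=np.array([[np.nan, 4.0]]))
        rgb = fl.render_lifetime(lt)
        assert np.allclose(rgb[0, 0], 0.0)


def test_pixel_size_propagates_through_pipeline():
    """The physical pixel size survives binning, phasor and lifetime maps."""
    from epiquant.synth import FlimSimConfig, generate_flim_stack

    cfg = FlimSimConfig(image_shape=(10, 10),
                        regions=[(rect(-0.5, -0.5, 9.5, 9.5), 4.0)],
                        photons_per_pixel_mean=500.0, pixel_size_nm=135.0,
                        seed=0)
    stack, _ = generate_flim_stack(cfg)
    binned = fl.bin_pixels(stack, 5)
    assert binned.pixel_size_nm == pytest.approx(675.0)
    ph = fl.phasor_transform(fl.threshold_background(binned, 1))
    assert ph.pixel_size_nm == pytest.approx(675.0)
    lt = fl.lifetime_map(fl.median_filter_phasor(ph, 3))
    assert lt.pixel_size_nm == pytest.approx(675.0)
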