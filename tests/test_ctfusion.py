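"""CT-derived multi-layered scenes: HU mapping, classing, edges, warping."""

import numpy as np
import pytest

from histophantom.ctfusion import (
    CONNECTIVE_TISSUE,
    CTSlice,
    DEFAULT_INTERVALS,
    DensityIntervalTable,
    THYROID,
    add_connective_edges,
    annulus_warp,
    apply_thyroid_region,
    classify_and_texture,
    density_to_sound_speed,
    embed_microstructure,
    hu_to_density,
)
from histophantom.datatypes import AcousticPhantom, ComponentMasks


class TestHuToDensity:
    def test_water_reference(self):
        rho = hu_to_density(CTSlice(np.array([[0.0]]), 500.0))
        assert rho[0, 0] == pytest.approx(1000.0, rel=0.03)

    def test_air_near_zero(self):
        rho = hu_to_density(CTSlice(np.array([[-1000.0]]), 500.0))
        assert rho[0, 0] < 40.0

    def test_monotone_non_decreasing(self):
        hu = np.linspace(-1024, 3000, 5000)[None, :]
        rho = hu_to_density(CTSlice(hu, 500.0))[0]
        assert np.all(np.diff(rho) >= -1e-9)

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            rho = hu_to_density(CTSlice(np.array([[5000.0]]), 500.0))
        assert np.isfinite(rho).all()


class TestDensityToSoundSpeed:
    def test_hand_values(self):
        assert density_to_sound_speed(np.array([1000.0]))[0] == pytest.approx(
            1510.6, abs=0.05
        )
        assert density_to_sound_speed(np.array([544.0]))[0] == pytest.approx(
            1000.0, abs=0.5
        )

    def test_linearity_and_composition_monotone(self):
        rho = np.linspace(200, 2000, 100)
        c = density_to_sound_speed(rho)
        assert np.allclose(np.diff(c, 2), 0.0, atol=1e-9)  # linear
        hu = np.linspace(-1024, 3000, 400)[None, :]
        c_of_hu = density_to_sound_speed(
            hu_to_density(CTSlice(hu, 500.0))
        )[0]
        assert np.all(np.diff(c_of_hu) >= -1e-9)


class TestClassifyAndTexture:
    def test_uniform_water_single_class(self):
        rho = np.full((32, 32), 1000.0)
        out = classify_and_texture(rho, rng=np.random.default_rng(0))
        assert np.unique(out["labels"]).size == 1

    def test_speckle_scaling_factor_50(self):
        rho = np.full((8, 8), 1000.0)
        out = classify_and_texture(rho)
        lab = out["labels"][0, 0]
        assert out["speckle_intensity"][0, 0] == pytest.approx(
            50.0 * DEFAULT_INTERVALS.speckle_intensity[lab]
        )

    def test_half_open_interval_boundaries(self):
        table = DensityIntervalTable(
            edges=np.array([0.0, 10.0, 20.0]),
            labels=["a", "b"],
            speckle_intensity=np.array([0.0, 0.0]),
            alpha0=np.array([0.1, 0.2]),
        )
        rho = np.array([[9.999, 10.0, 19.999]])
        labels = table.classify(rho)
        assert labels.tolist() == [[0, 1, 1]]  # [lo, hi) convention


class TestConnectiveEdges:
    def test_uniform_image_no_edges(self):
        rho = np.full((32, 32), 1000.0)
        c = density_to_sound_speed(rho)
        out = add_connective_edges(rho, c, np.zeros_like(rho), threshold=1.0)
        assert not out["edges"].any()

    def test_step_image_edge_band_and_printed_triple(self):
        rho = np.full((40, 40), 950.0)
        rho[:, 20:] = 1080.0
        c = density_to_sound_speed(rho)
        out = add_connective_edges(rho, c, np.zeros_like(rho), threshold=50.0)
        edges = out["edges"]
        # the band hugs the boundary columns
        cols = np.nonzero(edges.any(axis=0))[0]
        assert set(cols) <= {18, 19, 20, 21}
        assert edges[:, 19].all() or edges[:, 20].all()
        assert np.all(out["density"][edges] == CONNECTIVE_TISSUE["density"])
        assert np.all(
            out["sound_speed"][edges] == CONNECTIVE_TISSUE["sound_speed"]
        )
        assert np.all(out["absorption"][edges] == CONNECTIVE_TISSUE["alpha0"])


class TestThyroid:
    def test_properties_applied_inside_smoothed_mask(self):
        rho = np.full((64, 64), 1000.0)
        c = density_to_sound_speed(rho)
        mask = np.zeros((64, 64), bool)
        mask[20:40, 20:40] = True
        out = apply_thyroid_region(
            rho, c, np.zeros_like(rho), mask, spacing_um=2.47,
            rng=np.random.default_rng(0),
        )
        inside = out["mask"]
        assert inside[30, 30]
        assert out["sound_speed"][30, 30] == THYROID["sound_speed"]
        assert out["absorption"][30, 30] == THYROID["alpha0"]
        assert out["density"][inside].mean() == pytest.approx(
            THYROID["density"], rel=0.01
        )


class TestEmbedMicrostructure:
    def _setup(self):
        rng = np.random.default_rng(0)
        rho = 1085.0 * (1 + 0.05 * rng.standard_normal((20, 20)))
        c = density_to_sound_speed(rho)
        ph = AcousticPhantom(rho, c, np.zeros_like(rho), 1.1, 24.7)
        scene_rho = np.full((40, 40), 1000.0)
        scene_c = density_to_sound_speed(scene_rho)
        region = np.zeros((40, 40), bool)
        region[5:25, 5:25] = True
        return ph, scene_rho, scene_c, region

    def test_mu_scale_zero_homogeneous(self):
        ph, srho, sc, region = self._setup()
        out = embed_microstructure(srho, sc, ph, region, 0.0, 1085.0, 1585.0)
        assert np.allclose(out["density"][region], 1085.0)
        assert np.allclose(out["sound_speed"][region], 1585.0)

    def test_mu_scale_one_identity(self):
        ph, srho, sc, region = self._setup()
        out = embed_microstructure(srho, sc, ph, region, 1.0, 1085.0, 1585.0)
        assert np.allclose(out["density"][5:25, 5:25], ph.density)

    def test_mu_scale_half_halves_deviation(self):
        ph, srho, sc, region = self._setup()
        out = embed_microstructure(srho, sc, ph, region, 0.5, 1085.0, 1585.0)
        dev_full = ph.density - 1085.0
        dev_half = out["density"][5:25, 5:25] - 1085.0
        assert np.allclose(dev_half, 0.5 * dev_full)

    def test_outside_region_untouched(self):
        ph, srho, sc, region = self._setup()
        out = embed_microstructure(srho, sc, ph, region, 1.0, 1085.0, 1585.0)
        assert np.allclose(out["density"][~region], srho[~region])

    def test_tiling_covers_larger_region(self):
        ph, srho, sc, _ = self._setup()
        region = np.zeros((40, 40), bool)
        region[2:38, 2:38] = True  # larger than the 20x20 phantom
        out = embed_microstructure(srho, sc, ph, region, 1.0, 1085.0, 1585.0)
        assert np.all(out["density"][region] > 0)
        assert out["density"][region].std() > 0


class TestAnnulusWarp:
    def _strip(self, h=20, w=400, res=25.0):
        collagen = np.zeros((h, w), bool)
        collagen[::4] = True  # layered strip
        return ComponentMasks(collagen, ~collagen, np.zeros((h, w), bool), res)

    def test_uniform_strip_uniform_annulus(self):
        h, w, res = 12, 400, 25.0
        masks = ComponentMasks(
            np.ones((h, w), bool), np.zeros((h, w), bool),
            np.zeros((h, w), bool), res,
        )
        warped = annulus_warp(masks, inner_radius_mm=2.5)
        # every in-annulus pixel is collagen; thickness preserved
        n = warped.shape[0]
        cz = cx = n // 2
        zz, xx = np.indices(warped.shape)
        r = np.hypot(zz - cz, xx - cx) * res * 1e-6 * 1e3  # mm
        annulus = (r >= 2.5) & (r < 2.5 + h * res * 1e-3)
        inner = r < 2.5 - 0.05
        assert warped.collagen[annulus].mean() > 0.99
        assert not warped.collagen[inner].any()

    def test_area_preserved_for_thin_wall(self):
        masks = self._strip(h=10)
        warped = annulus_warp(masks, inner_radius_mm=2.5)
        res_m = masks.resolution_um * 1e-6
        strip_area = masks.collagen.mean() * np.pi * (
            (2.5e-3 + 10 * res_m) ** 2 - 2.5e-3**2
        )
        warped_area = warped.collagen.sum() * res_m**2
        assert warped_area == pytest.approx(strip_area, rel=0.10)

    def test_lumen_untouched_and_exclusive(self):
        masks = self._strip()
        warped = annulus_warp(masks, inner_radius_mm=2.5)
        assert warped.validate_partition(strict=False)
        n = warped.shape[0]
        assert warped.background[n // 2, n // 2]
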