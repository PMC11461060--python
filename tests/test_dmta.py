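"""Surface pre-treatment and texture parameters (Asfc, epLsar, Str, HAsfc)."""

import json

import numpy as np
import pytest

from paleodent import dmta
from paleodent import synthetic


SIZE = 128
SPACING = 200.0 / SIZE


def _grid(size=SIZE):
    yy, xx = np.mgrid[0:size, 0:size]
    return yy * (200.0 / size), xx * (200.0 / size)


class TestPreprocess:
    def test_masked_plane_reduces_to_zero(self):
        rng = np.random.default_rng(0)
        y_um, x_um = _grid()
        z = 2.0 * x_um + 1.0 * y_um + 5.0
        mask = rng.random(z.shape) > 0.005
        scan = dmta.SurfaceScan(np.where(mask, z, np.nan), SPACING)
        out = dmta.preprocess(scan, invert=False, window_um=None)
        assert np.abs(out.heights).max() < 1e-9

    def test_degree8_polynomial_annihilated(self):
        x = np.linspace(-1, 1, SIZE)
        X, Y = np.meshgrid(x, x)
        z = 3 * X ** 8 - 2 * X ** 3 * Y ** 5 + Y ** 6 + X * Y + 0.5
        out = dmta.preprocess(dmta.SurfaceScan(z, SPACING), invert=False,
                              window_um=None)
        assert np.abs(out.heights).max() < 1e-9

    def test_sinusoid_on_tilt_matches_independent_projection(self):
        y_um, x_um = _grid()
        sin = 0.5 * np.sin(2 * np.pi * x_um / 10.0)
        scan = dmta.SurfaceScan(sin + 1.0 * x_um, SPACING)
        out = dmta.preprocess(scan, invert=False, window_um=None)
        # independent oracle: dense monomial least squares of total degree 8
        u = np.linspace(-1, 1, SIZE)
        U, V = np.meshgrid(u, u)
        cols = [U ** i * V ** j for i in range(9) for j in range(9 - i)]
        A = np.column_stack([c.ravel() for c in cols])
        coef, *_ = np.linalg.lstsq(A, (sin + 1.0 * x_um).ravel(), rcond=None)
        expected = (sin + 1.0 * x_um).ravel() - A @ coef
        assert np.abs(out.heights.ravel() - expected).max() < 0.005  # 1% of amp
        assert abs(out.heights.mean()) < 1e-9

    def test_inversion_negates_relief(self):
        y_um, x_um = _grid()
        sin = 0.5 * np.sin(2 * np.pi * x_um / 10.0)
        a = dmta.preprocess(dmta.SurfaceScan(sin, SPACING), invert=True,
                            window_um=None)
        b = dmta.preprocess(dmta.SurfaceScan(sin, SPACING), invert=False,
                            window_um=None)
        assert np.allclose(a.heights, -b.heights, atol=1e-9)

    def test_idempotent_on_clean_surfaces(self):
        surf = synthetic.gen_surface("isotropic_gaussian", SIZE, seed=8)
        once = dmta.preprocess(surf, invert=False, window_um=None)
        twice = dmta.preprocess(once, invert=False, window_um=None)
        assert np.abs(once.heights - twice.heights).max() < 1e-9

    def test_excessive_nonmeasured_fraction_rejected(self):
        z = np.random.default_rng(1).normal(size=(64, 64))
        z[:10] = np.nan
        with pytest.raises(dmta.SurfaceError, match="non-measured"):
            dmta.preprocess(dmta.SurfaceScan(z, SPACING))

    def test_window_larger_than_grid_rejected(self):
        z = np.zeros((32, 32))
        with pytest.raises(dmta.SurfaceError, match="window"):
            dmta.preprocess(dmta.SurfaceScan(z, 1.0), window_um=200.0)

    def test_peak_removal_flattens_spikes(self):
        surf = synthetic.gen_surface("isotropic_gaussian", SIZE, seed=3)
        z = surf.heights.copy()
        z[40, 40] += 500.0
        out = dmta.preprocess(dmta.SurfaceScan(z, SPACING), invert=False,
                              window_um=None)
        ref = dmta.preprocess(surf, invert=False, window_um=None)
        assert np.abs(out.heights - ref.heights).max() < 1.0


class TestRelativeArea:
    def test_flat_surface_is_one_at_every_scale(self):
        curve = dmta.relative_area_curve(synthetic.gen_surface("flat", SIZE))
        assert all(a == pytest.approx(1.0, abs=1e-12) for _, a in curve)

    def test_45_degree_plane_gives_sqrt2(self):
        y_um, x_um = _grid()
        scan = dmta.SurfaceScan(x_um.astype(float), SPACING)  # slope 1
        curve = dmta.relative_area_curve(scan)
        for _, a in curve:
            assert a == pytest.approx(np.sqrt(2.0), rel=1e-9)

    def test_non_increasing_with_scale_on_rough_surface(self):
        surf = synthetic.gen_surface("isotropic_gaussian", SIZE, seed=4)
        curve = dmta.relative_area_curve(surf)
        areas = [a for _, a in curve]
        assert all(b <= a + 1e-9 for a, b in zip(areas, areas[1:]))


class TestAsfc:
    def test_flat_surface_zero(self):
        assert dmta.asfc_of(synthetic.gen_surface("flat", SIZE)) == 0.0

    def test_fractal_slope_recovery_within_10pct(self):
        for seed in (0, 1):
            surf = synthetic.gen_surface("spectral_fractal", 256, seed=seed,
                                         amplitude_um=20.0)
            clean = dmta.preprocess(surf, invert=False, window_um=None)
            curve = dmta.relative_area_curve(clean)
            fine = [(s, a) for s, a in curve if s <= dmta.FINE_SCALE_LIMIT_UM2]
            ls = np.log10([p[0] for p in fine])
            la = np.log10([p[1] for p in fine])
            oracle = -1000.0 * np.polyfit(ls, la, 1)[0]
            assert dmta.asfc(curve) == pytest.approx(oracle, rel=0.10)

    def test_amplitude_doubling_increases_complexity(self):
        for seed in (5, 6):
            surf = synthetic.gen_surface("isotropic_gaussian", SIZE, seed=seed)
            doubled = dmta.SurfaceScan(surf.heights * 2.0, surf.spacing_um)
            assert dmta.asfc_of(doubled) > dmta.asfc_of(surf)


class TestEplsar:
    def test_flat_surface_zero(self):
        assert dmta.eplsar(synthetic.gen_surface("flat", SIZE)) == pytest.approx(0.0, abs=1e-12)

    def test_grooves_score_high_and_rotation_invariant(self, grooved_surface):
        e = dmta.eplsar(grooved_surface)
        rotated = dmta.SurfaceScan(grooved_surface.heights.T.copy(),
                                   grooved_surface.spacing_um)
        e_rot = dmta.eplsar(rotated)
        assert e > 1e-3
        assert e_rot == pytest.approx(e, rel=0.01)

    def test_isotropic_surface_below_permuted_orientation_null(self, isotropic_surface):
        e = dmta.eplsar(isotropic_surface)
        # null: shuffle the orientation-to-share assignment; the mean
        # resultant of permuted shares bounds what isotropy can produce
        # (a modest slack absorbs the adjacent-orientation correlation
        # that permutation destroys)
        angles = np.deg2rad(np.arange(0.0, 180.0, 5.0))
        z = isotropic_surface.heights
        z = z / np.sqrt(np.mean((z - z.mean()) ** 2))
        lengths = np.array([
            dmta._profile_relative_length(z, isotropic_surface.spacing_um,
                                          a, 1.8)
            for a in angles])
        f = lengths / lengths.sum()
        rng = np.random.default_rng(0)
        null = []
        for _ in range(200):
            null.append(abs(np.sum(rng.permutation(f) * np.exp(2j * angles))))
        assert e <= np.quantile(null, 0.95) * 1.5

    def test_grooves_far_exceed_isotropic(self, grooved_surface, isotropic_surface):
        assert dmta.eplsar(grooved_surface) > 10 * dmta.eplsar(isotropic_surface)

    def test_too_few_orientations_rejected(self, isotropic_surface):
        with pytest.raises(dmta.SurfaceError):
            dmta.eplsar(isotropic_surface, angle_step_deg=90.0)


class TestStr:
    def test_isotropic_gaussian_near_one(self, isotropic_surface):
        s, _ = dmta.str_param(dmta.preprocess(isotropic_surface, invert=False,
                                              window_um=None))
        assert s >= 0.8

    def test_unidirectional_grooves_near_zero(self, grooved_surface):
        s, _ = dmta.str_param(dmta.preprocess(grooved_surface, invert=False,
                                              window_um=None))
        assert s <= 0.1

    def test_exactly_invariant_to_height_rescaling(self, isotropic_surface):
        s1, _ = dmta.str_param(isotropic_surface)
        scaled = dmta.SurfaceScan(isotropic_surface.heights * 3.7,
                                  isotropic_surface.spacing_um)
        s2, _ = dmta.str_param(scaled)
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_bad_threshold_rejected(self, isotropic_surface):
        with pytest.raises(dmta.SurfaceError):
            dmta.str_param(isotropic_surface, s=1.5)


class TestHasfc:
    def test_uniform_surface_low_heterogeneity(self, isotropic_surface):
        clean = dmta.preprocess(isotropic_surface, invert=False, window_um=None)
        assert dmta.hasfc(clean, 3) < 0.3
        assert dmta.hasfc(clean, 9) < 0.3

    def test_rough_quadrant_large_range_heterogeneity(self):
        surf = synthetic.gen_surface("rough_quadrant", 256, seed=4)
        clean = dmta.preprocess(surf, invert=False, window_um=None)
        assert dmta.hasfc(clean, 3, variant="range") > 1.0

    def test_exactly_invariant_to_height_rescaling(self, isotropic_surface):
        h1 = dmta.hasfc(isotropic_surface, 3)
        scaled = dmta.SurfaceScan(isotropic_surface.heights * 2.0,
                                  isotropic_surface.spacing_um)
        assert dmta.hasfc(scaled, 3) == pytest.approx(h1, rel=1e-9)


class TestClassification:
    @pytest.mark.parametrize("str_v,asfc_v,tendency", [
        (0.80, 2.31, "browsing with hard objects"),
        (0.14, 1.18, "abrasive-feeder"),
        (0.25, 1.50, "mixed/undetermined"),
    ])
    def test_threshold_rules(self, str_v, asfc_v, tendency):
        res = dmta.TextureResult(asfc=asfc_v, eplsar=0.0, str_ratio=str_v,
                                 hasfc_3x3=0.0, hasfc_9x9=0.0)
        assert dmta.classify_dmt(res)["tendency"] == tendency


class TestPipeline:
    def test_deterministic_results(self, isotropic_surface):
        a = dmta.analyze(isotropic_surface, invert=False, window_um=None)
        b = dmta.analyze(isotropic_surface, invert=False, window_um=None)
        assert (a.asfc, a.eplsar, a.str_ratio, a.hasfc_3x3, a.hasfc_9x9) == \
               (b.asfc, b.eplsar, b.str_ratio, b.hasfc_3x3, b.hasfc_9x9)

    def test_surface_io_round_trip(self, tmp_path, isotropic_surface):
        path = tmp_path / "scan.csv"
        dmta.write_surface(isotropic_surface, path)
        back = dmta.read_surface(path)
        assert np.allclose(back.heights, isotropic_surface.heights, atol=1e-4)
        assert back.spacing_um == isotropic_surface.spacing_um

    def test_full_resolution_field(self):
        """The standard 200 μm field at nominal profilometer resolution."""
        surf = synthetic.gen_surface("sinusoid_grooves", dmta.NOMINAL_PX,
                                     spacing_um=200.0 / (dmta.NOMINAL_PX - 1),
                                     seed=1)
        clean = dmta.preprocess(surf, invert=False)
        assert clean.shape[0] >= 1550
        s, _ = dmta.str_param(clean)
        assert s <= 0.1
        assert dmta.asfc_of(clean) > 0
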