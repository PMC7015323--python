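"""Detection-distance solver, sensitivity grid, iris comparison."""

import numpy as np
import pytest

from photoloc.detection import (
    DEFAULT_DISTANCES_MM,
    SceneTemplate,
    default_scene,
    detection_scan,
    iris_comparison,
    sensitivity_grid,
)
from photoloc.radiometry import GeometryParams
from photoloc.spectra import Spectrum, SpectrumKind, default_grid
from photoloc.vision import VisualSystemParams, default_visual_system


def flat(v, kind):
    return Spectrum.constant(v, kind)


def flat_vsp(**overrides):
    g = default_grid()
    one = Spectrum.constant(1.0, SpectrumKind.SENSITIVITY, g)
    t = Spectrum.constant(1.0, SpectrumKind.TRANSMISSION, g)
    return VisualSystemParams((one, one, one), t, **overrides)


def brute_force_max_detect(scene, vsp, threshold, step_mm=0.1):
    """Independent oracle: raw-formula fluxes on a fine distance grid.

    Recomputes both photon paths from first principles per distance (no
    power-law shortcut shared with the solver) and returns the supremum
    distance with Michelson contrast ≥ threshold.
    """
    d = np.arange(10.0, 150.0 + step_mm / 2, step_mm)
    g = scene.geometry
    T = vsp.ocular_media.values
    S = np.stack([s.values for s in vsp.sensitivities])  # (3, 301)
    phi2 = scene.L_base.values[None, :] * g.area_sp_pupil_mm2 * g.area_tf_pupil_mm2 / d[:, None] ** 2
    e_t = scene.L_spark.values[None, :] * g.area_spark_mm2 / d[:, None] ** 2
    phir = e_t * scene.R_retro.values[None, :] / np.pi * g.area_sp_pupil_mm2 * g.area_tf_pupil_mm2 / d[:, None] ** 2
    q2 = (phi2 * T[None, :]) @ S.T  # (nd, 3), Δλ = 1 nm
    q1 = ((phi2 + phir) * T[None, :]) @ S.T
    Q1, Q2 = q1[:, 1] + q1[:, 2], q2[:, 1] + q2[:, 2]
    C = np.where(Q1 + Q2 > 0, (Q1 - Q2) / np.where(Q1 + Q2 > 0, Q1 + Q2, 1), 0.0)
    ok = np.flatnonzero(C >= threshold)
    return float(d[ok[-1]]) if ok.size else None


class TestDetectionScan:
    def test_zero_spark_no_detection(self, vsp):
        scene = SceneTemplate(
            flat(1.0, SpectrumKind.RADIANCE),
            flat(0.0, SpectrumKind.RADIANCE),
            flat(1.0, SpectrumKind.REFLECTANCE),
            GeometryParams(),
        )
        scan = detection_scan(scene, vsp)
        assert np.all(scan.achromatic_contrasts == 0)
        assert np.all(scan.chromatic_jnds == 0)
        assert scan.max_detect_achromatic_mm is None
        assert scan.max_detect_chromatic_mm is None

    def test_vanishing_threshold_compliant_over_whole_grid(self):
        vsp = flat_vsp(achromatic_threshold=1e-12)
        scene = SceneTemplate(
            flat(1e-3, SpectrumKind.RADIANCE),
            flat(1.0, SpectrumKind.RADIANCE),
            flat(1.0, SpectrumKind.REFLECTANCE),
            GeometryParams(1.0, 1.0, 1.0, 100.0),
        )
        scan = detection_scan(scene, vsp)
        assert scan.max_detect_achromatic_mm == 150.0

    @pytest.mark.parametrize("L_base", [1e-3, 5e-3])
    def test_constant_scene_matches_analytic_root(self, L_base):
        # constant spectra: C(d) = K/(2M d² + K) with K and M from the
        # closed-form chain; the solver must return floor of the analytic
        # root of C(d) = threshold
        theta = 0.008
        vsp = flat_vsp(achromatic_threshold=theta)
        g = GeometryParams(1.0, 1.0, 1.0, 100.0)
        scene = SceneTemplate(
            flat(L_base, SpectrumKind.RADIANCE),
            flat(1.0, SpectrumKind.RADIANCE),
            flat(1.0, SpectrumKind.REFLECTANCE),
            g,
        )
        K = 1.0 / np.pi  # Ls·A_spark·Rr/π·A_sp·A_tf per nm
        M = L_base  # Lb·A_sp·A_tf per nm
        d_star = np.sqrt(K * (1 - theta) / (2 * M * theta))
        expected = min(float(np.floor(d_star)), 150.0)
        scan = detection_scan(scene, vsp)
        assert scan.max_detect_achromatic_mm == expected

    def test_constant_scene_has_zero_chromatic_contrast(self, vsp):
        scene = SceneTemplate(
            flat(1e-3, SpectrumKind.RADIANCE),
            flat(1.0, SpectrumKind.RADIANCE),
            flat(1.0, SpectrumKind.REFLECTANCE),
            GeometryParams(),
        )
        scan = detection_scan(scene, vsp)
        np.testing.assert_allclose(scan.chromatic_jnds, 0.0, atol=1e-9)

    def test_max_detect_lies_on_grid_and_meets_threshold(self, scene, vsp):
        scan = detection_scan(scene, vsp)
        d = scan.max_detect_achromatic_mm
        assert d in scan.distances_mm
        idx = int(np.flatnonzero(scan.distances_mm == d)[0])
        assert scan.achromatic_contrasts[idx] >= vsp.achromatic_threshold
        if idx + 1 < len(scan.distances_mm):
            assert scan.achromatic_contrasts[idx + 1] < vsp.achromatic_threshold

    def test_solver_within_one_cell_of_brute_force_on_random_scenes(self, vsp, rng):
        # 50 randomized synthetic scenes vs the 0.1-mm raw-formula oracle
        g = default_grid()
        for _ in range(50):
            scale = 10 ** rng.uniform(-4, -2)
            Lb = Spectrum(g, scale * rng.uniform(0.2, 1, g.size), SpectrumKind.RADIANCE)
            Ls = Spectrum(g, rng.uniform(0.2, 1, g.size), SpectrumKind.RADIANCE)
            Rr = Spectrum(g, rng.uniform(0.1, 2, g.size), SpectrumKind.REFLECTANCE)
            scene = SceneTemplate(Lb, Ls, Rr, GeometryParams())
            got = detection_scan(scene, vsp).max_detect_achromatic_mm
            want = brute_force_max_detect(scene, vsp, vsp.achromatic_threshold)
            if want is None:
                assert got is None
            else:
                assert got is not None and abs(got - want) <= 1.0


class TestSensitivityGrid:
    levels = np.array([0.0, 0.5, 1.0, 1.5, 2.0])

    def test_monotone_in_both_axes(self, scene, vsp):
        grid = sensitivity_grid(scene, vsp, self.levels, self.levels)
        m = np.nan_to_num(grid.detect_mm, nan=0.0)
        assert np.all(np.diff(m, axis=0) >= 0)
        assert np.all(np.diff(m, axis=1) >= 0)

    def test_zero_level_row_and_column_undetectable(self, scene, vsp):
        grid = sensitivity_grid(scene, vsp, self.levels, self.levels)
        assert np.all(np.isnan(grid.detect_mm[0, :]))
        assert np.all(np.isnan(grid.detect_mm[:, 0]))

    def test_unit_cell_consistent_with_single_scan(self, scene, vsp):
        grid = sensitivity_grid(scene, vsp, np.array([1.0]), np.array([1.0]))
        direct = detection_scan(scene, vsp).max_detect_achromatic_mm
        assert grid.detect_mm[0, 0] == direct

    def test_brighter_ambient_never_decreases_any_cell(self, scene, vsp):
        # orientation (north vs south) enters purely as an ambient
        # scaling, which doubles the spark radiance
        dim = sensitivity_grid(scene, vsp, self.levels, self.levels)
        bright = sensitivity_grid(scene.scaled(spark_factor=2.0), vsp, self.levels, self.levels)
        a = np.nan_to_num(dim.detect_mm, nan=0.0)
        b = np.nan_to_num(bright.detect_mm, nan=0.0)
        assert np.all(b >= a)

    def test_negative_levels_rejected(self, scene, vsp):
        with pytest.raises(ValueError):
            sensitivity_grid(scene, vsp, np.array([-0.5, 1.0]), self.levels)


class TestIrisComparison:
    def test_zero_iris_reflectance_no_detection(self, scene, vsp, ambient):
        scan = iris_comparison(
            flat(0.0, SpectrumKind.REFLECTANCE), scene.L_spark, scene.geometry, vsp,
            E_down=ambient,
        )
        assert scan.max_detect_achromatic_mm is None

    def test_dull_iris_detected_shorter_than_retro_pupil(self, scene, vsp, ambient):
        pupil = detection_scan(scene, vsp).max_detect_achromatic_mm
        iris = iris_comparison(
            flat(0.1, SpectrumKind.REFLECTANCE), scene.L_spark, scene.geometry, vsp,
            E_down=ambient,
        ).max_detect_achromatic_mm
        assert pupil is not None
        assert iris is None or iris < pupil

    def test_substitution_identity_reproduces_pupil_scan(self, scene, vsp):
        # feeding the pupil's own retro spectrum and baseline through the
        # iris path must reproduce the pupil scan exactly
        scan_iris = iris_comparison(
            scene.R_retro, scene.L_spark, scene.geometry, vsp, L_base_iris=scene.L_base
        )
        scan_pupil = detection_scan(scene, vsp)
        np.testing.assert_array_equal(
            scan_iris.achromatic_contrasts, scan_pupil.achromatic_contrasts
        )
        assert scan_iris.max_detect_achromatic_mm == scan_pupil.max_detect_achromatic_mm

    def test_requires_baseline_or_ambient(self, scene, vsp):
        with pytest.raises(ValueError, match="E_down"):
            iris_comparison(scene.R_retro, scene.L_spark, scene.geometry, vsp)


class TestDefaultScene:
    def test_achromatic_finite_chromatic_absent(self, scene, vsp):
        scan = detection_scan(scene, vsp)
        assert scan.max_detect_achromatic_mm is not None
        assert 10.0 <= scan.max_detect_achromatic_mm <= 150.0
        assert scan.max_detect_chromatic_mm is None
        assert np.all(scan.chromatic_jnds < 1.0)

    def test_contrasts_decrease_with_distance(self, scene, vsp):
        scan = detection_scan(scene, vsp)
        assert np.all(np.diff(scan.achromatic_contrasts) < 0)
        assert np.all(np.diff(scan.chromatic_jnds) <= 1e-12)
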