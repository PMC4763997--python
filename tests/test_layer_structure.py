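"""Transect thickness measurement and depth-layer clustering."""

import numpy as np
import pytest

from peritomorph import (
    SectionParams,
    cluster_vessel_layers,
    generate_section,
    layer_depth_vs_thickness,
    measure_submesothelial_thickness,
    sample_layer_depths,
)
from peritomorph.stain_quant import StainSection
from peritomorph.synthetic_tissue import LABEL_BOUNDARY, LABEL_MESO, LABEL_SUBMESO


def _structural(thickness_profile_um, scale=1.0, height_um=700):
    """Build a structural label map from a thickness-per-column profile."""
    n_cols = len(thickness_profile_um)
    n_rows = int(height_um / scale)
    img = np.full((n_rows, n_cols), LABEL_SUBMESO, dtype=np.float32)
    meso_rows = max(int(4.0 / scale), 1)
    img[:meso_rows, :] = LABEL_MESO
    for j, t in enumerate(thickness_profile_um):
        lower = int(round((t / scale))) + meso_rows
        img[lower:, j] = LABEL_BOUNDARY
    return StainSection(img, "structural", scale)


class TestThicknessMeasurement:
    def test_uniform_band(self):
        sec = _structural(np.full(300, 400.0))
        assert measure_submesothelial_thickness(sec) == pytest.approx(400.0, abs=1.0)

    def test_linear_wedge_median_matches_dense_transects(self):
        profile = np.linspace(200, 600, 400)
        sec = _structural(profile)
        sparse = measure_submesothelial_thickness(sec, n_transects=7)
        dense = measure_submesothelial_thickness(sec, n_transects=200)
        assert dense == pytest.approx(400.0, rel=0.02)  # dense-transect oracle
        assert sparse == pytest.approx(dense, rel=0.02)

    def test_fewer_than_five_transects_rejected(self):
        with pytest.raises(ValueError, match="five"):
            measure_submesothelial_thickness(_structural(np.full(50, 100.0)), n_transects=3)

    def test_missing_lower_boundary_named(self):
        img = np.full((100, 100), LABEL_SUBMESO, dtype=np.float32)
        with pytest.raises(ValueError, match="boundary"):
            measure_submesothelial_thickness(StainSection(img, "structural", 1.0))

    def test_invariant_to_horizontal_translation(self):
        profile = 300 + 50 * np.sin(np.linspace(0, 4 * np.pi, 360))
        sec = _structural(profile)
        rolled = StainSection(np.roll(sec.image, 90, axis=1), "structural", 1.0)
        a = measure_submesothelial_thickness(sec, n_transects=36)
        b = measure_submesothelial_thickness(rolled, n_transects=36)
        assert a == pytest.approx(b, rel=0.02)

    def test_generated_section_recovers_true_thickness(self):
        params = SectionParams(
            analyzed_area=0.1, submeso_thickness_true=402.0,
            blood_density_true=0.0, lymph_density_true=0.0, seed=2,
        )
        sections, _ = generate_section(params, channels=("structural",))
        got = measure_submesothelial_thickness(sections["structural"])
        assert got == pytest.approx(402.0, rel=0.08)  # one section, sinusoidal boundary


class TestClusterLayers:
    WELL_SEPARATED = [30, 35, 40, 90, 95, 100, 185, 190, 200]

    def test_well_separated_kmedians_exact(self):
        fit = cluster_vessel_layers(self.WELL_SEPARATED, method="kmedians")
        np.testing.assert_allclose(fit.layer_median_depths, [35, 95, 190])
        assert fit.assignments.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_well_separated_mixture_close(self):
        fit = cluster_vessel_layers(self.WELL_SEPARATED)
        np.testing.assert_allclose(fit.layer_median_depths, [35, 95, 190], rtol=0.02)
        assert fit.assignments.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_medians_strictly_increasing_and_all_assigned(self):
        d = sample_layer_depths(300, rng=0, lo=0.0)
        fit = cluster_vessel_layers(d)
        assert np.all(np.diff(fit.layer_median_depths) > 0)
        assert fit.assignments.shape == (len(d),)
        assert set(np.unique(fit.assignments)) <= {0, 1, 2}

    def test_all_equal_depths_degenerate_single_layer(self):
        with pytest.warns(UserWarning, match="single layer"):
            fit = cluster_vessel_layers([50.0] * 10)
        assert fit.k == 1
        assert fit.layer_median_depths[0] == 50.0

    def test_fewer_vessels_than_k_reduces_k(self):
        with pytest.warns(UserWarning, match="reducing k"):
            fit = cluster_vessel_layers([10.0, 200.0], k=3)
        assert fit.k == 2

    def test_deterministic_and_permutation_invariant(self):
        d = sample_layer_depths(200, rng=3, lo=0.0)
        f1 = cluster_vessel_layers(d)
        f2 = cluster_vessel_layers(d[::-1])
        np.testing.assert_allclose(f1.layer_median_depths, f2.layer_median_depths)

    def test_separated_synthetic_layers_assigned_exactly(self):
        """Gaps > 4x the within-layer spread: assignments match generation."""
        rng = np.random.default_rng(1)
        comp = rng.integers(0, 3, 150)
        d = rng.normal(np.array([40.0, 150.0, 300.0])[comp], 5.0)
        for method in ("mixture", "kmedians"):
            fit = cluster_vessel_layers(d, method=method)
            assert (fit.assignments == comp).all()


class TestDepthThicknessCorrelation:
    def test_proportional_gives_rho_one(self):
        t = np.array([100, 200, 300, 400, 500.0])
        depths = np.column_stack([0.2 * t, 0.5 * t, 0.9 * t])
        res = layer_depth_vs_thickness(depths, t)
        np.testing.assert_allclose(res.rho, 1.0)

    def test_independent_is_near_zero(self):
        rng = np.random.default_rng(42)
        t = rng.uniform(100, 500, 200)
        depths = rng.uniform(20, 250, (200, 3))
        res = layer_depth_vs_thickness(depths, t)
        assert np.all(np.abs(res.rho) < 0.15)

    def test_constant_margin_reported_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            res = layer_depth_vs_thickness(np.full((5, 1), 50.0), [1, 2, 3, 4, 5])
        assert np.isnan(res.rho).all()

    def test_cohort_coupling_reproduces_reported_band(self):
        """Depths coupled to thickness through the generator: rho ~ 0.5-0.7."""
        from peritomorph import generate_cohort
        from peritomorph.synthetic_tissue import default_group_table

        tiny = SectionParams(analyzed_area=0.02)
        depths, thick = [], []
        for p in generate_cohort(default_group_table(), seed=8, base_params=tiny,
                                 channels=()):
            depths.append(p.params.layer_depths)
            thick.append(p.params.submeso_thickness_true)
        res = layer_depth_vs_thickness(np.array(depths), np.array(thick))
        assert np.all(res.rho > 0.4) and np.all(res.rho < 0.8)
        assert np.all(res.p_value < 0.001)
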