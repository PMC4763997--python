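"""Generator contracts: rasterization, densities, layers, determinism."""

import numpy as np
import pandas as pd
import pytest

from peritomorph import SectionParams, generate_cohort, generate_section, render_annulus
from peritomorph.synthetic_tissue import (
    DegenerateMaskWarning,
    default_group_table,
    expected_endothelial_area_per_vessel,
    iqr_to_sigma,
    sample_layer_depths,
)


class TestRenderAnnulus:
    @pytest.mark.parametrize("pixel_scale, tol", [(0.25, 0.05), (0.1, 0.02)])
    def test_area_converges_to_closed_form(self, pixel_scale, tol):
        # pixel-count oracle vs analytic pi (r_out^2 - r_in^2)
        mask = render_annulus((0.0, 0.0), 5.0, 3.5, pixel_scale)
        area = mask.sum() * pixel_scale**2
        assert area == pytest.approx(np.pi * (25 - 12.25), rel=tol)

    def test_inner_zero_gives_filled_disc(self):
        mask = render_annulus((0.0, 0.0), 5.0, 0.0, 0.25)
        from scipy import ndimage

        filled = ndimage.binary_fill_holes(mask)
        assert (filled == mask).all()  # no lumen: the collapsed phenotype
        assert mask.sum() * 0.0625 == pytest.approx(np.pi * 25, rel=0.05)

    def test_equal_radii_rejected(self):
        with pytest.raises(ValueError):
            render_annulus((0.0, 0.0), 5.0, 5.0, 0.25)

    def test_subpixel_wall_warns(self):
        with pytest.warns(DegenerateMaskWarning):
            render_annulus((0.0, 0.0), 5.0, 4.9, 0.25)


class TestGenerateSection:
    def test_zero_densities_give_empty_truth_and_blank_cd31(self):
        params = SectionParams(
            analyzed_area=0.05, blood_density_true=0.0, lymph_density_true=0.0,
            mast_density_true=0.0, seed=1,
        )
        sections, truth = generate_section(params)
        assert len(truth.vessels) == 0
        # CD31 contains nothing above the noise floor
        assert sections["cd31"].image.max() < 0.4

    def test_vessel_count_follows_requested_density(self):
        """Empirical density converges to the requested density (<2% rel. err).

        Counting ground-truth records over many seeded sections; Poisson
        placement means relative error shrinks as 1/sqrt(total count).
        """
        params = SectionParams(analyzed_area=0.144)
        total = 0
        n_sections = 500
        area = None
        for seed in range(n_sections):
            _, truth = generate_section(
                params.replace(seed=seed), channels=()
            )
            total += len(truth.vessels[truth.vessels.stain_class == "blood"])
            area = truth.analyzed_area
        density = total / (n_sections * area)
        assert density == pytest.approx(223.0, rel=0.02)

    def test_layer_medians_recovered_at_small_dispersion(self):
        params = SectionParams(
            analyzed_area=0.5, layer_iqrs=(4.0, 4.0, 4.0), seed=7,
            blood_density_true=400.0, lymph_density_true=0.0,
            submeso_thickness_true=260.0,
        )
        _, truth = generate_section(params, channels=())
        d = truth.vessels["depth_um"].to_numpy()
        centers = np.array([36.0, 96.0, 192.0])
        for c in centers:
            layer = d[np.abs(d - c) < 25]
            assert len(layer) > 10
            assert np.median(layer) == pytest.approx(c, rel=0.05)

    def test_collapsed_fraction_within_binomial_ci(self):
        params = SectionParams(analyzed_area=0.5, collapsed_fraction=0.2, seed=3)
        _, truth = generate_section(params, channels=())
        n = len(truth.vessels)
        k = int(truth.vessels["collapsed"].sum())
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(k / n - 0.2) < 4 * se

    def test_same_seed_bit_stable(self):
        params = SectionParams(analyzed_area=0.05, seed=11)
        s1, t1 = generate_section(params)
        s2, t2 = generate_section(params)
        assert t1.vessels.to_csv() == t2.vessels.to_csv()
        for name in s1:
            np.testing.assert_array_equal(s1[name].image, s2[name].image)

    def test_too_small_section_warns_and_is_empty(self):
        params = SectionParams(analyzed_area=0.001, submeso_thickness_true=30.0)
        with pytest.warns(UserWarning, match="too small"):
            _, truth = generate_section(params, channels=())
        assert len(truth.vessels) == 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SectionParams(blood_density_true=-1.0)
        with pytest.raises(ValueError):
            SectionParams(pixel_scale=0.0)
        with pytest.raises(ValueError):
            SectionParams(denuded_fraction=1.5)
        with pytest.raises(ValueError):
            SectionParams(layer_weights=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SectionParams(blood_density_true=np.nan)


class TestLayerDepthSampling:
    def test_respects_truncation_bounds(self, rng):
        d = sample_layer_depths(2000, rng=rng, lo=25.0, hi=200.0)
        assert d.min() >= 25.0 and d.max() <= 200.0

    def test_iqr_to_sigma_is_normal_equivalent(self):
        assert iqr_to_sigma(1.349) == pytest.approx(1.0, abs=1e-3)


class TestGenerateCohort:
    def _tiny(self):
        # keep sections tiny: cohort tests exercise structure, not imaging
        return SectionParams(analyzed_area=0.02, submeso_thickness_true=230.0)

    def test_default_cohort_has_107_patients(self):
        table = default_group_table()
        patients = list(
            generate_cohort(table, seed=0, base_params=self._tiny(), channels=())
        )
        assert len(patients) == 107
        assert [p.group for p in patients[:14]] == ["<1"] * 14

    def test_single_group_single_patient(self):
        table = default_group_table().iloc[:1].assign(n=1)
        patients = list(
            generate_cohort(table, seed=0, base_params=self._tiny(), channels=())
        )
        assert len(patients) == 1

    def test_same_seed_identical_truth_tables(self):
        table = default_group_table().iloc[:2].assign(n=2)
        run = lambda: [
            p.truth.vessels.to_csv()
            for p in generate_cohort(table, seed=5, base_params=self._tiny(), channels=())
        ]
        assert run() == run()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            list(generate_cohort(default_group_table().iloc[:0]))

    def test_zero_group_size_rejected(self):
        with pytest.raises(ValueError):
            list(generate_cohort(default_group_table().assign(n=0)))


class TestEndothelialCalibration:
    def test_analytic_expectation_matches_truth_tables(self):
        params = SectionParams(analyzed_area=0.4, seed=0)
        expect = expected_endothelial_area_per_vessel(params)
        areas = []
        for seed in range(30):
            _, truth = generate_section(params.replace(seed=seed), channels=())
            v = truth.vessels
            areas.extend(np.pi * (v.r_out_um**2 - v.r_in_um**2))
        assert np.mean(areas) == pytest.approx(expect, rel=0.03)
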