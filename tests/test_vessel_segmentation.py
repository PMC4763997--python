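"""Vessel detection, dual-stain differencing, mesothelial integrity."""

import numpy as np
import pandas as pd
import pytest

from peritomorph import (
    SectionParams,
    StainSection,
    classify_by_dual_stain,
    detect_vessels,
    generate_section,
    mesothelial_integrity,
    render_annulus,
)
from peritomorph.synthetic_tissue import BACKGROUND_INTENSITY, POSITIVE_INTENSITY


def _section_from_annuli(annuli, shape=(400, 400), scale=0.25, stain="cd31"):
    """Paint analytic annuli ((x, y, r_out, r_in) in μm) on a clean canvas."""
    img = np.full(shape, BACKGROUND_INTENSITY, dtype=np.float32)
    for x, y, r_out, r_in in annuli:
        mask = render_annulus((x, y), r_out, r_in, scale, shape=shape)
        img[mask] = POSITIVE_INTENSITY
    return StainSection(img, stain, pixel_scale=scale)


class TestDetectVessels:
    def test_blank_section_yields_empty_table(self):
        sec = StainSection(np.full((100, 100), 0.1), "cd31", 0.25)
        records = detect_vessels(sec)
        assert len(records) == 0

    def test_single_annulus_metrics_match_closed_form(self):
        sec = _section_from_annuli([(50, 50, 5.0, 3.5)])
        rec = detect_vessels(sec).iloc[0]
        assert rec.endothelial_area_um2 == pytest.approx(np.pi * (25 - 12.25), rel=0.02)
        assert rec.lumen_area_um2 == pytest.approx(np.pi * 12.25, rel=0.02)
        assert rec.vessel_area_um2 == pytest.approx(np.pi * 25, rel=0.02)
        assert rec.outer_perimeter_um == pytest.approx(2 * np.pi * 5, rel=0.02)
        assert rec.endoluminal_perimeter_um == pytest.approx(2 * np.pi * 3.5, rel=0.02)
        assert not rec.collapsed

    def test_area_identity_exact_on_masks(self):
        """vessel_area == endothelial_area + lumen_area for every record."""
        annuli = [(20, 30, 5, 3.5), (60, 30, 4, 0), (40, 70, 6, 4.5)]
        records = detect_vessels(_section_from_annuli(annuli))
        assert len(records) == 3
        np.testing.assert_allclose(
            records.vessel_area_um2,
            records.endothelial_area_um2 + records.lumen_area_um2,
            rtol=0, atol=1e-9,
        )

    def test_collapsed_vessels_flagged_and_counted(self):
        """A filled disc has no distinct lumen: flagged, but still a vessel."""
        annuli = [(20, 30, 5, 3.5), (60, 30, 4, 0), (40, 70, 5, 3.5), (80, 70, 4, 0)]
        records = detect_vessels(_section_from_annuli(annuli))
        assert len(records) == 4
        assert int(records.collapsed.sum()) == 2
        assert records.loc[records.collapsed, "endothelial_thickness_um"].isna().all()

    def test_synthetic_section_detection_matches_truth(self, infant_sample):
        sections, truth = infant_sample
        records = detect_vessels(sections["cd31"], sample_id="s")
        assert len(records) == len(truth.vessels)
        assert int(records.collapsed.sum()) == int(truth.vessels.collapsed.sum())

    def test_depth_matches_ground_truth_within_one_pixel(self, infant_sample):
        sections, truth = infant_sample
        from peritomorph.synthetic_tissue import MESO_BAND_UM

        records = detect_vessels(sections["cd31"])
        got = np.sort(records.depth_um.to_numpy())
        want = np.sort(truth.vessels.depth_um.to_numpy() + MESO_BAND_UM)
        # centroid depth of a symmetric ring equals the center depth
        assert np.max(np.abs(got - want)) <= sections["cd31"].pixel_scale

    def test_doubled_noise_keeps_count_error_small(self, infant_params):
        sections, truth = generate_section(
            infant_params.replace(noise_sd=0.10, seed=99), channels=("cd31",)
        )
        records = detect_vessels(sections["cd31"])
        n_true = len(truth.vessels)
        assert abs(len(records) - n_true) <= max(0.02 * n_true, 1)

    def test_border_components_flagged_and_shape_excluded(self):
        sec = _section_from_annuli([(2.0, 50.0, 5, 3.5), (50, 50, 5, 3.5)])
        records = detect_vessels(sec)
        assert len(records) == 2
        border = records[records.border]
        assert len(border) == 1
        assert border.endothelial_area_um2.isna().all()

    def test_merged_rings_split_by_watershed(self):
        # two rings fused along a vertical tangent: one component, two lumina
        sec = _section_from_annuli([(40, 50, 5, 3.5), (49.5, 50, 5, 3.5)])
        records = detect_vessels(sec)
        assert len(records) == 2
        assert records.merged.all()
        np.testing.assert_allclose(
            sorted(records.centroid_x_um), [40, 49.5], atol=1.0
        )

    def test_min_object_area_suppresses_specks(self):
        img = np.full((100, 100), 0.1, dtype=np.float32)
        img[50, 50] = 0.9  # single hot pixel
        records = detect_vessels(StainSection(img, "cd31", 0.25))
        assert len(records) == 0

    def test_surface_margin_excludes_mesothelial_band(self, infant_sample):
        sections, truth = infant_sample
        records = detect_vessels(sections["podoplanin"], surface_margin=15.0)
        n_lymph_true = int((truth.vessels.stain_class == "lymphatic").sum())
        assert len(records) == n_lymph_true


class TestDualStain:
    def _records(self, n, sample="s"):
        return pd.DataFrame({"sample_id": [sample] * n, "depth_um": np.arange(n)})

    def test_blood_is_count_difference(self):
        out = classify_by_dual_stain(self._records(25), self._records(5))
        assert out == {"total": 25, "lymphatic": 5, "blood": 20, "clamped": False}

    def test_negative_difference_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = classify_by_dual_stain(self._records(3), self._records(5))
        assert out["blood"] == 0 and out["clamped"]

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError, match="different samples"):
            classify_by_dual_stain(self._records(3, "a"), self._records(2, "b"))

    def test_densities_when_area_given(self):
        out = classify_by_dual_stain(self._records(20), self._records(5),
                                     analyzed_area=0.1)
        assert out["blood_density"] == pytest.approx(150.0)

    def test_recovers_generator_blood_density(self, infant_sample):
        sections, truth = infant_sample
        cd31 = detect_vessels(sections["cd31"], sample_id="s")
        podo = detect_vessels(sections["podoplanin"], surface_margin=15.0, sample_id="s")
        out = classify_by_dual_stain(cd31, podo, analyzed_area=truth.analyzed_area)
        assert out["blood_density"] == pytest.approx(truth.vessel_density("blood"), rel=0.02)


class TestMesothelialIntegrity:
    def test_fully_covered_surface(self):
        img = np.full((100, 200), 0.1, dtype=np.float32)
        img[:16, :] = 0.8
        coverage, denuded = mesothelial_integrity(StainSection(img, "podoplanin", 0.25))
        assert coverage == 1.0 and not denuded

    def test_denuded_fraction_recovered_and_flagged(self):
        params = SectionParams(
            analyzed_area=0.02, denuded_fraction=0.6,
            blood_density_true=0.0, lymph_density_true=0.0, seed=4,
        )
        sections, truth = generate_section(params, channels=("podoplanin", "structural"))
        for name in ("podoplanin", "structural"):
            coverage, denuded = mesothelial_integrity(sections[name])
            assert coverage == pytest.approx(truth.coverage_fraction, abs=0.02)
            assert denuded

    def test_image_shorter_than_band_rejected(self):
        with pytest.raises(ValueError, match="surface"):
            mesothelial_integrity(StainSection(np.zeros((2, 10)), "podoplanin", 0.25))

    def test_cohort_denuded_proportion(self):
        """Samples drawn so ~21% fall below the coverage cutoff are so flagged."""
        rng = np.random.default_rng(0)
        flags = []
        for i in range(24):
            frac = 0.8 if rng.uniform() < 0.21 else 0.1  # denuded vs intact draw
            params = SectionParams(
                analyzed_area=0.01, denuded_fraction=frac,
                blood_density_true=0.0, lymph_density_true=0.0,
                mast_density_true=0.0, seed=100 + i,
            )
            sections, _ = generate_section(params, channels=("structural",))
            flags.append(mesothelial_integrity(sections["structural"])[1])
        assert abs(np.mean(flags) - 0.21) < 0.15  # binomial noise at n=24
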