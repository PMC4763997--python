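"""Per-vessel and per-sample quantitative morphometry.

Definitions follow standard microvessel-density practice for stained tissue
sections:

* **Microvessel density** — number of detected vessels (collapsed included)
  per mm² of analyzed tissue.
* **Vessel area** — endothelial area plus lumen area; the endothelial area
  is the stained ring without the lumen.
* **Endothelial thickness** — endothelial area divided by the mean ring
  length, ``(outer perimeter + endoluminal perimeter) / 2``; for a perfect
  annulus this equals ``r_out − r_in``.  Collapsed vessels have no distinct
  lumen and are excluded from all shape metrics.
* **Endothelial surface area per volume** — total endoluminal perimeter ×
  section thickness × vessel count over analyzed area × section thickness;
  the section thickness cancels algebraically, leaving Σ perimeter / area in
  μm²/μm³, and the implementation is numerically independent of it.
* **Relative endothelial area** — percentage of the analyzed tissue area
  occupied by endothelial pixels of a vessel class, collapsed vessels
  included (they are endothelium even without a lumen).

Per-sample summaries use medians across non-collapsed, non-border records,
matching the median/IQR reporting convention of reference cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .stain_quant import IntensityThresholds, StainSection, classify_pixels

__all__ = [
    "SampleMetrics",
    "microvessel_density",
    "endothelial_thickness",
    "endothelial_surface_per_volume",
    "relative_endothelial_area",
    "count_point_cells",
    "summarize_sample",
]


def microvessel_density(n_vessels: int, analyzed_area: float) -> float:
    """Vessels per mm² of analyzed area; collapsed vessels included."""
    if analyzed_area <= 0:
        raise ValueError(f"analyzed_area must be > 0, got {analyzed_area}")
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    return n_vessels / analyzed_area


def endothelial_thickness(record: pd.Series | dict) -> float:
    """Endothelial layer thickness of one non-collapsed vessel record, μm."""
    rec = record
    if rec["collapsed"]:
        raise ValueError("collapsed vessels are excluded from endothelial thickness")
    if rec.get("border", False):
        raise ValueError("border-flagged vessels are excluded from shape metrics")
    mean_ring = (rec["outer_perimeter_um"] + rec["endoluminal_perimeter_um"]) / 2.0
    if not np.isfinite(mean_ring) or mean_ring <= 0:
        raise ValueError("record has no valid perimeters")
    return float(rec["endothelial_area_um2"] / mean_ring)


def endothelial_surface_per_volume(
    perimeters_um,
    analyzed_area_um2: float,
    section_thickness_um: float | None = None,
) -> float:
    """Endothelial surface area per tissue volume, μm²/μm³.

    ``Σ perimeter / analyzed_area``: the section thickness multiplies both
    numerator and denominator of the defining ratio and cancels, so it is
    accepted only for interface completeness and never enters the value.
    """
    if analyzed_area_um2 <= 0:
        raise ValueError("analyzed_area_um2 must be > 0")
    perimeters = np.asarray(list(perimeters_um), dtype=float)
    if perimeters.size == 0:
        return 0.0
    if np.any(~np.isfinite(perimeters)) or np.any(perimeters < 0):
        raise ValueError("perimeters must be finite and non-negative")
    return float(perimeters.sum() / analyzed_area_um2)


def relative_endothelial_area(
    endothelial_pixel_area_um2: float, analyzed_area_um2: float
) -> float:
    """Endothelial pixel area as a percentage of the analyzed tissue area."""
    if analyzed_area_um2 <= 0:
        raise ValueError("analyzed_area_um2 must be > 0")
    pct = 100.0 * endothelial_pixel_area_um2 / analyzed_area_um2
    assert pct <= 100.0 + 1e-9, "endothelial area cannot exceed the analyzed area"
    return float(pct)


def count_point_cells(
    section: StainSection,
    thresholds: IntensityThresholds | None = None,
    min_cell_area: float = 5.0,
    max_cell_area: float = 100.0,
) -> float:
    """Density of point-like stained cells (e.g. tryptase⁺ mast cells), /mm².

    Counts connected positive components whose area falls in the
    ``[min_cell_area, max_cell_area]`` μm² window over the analyzed area.
    """
    labels = classify_pixels(section, thresholds)
    comp, n = ndimage.label(labels > 0, structure=np.ones((3, 3), bool))
    if n == 0:
        return 0.0
    px = section.pixel_scale**2
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1)) * px
    n_cells = int(np.count_nonzero((sizes >= min_cell_area) & (sizes <= max_cell_area)))
    return n_cells / section.analyzed_area


@dataclass
class SampleMetrics:
    """Every per-sample quantity of the morphometry report.

    Shape medians (area, perimeter, endothelial area/thickness) are per
    vessel class over non-collapsed, non-border records; densities include
    every record.  Missing stain channels leave the corresponding fields as
    NaN — absent evidence, not zero.
    """

    sample_id: str | None = None
    age: float | None = None
    analyzed_area: float = np.nan            # mm²
    total_density: float = np.nan            # /mm² (CD31)
    blood_density: float = np.nan            # /mm² (dual-stain difference)
    lymph_density: float = np.nan            # /mm² (podoplanin)
    density_clamped: bool = False
    blood_vessel_area: float = np.nan        # μm², median
    blood_perimeter: float = np.nan          # μm, median
    blood_endothelial_area: float = np.nan   # μm², median
    blood_endothelial_thickness: float = np.nan  # μm, median
    lymph_vessel_area: float = np.nan
    lymph_perimeter: float = np.nan
    lymph_endothelial_area: float = np.nan
    lymph_endothelial_thickness: float = np.nan
    blood_relative_endothelial_area: float = np.nan   # %
    lymph_relative_endothelial_area: float = np.nan   # %
    blood_surface_per_volume: float = np.nan  # μm²/μm³
    lymph_surface_per_volume: float = np.nan  # μm²/μm³
    mast_cell_density: float = np.nan        # /mm²
    submesothelial_thickness: float = np.nan  # μm
    layer_depths: tuple = (np.nan, np.nan, np.nan)  # μm
    mesothelial_coverage: float = np.nan     # fraction
    denuded: bool = False
    n_collapsed: int = 0
    n_border: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        depths = d.pop("layer_depths")
        for i, v in enumerate(depths, start=1):
            d[f"layer{i}_depth"] = v
        return d


def _class_medians(records: pd.DataFrame) -> dict:
    """Shape-metric medians over non-collapsed, non-border records."""
    ok = records[(~records["collapsed"]) & (~records["border"])]
    if len(ok) == 0:
        return dict(vessel_area=np.nan, perimeter=np.nan,
                    endothelial_area=np.nan, endothelial_thickness=np.nan)
    return dict(
        vessel_area=float(ok["vessel_area_um2"].median()),
        perimeter=float(ok["outer_perimeter_um"].median()),
        endothelial_area=float(ok["endothelial_area_um2"].median()),
        endothelial_thickness=float(ok["endothelial_thickness_um"].median()),
    )


def summarize_sample(
    cd31_records: pd.DataFrame | None = None,
    podo_records: pd.DataFrame | None = None,
    analyzed_area: float | None = None,
    sample_id: str | None = None,
    age: float | None = None,
    mast_cell_density: float | None = None,
    submesothelial_thickness: float | None = None,
    layer_depths=None,
    mesothelial_coverage: float | None = None,
    denuded: bool | None = None,
) -> SampleMetrics:
    """Aggregate one sample's records and structure measures into a row.

    CD31 shape metrics are reported under the blood class (blood capillaries
    dominate the CD31 channel and no object-level registration between the
    adjacent sections is assumed); podoplanin records provide the lymphatic
    metrics.  Densities follow the dual-stain difference when both channels
    are present.
    """
    from .vessel_segmentation import classify_by_dual_stain

    if analyzed_area is None or analyzed_area <= 0:
        raise ValueError("analyzed_area (mm², > 0) is required")
    m = SampleMetrics(sample_id=sample_id, age=age, analyzed_area=analyzed_area)
    area_um2 = analyzed_area * 1e6

    if cd31_records is not None:
        m.total_density = microvessel_density(len(cd31_records), analyzed_area)
        med = _class_medians(cd31_records)
        m.blood_vessel_area = med["vessel_area"]
        m.blood_perimeter = med["perimeter"]
        m.blood_endothelial_area = med["endothelial_area"]
        m.blood_endothelial_thickness = med["endothelial_thickness"]
        endo = cd31_records["endothelial_area_um2"].sum(skipna=True)
        m.blood_relative_endothelial_area = relative_endothelial_area(endo, area_um2)
        ok = cd31_records[(~cd31_records["collapsed"]) & (~cd31_records["border"])]
        m.blood_surface_per_volume = endothelial_surface_per_volume(
            ok["endoluminal_perimeter_um"], area_um2
        )
        m.n_collapsed += int(cd31_records["collapsed"].sum())
        m.n_border += int(cd31_records["border"].sum())

    if podo_records is not None:
        m.lymph_density = microvessel_density(len(podo_records), analyzed_area)
        med = _class_medians(podo_records)
        m.lymph_vessel_area = med["vessel_area"]
        m.lymph_perimeter = med["perimeter"]
        m.lymph_endothelial_area = med["endothelial_area"]
        m.lymph_endothelial_thickness = med["endothelial_thickness"]
        endo = podo_records["endothelial_area_um2"].sum(skipna=True)
        m.lymph_relative_endothelial_area = relative_endothelial_area(endo, area_um2)
        ok = podo_records[(~podo_records["collapsed"]) & (~podo_records["border"])]
        m.lymph_surface_per_volume = endothelial_surface_per_volume(
            ok["endoluminal_perimeter_um"], area_um2
        )
        m.n_collapsed += int(podo_records["collapsed"].sum())
        m.n_border += int(podo_records["border"].sum())

    if cd31_records is not None and podo_records is not None:
        counts = classify_by_dual_stain(cd31_records, podo_records, analyzed_area)
        m.blood_density = counts["blood_density"]
        m.density_clamped = counts["clamped"]
    elif cd31_records is not None:
        # no lymphatic channel: every CD31 vessel is attributed to blood
        m.blood_density = m.total_density

    if mast_cell_density is not None:
        m.mast_cell_density = float(mast_cell_density)
    if submesothelial_thickness is not None:
        m.submesothelial_thickness = float(submesothelial_thickness)
    if layer_depths is not None:
        m.layer_depths = tuple(float(d) for d in layer_depths)
    if mesothelial_coverage is not None:
        m.mesothelial_coverage = float(mesothelial_coverage)
    if denuded is not None:
        m.denuded = bool(denuded)
    return m
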