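"""Vessel object detection and dual-stain blood/lymphatic classification.

Vessels are defined as stain-positive endothelial rings, typically with a
lumen.  Detection runs on a classified pixel map: each connected positive
component at least ``min_object_area`` large becomes one vessel record with
its lumen recovered by hole-filling.  Components without a distinct lumen
(hole below the lumen threshold) are flagged *collapsed*: they count toward
vessel density but are excluded from shape metrics downstream.  Because
podoplanin also stains the mesothelial monolayer, lymphatic-vessel counting
masks a configurable surface margin before detection.

Blood vessels are not directly distinguishable on a CD31 section (CD31 marks
blood *and* lymphatic endothelium), so per-sample blood counts are derived by
intraindividual differencing: blood = CD31 count − podoplanin vessel count,
clamped at zero.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import perimeter_crofton
from skimage.segmentation import watershed

from .stain_quant import IntensityThresholds, StainSection, classify_pixels

__all__ = [
    "VESSEL_RECORD_COLUMNS",
    "detect_vessels",
    "classify_by_dual_stain",
    "mesothelial_integrity",
]

logger = logging.getLogger(__name__)

#: Columns of the vessel record table (one row per detected vessel).
VESSEL_RECORD_COLUMNS = [
    "id",
    "sample_id",
    "stain",
    "vessel_class",
    "centroid_x_um",
    "depth_um",
    "endothelial_area_um2",
    "lumen_area_um2",
    "vessel_area_um2",
    "outer_perimeter_um",
    "endoluminal_perimeter_um",
    "endothelial_thickness_um",
    "collapsed",
    "border",
    "merged",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity for ring components


def _empty_records() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in VESSEL_RECORD_COLUMNS})
    for c in ("sample_id", "stain", "vessel_class"):
        df[c] = df[c].astype(object)
    for c in ("collapsed", "border", "merged"):
        df[c] = df[c].astype(bool)
    df["id"] = df["id"].astype(int)
    return df


def _perimeters_um(ring: np.ndarray, lumen: np.ndarray, scale: float):
    """Digitization-corrected (Crofton, 4 directions) perimeters in μm."""
    filled = ring | lumen
    p_out = perimeter_crofton(filled, directions=4) * scale
    p_in = perimeter_crofton(lumen, directions=4) * scale if lumen.any() else 0.0
    return float(p_out), float(p_in)


def _component_record(ring, lumen, offset_rc, scale, lumen_threshold_px):
    """Measure one (sub)component; returns a dict without id/sample metadata."""
    px_area = scale * scale
    endo_area = float(ring.sum()) * px_area
    lumen_area = float(lumen.sum()) * px_area
    collapsed = lumen.sum() < lumen_threshold_px
    if collapsed:
        # a hole below the lumen threshold is not a distinct lumen
        endo_area += lumen_area
        lumen_area = 0.0
        lumen = np.zeros_like(lumen)
    filled = ring | lumen
    rows, cols = np.nonzero(filled)
    cy = (rows.mean() + 0.5 + offset_rc[0]) * scale
    cx = (cols.mean() + 0.5 + offset_rc[1]) * scale
    p_out, p_in = _perimeters_um(ring, lumen, scale)
    if collapsed or (p_out + p_in) <= 0:
        thickness = np.nan
    else:
        thickness = endo_area / ((p_out + p_in) / 2.0)
    return {
        "centroid_x_um": cx,
        "depth_um": cy,
        "endothelial_area_um2": endo_area,
        "lumen_area_um2": lumen_area,
        "vessel_area_um2": endo_area + lumen_area,
        "outer_perimeter_um": p_out,
        "endoluminal_perimeter_um": p_in,
        "endothelial_thickness_um": thickness,
        "collapsed": bool(collapsed),
    }


def _split_merged(ring, lumens_lbl, n_lumens):
    """Split a ring containing several lumina by watershed on the distance map.

    One round only: the watershed is seeded from the lumina, so rings merged
    without distinct lumina remain single objects (counted once, logged).
    Returns a list of (sub_ring, sub_lumen) boolean mask pairs.
    """
    filled = ring | (lumens_lbl > 0)
    dist = ndimage.distance_transform_edt(filled)
    labels = watershed(-dist, markers=lumens_lbl, mask=filled)
    parts = []
    for j in range(1, n_lumens + 1):
        region = labels == j
        parts.append((region & ring, region & (lumens_lbl == j)))
    return parts


def detect_vessels(
    section: StainSection,
    thresholds: IntensityThresholds | None = None,
    min_object_area: float = 12.0,
    surface_margin: float = 0.0,
    lumen_threshold_px: int = 4,
    split_merged: bool = True,
    sample_id: str | None = None,
    vessel_class: str | None = None,
) -> pd.DataFrame:
    """Detect vessel objects on a CD31 or podoplanin stained section.

    Parameters
    ----------
    section
        The stained section; the mesothelial surface is the top edge, so
        vessel depth is the centroid's vertical distance in μm.
    thresholds
        Intensity bin boundaries; any positive class counts as stain signal.
    min_object_area
        Minimum component area in μm² (suppresses noise specks; default 12,
        well below the smallest reported capillary cross-sections).
    surface_margin
        Depth in μm masked out at the surface before detection.  Use ~15 μm
        on podoplanin sections to exclude the mesothelial monolayer band.
    lumen_threshold_px
        A hole smaller than this many pixels is not a distinct lumen; the
        component is flagged collapsed.
    split_merged
        Split touching rings with several distinct lumina by one round of
        watershed on the distance transform.
    vessel_class
        Class stored on the records: defaults to ``"lymphatic"`` for
        podoplanin sections and ``"unassigned"`` otherwise (object-level
        blood/lymph classification needs the dual-stain difference).

    Returns
    -------
    pandas.DataFrame
        One row per vessel, columns :data:`VESSEL_RECORD_COLUMNS`, sorted by
        depth.  Border-touching components are flagged (``border``) and get
        NaN shape metrics but still count toward density.
    """
    labels = classify_pixels(section, thresholds)
    positive = labels > 0
    scale = section.pixel_scale
    margin_rows = int(round(surface_margin / scale))
    if margin_rows > 0:
        positive[:margin_rows, :] = False
    if vessel_class is None:
        vessel_class = "lymphatic" if section.stain.lower().startswith("podo") else "unassigned"
    if sample_id is None:
        sample_id = section.sample_id

    comp_lbl, n_comp = ndimage.label(positive, structure=_STRUCT8)
    if n_comp == 0:
        return _empty_records()
    min_px = max(int(np.ceil(min_object_area / scale**2)), 1)
    slices = ndimage.find_objects(comp_lbl)
    rows_out = []
    n_rows, n_cols = positive.shape
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        local = comp_lbl[sl] == idx
        if local.sum() < min_px:
            continue
        # pad by 1 px so hole filling sees a closed background frame
        ring = np.pad(local, 1)
        filled = ndimage.binary_fill_holes(ring)
        holes = filled & ~ring
        # 4-connectivity for holes complements the 8-connected foreground
        lumens_lbl, n_lumens = ndimage.label(holes)
        distinct = [
            j for j in range(1, n_lumens + 1)
            if (lumens_lbl == j).sum() >= lumen_threshold_px
        ]
        offset = (sl[0].start - 1, sl[1].start - 1)
        border = (
            sl[0].start == 0 or sl[1].start == 0
            or sl[0].stop == n_rows or sl[1].stop == n_cols
            or (margin_rows > 0 and sl[0].start <= margin_rows)
        )
        if split_merged and len(distinct) >= 2:
            relabel = np.zeros_like(lumens_lbl)
            for newj, oldj in enumerate(distinct, start=1):
                relabel[lumens_lbl == oldj] = newj
            parts = _split_merged(ring, relabel, len(distinct))
        else:
            parts = [(ring, holes)]
        for sub_ring, sub_lumen in parts:
            if not sub_ring.any():
                continue
            rec = _component_record(sub_ring, sub_lumen, offset, scale, lumen_threshold_px)
            rec["merged"] = bool(split_merged and len(distinct) >= 2)
            rec["border"] = bool(border)
            if border:
                for c in (
                    "endothelial_area_um2", "lumen_area_um2", "vessel_area_um2",
                    "outer_perimeter_um", "endoluminal_perimeter_um",
                    "endothelial_thickness_um",
                ):
                    rec[c] = np.nan
            rows_out.append(rec)
    if not rows_out:
        return _empty_records()
    df = pd.DataFrame(rows_out).sort_values("depth_um", kind="stable").reset_index(drop=True)
    df.insert(0, "id", np.arange(len(df)))
    df.insert(1, "sample_id", sample_id)
    df.insert(2, "stain", section.stain)
    df.insert(3, "vessel_class", vessel_class)
    n_merged = int(df["merged"].sum())
    if n_merged:
        logger.info("%d record(s) produced by splitting merged components", n_merged)
    return df[VESSEL_RECORD_COLUMNS]


def classify_by_dual_stain(
    cd31_records: pd.DataFrame,
    podo_records: pd.DataFrame,
    analyzed_area: float | None = None,
) -> dict:
    """Per-sample vessel counts from the CD31/podoplanin difference.

    ``total`` is the CD31 vessel count (CD31 stains all endothelium),
    ``lymphatic`` the podoplanin vessel count (mesothelial band already
    excluded at detection), and ``blood = max(total − lymphatic, 0)`` with a
    warning when clamping occurs.  When ``analyzed_area`` (mm²) is given the
    corresponding densities are included.
    """

    def _sample_ids(df):
        if "sample_id" in df and len(df):
            return set(df["sample_id"].dropna().unique())
        return set()

    ids_a, ids_b = _sample_ids(cd31_records), _sample_ids(podo_records)
    if ids_a and ids_b and ids_a != ids_b:
        raise ValueError(
            f"records come from different samples: {sorted(ids_a)} vs {sorted(ids_b)}"
        )
    total = int(len(cd31_records))
    lymphatic = int(len(podo_records))
    blood = total - lymphatic
    clamped = blood < 0
    if clamped:
        warnings.warn(
            f"podoplanin count ({lymphatic}) exceeds CD31 count ({total}); "
            "blood count clamped to 0",
            stacklevel=2,
        )
        blood = 0
    out = {"total": total, "lymphatic": lymphatic, "blood": blood, "clamped": clamped}
    if analyzed_area is not None:
        if analyzed_area <= 0:
            raise ValueError("analyzed_area must be > 0")
        out.update(
            total_density=total / analyzed_area,
            lymph_density=lymphatic / analyzed_area,
            blood_density=blood / analyzed_area,
        )
    return out


def mesothelial_integrity(
    section: StainSection,
    band_um: float = 6.0,
    cutoff: float = 0.5,
    thresholds: IntensityThresholds | None = None,
) -> tuple[float, bool]:
    """Fraction of the surface covered by mesothelium, plus a denuded flag.

    Works on the structural label map (mesothelium class) or on a podoplanin
    section (the stain marks mesothelial cells).  A surface column counts as
    covered when any pixel in the top ``band_um`` carries mesothelial signal.
    The sample is flagged denuded when coverage falls below ``cutoff``.
    """
    from .synthetic_tissue import LABEL_MESO  # local import avoids cycle

    scale = section.pixel_scale
    band_rows = int(round(band_um / scale))
    if band_rows < 1 or section.image.shape[0] < band_rows:
        raise ValueError("no surface band in image (image shorter than the band)")
    band = section.image[:band_rows, :]
    if section.stain == "structural":
        signal = band == LABEL_MESO
    else:
        signal = classify_pixels(band, thresholds) > 0
    coverage = float(signal.any(axis=0).mean())
    return coverage, bool(coverage < cutoff)
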