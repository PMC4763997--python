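"""End-to-end per-sample quantification: stains → vessels → metrics.

Binds the analysis stages in the order they run on a real slide set: pixel
classification and positivity, vessel detection on the CD31 and podoplanin
channels (mesothelial band masked on the latter), dual-stain differencing,
mast-cell counting, submesothelial thickness and mesothelial integrity, and
the per-sample metric summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .layer_structure import cluster_vessel_layers, measure_submesothelial_thickness
from .morphometry import SampleMetrics, count_point_cells, summarize_sample
from .stain_quant import IntensityThresholds, StainSection
from .vessel_segmentation import (
    classify_by_dual_stain,
    detect_vessels,
    mesothelial_integrity,
)

__all__ = ["quantify_sample", "PODO_SURFACE_MARGIN_UM"]

#: Surface margin masked on podoplanin sections before vessel counting;
#: excludes the mesothelial monolayer band, which podoplanin also stains.
PODO_SURFACE_MARGIN_UM = 15.0


def quantify_sample(
    sections: dict[str, StainSection],
    thresholds: IntensityThresholds | None = None,
    sample_id: str | None = None,
    age: float | None = None,
    min_object_area: float = 12.0,
    podo_surface_margin: float = PODO_SURFACE_MARGIN_UM,
    denuded_cutoff: float = 0.5,
    cluster_layers: bool = True,
    layer_k: int = 3,
) -> tuple[SampleMetrics, pd.DataFrame]:
    """Quantify one sample's section set.

    ``sections`` maps channel names (any of ``structural``, ``cd31``,
    ``podoplanin``, ``tryptase``) to sections; missing channels leave the
    corresponding metrics as NaN.  Returns the per-sample metrics and the
    concatenated vessel-record table.
    """
    if not sections:
        raise ValueError("no sections supplied")
    cd31 = sections.get("cd31")
    podo = sections.get("podoplanin")
    tryptase = sections.get("tryptase")
    structural = sections.get("structural")

    area = None
    for sec in sections.values():
        area = sec.analyzed_area
        break
    cd31_records = podo_records = None
    record_tables = []
    if cd31 is not None:
        area = cd31.analyzed_area
        cd31_records = detect_vessels(
            cd31, thresholds, min_object_area=min_object_area, sample_id=sample_id
        )
        record_tables.append(cd31_records)
    if podo is not None:
        podo_records = detect_vessels(
            podo, thresholds, min_object_area=min_object_area,
            surface_margin=podo_surface_margin, sample_id=sample_id,
        )
        record_tables.append(podo_records)

    mast_density = None
    if tryptase is not None:
        mast_density = count_point_cells(tryptase, thresholds)

    thickness = None
    coverage = denuded = None
    layer_depths = None
    if structural is not None:
        thickness = measure_submesothelial_thickness(structural)
        coverage, denuded = mesothelial_integrity(structural, cutoff=denuded_cutoff)
    elif podo is not None:
        coverage, denuded = mesothelial_integrity(podo, cutoff=denuded_cutoff)

    if cluster_layers and cd31_records is not None and len(cd31_records) >= layer_k:
        fit = cluster_vessel_layers(cd31_records["depth_um"].to_numpy(), k=layer_k)
        layer_depths = fit.layer_median_depths

    metrics = summarize_sample(
        cd31_records=cd31_records,
        podo_records=podo_records,
        analyzed_area=area,
        sample_id=sample_id,
        age=age,
        mast_cell_density=mast_density,
        submesothelial_thickness=thickness,
        layer_depths=layer_depths,
        mesothelial_coverage=coverage,
        denuded=denuded,
    )
    records = (
        pd.concat(record_tables, ignore_index=True)
        if record_tables
        else pd.DataFrame()
    )
    return metrics, records
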