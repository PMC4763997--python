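"""Readers and writers binding the pipeline stages to disk.

Sections travel as single-channel TIFF (or PNG) images with a JSON sidecar
holding the physical metadata; ground truth is JSON, tabular outputs are
CSV.  Every manifest records the seed and a hash of the configuration so
that two runs with identical configuration are byte-identical except for
timestamps.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stain_quant import StainSection
from .synthetic_tissue import GroundTruth

__all__ = [
    "write_section",
    "read_section",
    "write_truth",
    "read_truth",
    "config_hash",
    "write_manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_section(section: StainSection, path) -> Path:
    """Write a section as TIFF/PNG plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, section.image.astype(np.float32))
    elif path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.clip(section.image * 65535.0, 0, 65535).astype(np.uint16)
        Image.fromarray(arr).save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    meta = {
        "stain": section.stain,
        "pixel_scale": section.pixel_scale,
        "section_thickness": section.section_thickness,
        "analyzed_area": section.analyzed_area,
        "sample_id": section.sample_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_section(path) -> StainSection:
    """Read a section image and its JSON sidecar back into a StainSection."""
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        image = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        image = np.asarray(Image.open(path), dtype=np.float32) / 65535.0
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    return StainSection(
        image=np.asarray(image),
        stain=meta["stain"],
        pixel_scale=meta["pixel_scale"],
        section_thickness=meta.get("section_thickness", 4.0),
        analyzed_area=meta.get("analyzed_area"),
        sample_id=meta.get("sample_id"),
    )


def write_truth(truth: GroundTruth, path) -> Path:
    """Serialize ground truth (vessel table, masts, boundary, params) to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "vessels": truth.vessels.to_dict(orient="list"),
        "mast_cells": np.asarray(truth.mast_cells).tolist(),
        "thickness_profile": np.asarray(truth.thickness_profile).tolist(),
        "coverage_fraction": truth.coverage_fraction,
        "analyzed_area": truth.analyzed_area,
        "params": truth.params.to_dict(),
    }
    path.write_text(json.dumps(payload, sort_keys=True))
    return path


def read_truth(path) -> GroundTruth:
    from .synthetic_tissue import SectionParams

    payload = json.loads(Path(path).read_text())
    params = {
        k: tuple(v) if isinstance(v, list) else v for k, v in payload["params"].items()
    }
    from .synthetic_tissue import VESSEL_COLUMNS

    vessels = pd.DataFrame(payload["vessels"])
    if len(vessels):
        vessels = vessels[VESSEL_COLUMNS]
        vessels = vessels.astype(
            {c: float for c in VESSEL_COLUMNS if c.endswith("_um")}
            | {"collapsed": bool, "stain_class": str}
        )
    return GroundTruth(
        vessels=vessels,
        mast_cells=np.asarray(payload["mast_cells"], dtype=float).reshape(-1, 2),
        thickness_profile=np.asarray(payload["thickness_profile"], dtype=float),
        coverage_fraction=payload["coverage_fraction"],
        analyzed_area=payload["analyzed_area"],
        params=SectionParams(**params),
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(out_dir, config: dict, seed: int, files: list, extra: dict | None = None):
    """Write the run manifest (seed, config hash, file checksums)."""
    from . import __version__

    out_dir = Path(out_dir)
    checksums = {}
    for f in sorted(map(str, files)):
        p = Path(f)
        checksums[str(p.relative_to(out_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "files": checksums,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
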