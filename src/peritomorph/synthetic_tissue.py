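"""Seeded synthetic peritoneal tissue sections with known ground truth.

The study conditions this package analyzes — peritoneal biopsies dual-stained
for CD31 (all vessel endothelium), podoplanin (lymphatic endothelium plus the
mesothelial monolayer) and tryptase (mast cells) — are emulated here as
single-channel intensity images with a fully known ground truth, so that the
analysis pipeline can be validated as a parameter-recovery experiment.

Geometry
--------
Sections are oriented with the mesothelial surface along the top row; depth is
the vertical distance below the surface in μm, coordinates are 0-based and
row-major.  The image canvas holds, top to bottom: a thin mesothelial band,
the submesothelial connective-tissue zone whose lower boundary undulates
around the true submesothelial thickness, and the lower boundary tissue
(fat / muscle / fascia).  Vessels are placed by a Poisson point process whose
depth marginal is a three-component mixture — the three submesothelial vessel
layers — truncated to the submesothelium.  Overlapping vessel cross-sections
are re-sampled (up to 100 attempts) so that objects stay separable; merging
behavior of the segmenter is tested separately with constructed inputs.

Intensity model
---------------
Stain-positive objects are drawn at intensity 0.8 on a 0.1 background with
additive Gaussian noise (default sd 0.05); the default thresholds of
:mod:`peritomorph.stain_quant` are calibrated to this model.  The structural
channel is a noise-free label map (`LABEL_MESO`, `LABEL_SUBMESO`,
`LABEL_BOUNDARY`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .stain_quant import StainSection

__all__ = [
    "SectionParams",
    "GroundTruth",
    "VirtualPatient",
    "DegenerateMaskWarning",
    "render_annulus",
    "generate_section",
    "generate_cohort",
    "sample_layer_depths",
    "default_group_table",
    "expected_endothelial_area_per_vessel",
    "params_for_endothelial_fraction",
    "iqr_to_sigma",
    "AGE_GROUP_LABELS",
]

# --- intensity / label constants -------------------------------------------

BACKGROUND_INTENSITY = 0.1
POSITIVE_INTENSITY = 0.8
LABEL_BACKGROUND = np.float32(0.0)
LABEL_SUBMESO = np.float32(0.4)
LABEL_BOUNDARY = np.float32(0.7)
LABEL_MESO = np.float32(1.0)

MESO_BAND_UM = 4.0  # rendered mesothelial monolayer thickness, μm

#: IQR of a normal distribution equals 1.349 σ; the study reports median/IQR
#: only, so IQR-scale dispersions are converted with this factor.
IQR_TO_SIGMA = 1.0 / 1.349

AGE_GROUP_LABELS = ("<1", "1-<2", "2-<7", "7-<12", "12-<18", "18-40", "41-60")


def iqr_to_sigma(iqr: float) -> float:
    """Normal-equivalent standard deviation for a reported IQR."""
    return float(iqr) * IQR_TO_SIGMA


class DegenerateMaskWarning(UserWarning):
    """Raised when a rasterized object is near or below one pixel."""


# --- parameters -------------------------------------------------------------


@dataclass
class SectionParams:
    """Generator-side counterparts of every measured quantity.

    Defaults are the parietal-peritoneum infant (<1 year) condition: blood
    capillary density 223/mm², lymphatic density 58/mm², endothelial wall
    1.29 μm, submesothelial thickness 230 μm, vessel layers at 36/96/192 μm
    with IQR-scale dispersions 20/65/133 μm, denuded-surface fraction 0.21,
    mast cells 12.9/mm², analyzed area 1.44 mm² scanned at 0.25 μm/px (a 40×
    whole-slide scan).
    """

    analyzed_area: float = 1.44          # mm²
    pixel_scale: float = 0.25            # μm/px
    section_thickness: float = 4.0       # μm
    blood_density_true: float = 223.0    # vessels/mm²
    lymph_density_true: float = 58.0     # vessels/mm²
    layer_depths: tuple[float, float, float] = (36.0, 96.0, 192.0)    # μm medians
    layer_iqrs: tuple[float, float, float] = (20.0, 65.0, 133.0)      # μm IQR scale
    layer_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    vessel_radius_mean: float = 4.5      # μm, outer radius
    vessel_radius_sd: float = 0.8        # μm
    wall_thickness_true: float = 1.29    # μm (median; per-vessel lognormal jitter)
    wall_jitter_sd: float = 0.15         # lognormal sigma; median-preserving
    collapsed_fraction: float = 0.10
    submeso_thickness_true: float = 230.0  # μm
    boundary_roughness: float = 0.08     # relative amplitude of boundary undulation
    denuded_fraction: float = 0.21
    mast_density_true: float = 12.9      # cells/mm²
    mast_cell_radius: float = 2.5        # μm
    noise_sd: float = 0.05               # additive Gaussian intensity noise
    min_depth: float = 20.0              # μm; vessels kept below the mesothelial zone
    margin_below: float = 40.0           # μm of lower boundary tissue on the canvas
    seed: int = 0

    def __post_init__(self) -> None:
        scalars = {
            "analyzed_area": self.analyzed_area,
            "pixel_scale": self.pixel_scale,
            "section_thickness": self.section_thickness,
            "blood_density_true": self.blood_density_true,
            "lymph_density_true": self.lymph_density_true,
            "vessel_radius_mean": self.vessel_radius_mean,
            "wall_thickness_true": self.wall_thickness_true,
            "submeso_thickness_true": self.submeso_thickness_true,
            "mast_density_true": self.mast_density_true,
            "noise_sd": self.noise_sd,
        }
        for name, value in scalars.items():
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        if self.analyzed_area <= 0:
            raise ValueError("analyzed_area must be > 0")
        for name in ("blood_density_true", "lymph_density_true", "mast_density_true"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("collapsed_fraction", "denuded_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.layer_weights) - 1.0) > 1e-9 or min(self.layer_weights) < 0:
            raise ValueError(f"layer_weights must be a simplex, got {self.layer_weights}")
        if self.wall_thickness_true <= 0 or self.wall_thickness_true >= self.vessel_radius_mean:
            raise ValueError("wall_thickness_true must be in (0, vessel_radius_mean)")

    @property
    def layer_sigmas(self) -> tuple[float, ...]:
        return tuple(iqr_to_sigma(i) for i in self.layer_iqrs)

    def replace(self, **kwargs) -> "SectionParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class GroundTruth:
    """Per-object truth channel for parameter-recovery tests.

    ``vessels`` has one row per vessel with columns ``x_um`` (horizontal
    center), ``depth_um`` (center depth below the surface), ``r_out_um``,
    ``r_in_um`` (0 for collapsed cross-sections), ``wall_um``,
    ``stain_class`` (``blood``/``lymphatic``) and ``collapsed``.
    """

    vessels: pd.DataFrame
    mast_cells: np.ndarray                # (n, 2) [x_um, depth_um]
    thickness_profile: np.ndarray         # submesothelial thickness per column, μm
    coverage_fraction: float              # true mesothelial coverage
    analyzed_area: float                  # mm², exact pixel-grid area
    params: SectionParams

    def vessel_density(self, stain_class: str | None = None) -> float:
        """Ground-truth vessel count per mm² of analyzed area."""
        v = self.vessels
        if stain_class is not None:
            v = v[v["stain_class"] == stain_class]
        return len(v) / self.analyzed_area

    def endothelial_area_fraction(self, stain_class: str | None = None) -> float:
        """Analytic endothelial (ring or full disc) area fraction of the section."""
        v = self.vessels
        if stain_class is not None:
            v = v[v["stain_class"] == stain_class]
        area_um2 = np.pi * (v["r_out_um"] ** 2 - v["r_in_um"] ** 2)
        return float(area_um2.sum() / (self.analyzed_area * 1e6))


VESSEL_COLUMNS = ["x_um", "depth_um", "r_out_um", "r_in_um", "wall_um", "stain_class", "collapsed"]


def _empty_vessels() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": pd.Series(dtype=float),
            "depth_um": pd.Series(dtype=float),
            "r_out_um": pd.Series(dtype=float),
            "r_in_um": pd.Series(dtype=float),
            "wall_um": pd.Series(dtype=float),
            "stain_class": pd.Series(dtype=str),
            "collapsed": pd.Series(dtype=bool),
        }
    )


# --- rasterization ----------------------------------------------------------


def render_annulus(
    center: tuple[float, float],
    outer_radius: float,
    inner_radius: float,
    pixel_scale: float,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Rasterize an annulus (ring) as a boolean pixel mask.

    ``center`` is ``(x_um, depth_um)`` in physical coordinates; a pixel
    belongs to the mask when its center lies within ``[inner_radius,
    outer_radius]`` of the annulus center, so the mask area converges to
    π(r_out² − r_in²) as ``pixel_scale`` → 0.  ``inner_radius`` 0 renders a
    filled disc — the collapsed-vessel phenotype.

    When ``shape`` is omitted the mask covers a minimal local canvas with
    the annulus centered; otherwise it covers the full ``shape`` canvas with
    pixel centers at ``(index + 0.5) * pixel_scale``.
    """
    if not (np.isfinite(outer_radius) and np.isfinite(inner_radius)):
        raise ValueError("radii must be finite")
    if inner_radius < 0 or outer_radius <= inner_radius:
        raise ValueError(
            f"need outer_radius > inner_radius >= 0, got {outer_radius}, {inner_radius}"
        )
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be > 0")
    if outer_radius < pixel_scale or (outer_radius - inner_radius) < pixel_scale:
        warnings.warn(
            f"annulus (r_out={outer_radius}, r_in={inner_radius}) is below one pixel "
            f"at {pixel_scale} μm/px; mask may be degenerate",
            DegenerateMaskWarning,
            stacklevel=2,
        )
    s = pixel_scale
    if shape is None:
        n = int(np.ceil(2 * (outer_radius + s) / s)) + 1
        shape = (n, n)
        center = (n * s / 2.0, n * s / 2.0)
    cx, cy = float(center[0]), float(center[1])
    r0 = max(int(np.floor((cy - outer_radius) / s - 1)), 0)
    r1 = min(int(np.ceil((cy + outer_radius) / s + 1)), shape[0])
    c0 = max(int(np.floor((cx - outer_radius) / s - 1)), 0)
    c1 = min(int(np.ceil((cx + outer_radius) / s + 1)), shape[1])
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    yy = (np.arange(r0, r1, dtype=np.float64) + 0.5) * s - cy
    xx = (np.arange(c0, c1, dtype=np.float64) + 0.5) * s - cx
    d2 = yy[:, None] ** 2 + xx[None, :] ** 2
    mask[r0:r1, c0:c1] = (d2 <= outer_radius**2) & (d2 >= inner_radius**2)
    return mask


def _paint_annulus(canvas, center, r_out, r_in, pixel_scale, value):
    """Paint an annulus directly onto a full canvas (fast path, no checks)."""
    s = pixel_scale
    cx, cy = center
    r0 = max(int((cy - r_out) / s - 1), 0)
    r1 = min(int((cy + r_out) / s + 2), canvas.shape[0])
    c0 = max(int((cx - r_out) / s - 1), 0)
    c1 = min(int((cx + r_out) / s + 2), canvas.shape[1])
    if r1 <= r0 or c1 <= c0:
        return
    yy = (np.arange(r0, r1, dtype=np.float64) + 0.5) * s - cy
    xx = (np.arange(c0, c1, dtype=np.float64) + 0.5) * s - cx
    d2 = yy[:, None] ** 2 + xx[None, :] ** 2
    sel = (d2 <= r_out**2) & (d2 >= r_in**2)
    sub = canvas[r0:r1, c0:c1]
    sub[sel] = value


# --- sampling helpers -------------------------------------------------------


def sample_layer_depths(
    n: int,
    medians=(36.0, 96.0, 192.0),
    iqrs=(20.0, 65.0, 133.0),
    weights=(1 / 3, 1 / 3, 1 / 3),
    rng: np.random.Generator | int | None = None,
    lo: float = 0.0,
    hi: float = np.inf,
) -> np.ndarray:
    """Draw vessel depths from the three-layer mixture, truncated to [lo, hi].

    Components are normal with the given medians and IQR-derived sigmas
    (σ = IQR/1.349).  Used both by the section generator and directly by the
    layer-recovery experiments.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    medians = np.asarray(medians, float)
    sigmas = np.asarray([iqr_to_sigma(i) for i in iqrs])
    if hi <= lo:
        raise ValueError(f"empty depth interval [{lo}, {hi}]")
    comp = rng.choice(len(medians), size=n, p=np.asarray(weights) / np.sum(weights))
    a = (lo - medians[comp]) / sigmas[comp]
    b = (hi - medians[comp]) / sigmas[comp]
    # inverse-CDF truncated normal draw, vectorized and reproducible
    u = rng.uniform(size=n)
    depths = truncnorm.ppf(u, a, b, loc=medians[comp], scale=sigmas[comp])
    return depths


def _sample_radii(n, params, rng):
    lo = max(2.5, params.wall_thickness_true + 0.5)
    a = (lo - params.vessel_radius_mean) / params.vessel_radius_sd
    u = rng.uniform(size=n)
    return truncnorm.ppf(
        u, a, np.inf, loc=params.vessel_radius_mean, scale=params.vessel_radius_sd
    )


def _place_vessels(params, n_blood, n_lymph, width_um, rng, gap_um=2.0, max_attempts=100):
    """Poisson-process placement with overlap re-sampling.

    Returns the vessel ground-truth table.  Depths are drawn from the
    three-layer mixture truncated to the submesothelium, keeping whole
    cross-sections below the mesothelial zone and above the lower boundary.
    """
    n_total = n_blood + n_lymph
    if n_total == 0:
        return _empty_vessels()
    classes = np.array(["blood"] * n_blood + ["lymphatic"] * n_lymph)
    r_out = _sample_radii(n_total, params, rng)
    collapsed = rng.uniform(size=n_total) < params.collapsed_fraction
    wall = params.wall_thickness_true * np.exp(rng.normal(0.0, params.wall_jitter_sd, n_total))
    wall = np.minimum(wall, r_out - 0.5)
    r_in = np.where(collapsed, 0.0, r_out - wall)

    t_min = params.submeso_thickness_true * (1.0 - params.boundary_roughness)
    xs = np.empty(n_total)
    ds = np.empty(n_total)
    placed_x: list[float] = []
    placed_d: list[float] = []
    placed_r: list[float] = []
    n_collisions = 0
    for i in range(n_total):
        r = r_out[i]
        lo_d = params.min_depth + r
        hi_d = max(t_min - r, lo_d + 1e-6)
        lo_x, hi_x = r + gap_um, max(width_um - r - gap_um, r + gap_um + 1e-6)
        for attempt in range(max_attempts):
            d = sample_layer_depths(
                1, params.layer_depths, params.layer_iqrs, params.layer_weights,
                rng, lo=lo_d, hi=hi_d,
            )[0]
            x = rng.uniform(lo_x, hi_x)
            if placed_x:
                dist2 = (np.array(placed_x) - x) ** 2 + (np.array(placed_d) - d) ** 2
                min_sep = (np.array(placed_r) + r + gap_um) ** 2
                if np.any(dist2 < min_sep):
                    continue
            break
        else:
            n_collisions += 1
        xs[i] = x
        ds[i] = d
        placed_x.append(x)
        placed_d.append(d)
        placed_r.append(r)
    if n_collisions:
        warnings.warn(
            f"{n_collisions} vessel(s) placed with residual overlap after "
            f"{max_attempts} attempts",
            stacklevel=3,
        )
    order = np.argsort(ds, kind="stable")
    return pd.DataFrame(
        {
            "x_um": xs[order],
            "depth_um": ds[order],
            "r_out_um": r_out[order],
            "r_in_um": r_in[order],
            "wall_um": wall[order],
            "stain_class": classes[order],
            "collapsed": collapsed[order],
        }
    ).reset_index(drop=True)


def _coverage_intervals(width_um, denuded_fraction, rng):
    """One contiguous denuded stretch at a random position; returns (lo, hi)."""
    if denuded_fraction <= 0:
        return None
    if denuded_fraction >= 1:
        return (0.0, width_um)
    gap = denuded_fraction * width_um
    start = rng.uniform(0.0, width_um - gap)
    return (start, start + gap)


ALL_CHANNELS = ("structural", "cd31", "podoplanin", "tryptase")


def generate_section(
    params: SectionParams,
    channels: tuple[str, ...] = ALL_CHANNELS,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, StainSection], GroundTruth]:
    """Generate one synthetic tissue section and its ground truth.

    Returns ``(sections, truth)`` where ``sections`` maps channel name to
    :class:`~peritomorph.stain_quant.StainSection`.  The CD31 channel marks
    all vessels (annuli; collapsed ones as filled discs), the podoplanin
    channel marks lymphatic vessels plus the mesothelial monolayer band, the
    tryptase channel marks mast cells, and the structural channel is a
    noise-free tissue-class label map.  Output is reproducible for a fixed
    ``params.seed`` (or caller-supplied ``rng``).
    """
    unknown = set(channels) - set(ALL_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    s = params.pixel_scale
    height_um = (
        MESO_BAND_UM
        + params.submeso_thickness_true * (1.0 + params.boundary_roughness)
        + params.margin_below
    )
    width_um = params.analyzed_area * 1e6 / height_um
    n_rows = max(int(round(height_um / s)), 1)
    n_cols = max(int(round(width_um / s)), 1)
    width_um = n_cols * s
    analyzed_area = n_rows * n_cols * s**2 / 1e6  # exact pixel-grid area, mm²

    r_max = params.vessel_radius_mean + 3 * params.vessel_radius_sd
    too_small = (
        width_um < 2 * (r_max + 2.0)
        or params.submeso_thickness_true * (1 - params.boundary_roughness)
        < params.min_depth + 2 * r_max
    )
    if too_small and (params.blood_density_true > 0 or params.lymph_density_true > 0):
        warnings.warn(
            "section too small to hold a single vessel; returning empty truth",
            stacklevel=2,
        )
        n_blood = n_lymph = 0
    else:
        n_blood = rng.poisson(params.blood_density_true * analyzed_area)
        n_lymph = rng.poisson(params.lymph_density_true * analyzed_area)

    vessels = _place_vessels(params, int(n_blood), int(n_lymph), width_um, rng)

    # mesothelial coverage and submesothelial boundary profile
    denuded = _coverage_intervals(width_um, params.denuded_fraction, rng)
    col_x = (np.arange(n_cols) + 0.5) * s
    covered = np.ones(n_cols, dtype=bool)
    if denuded is not None:
        covered &= ~((col_x >= denuded[0]) & (col_x < denuded[1]))
    coverage_fraction = float(covered.mean())

    n_cycles = rng.uniform(1.0, 3.0)
    phase = rng.uniform(0.0, 2 * np.pi)
    thickness_profile = params.submeso_thickness_true * (
        1.0 + params.boundary_roughness * np.sin(2 * np.pi * n_cycles * col_x / width_um + phase)
    )

    n_mast = rng.poisson(params.mast_density_true * analyzed_area)
    mast_lo = MESO_BAND_UM + params.mast_cell_radius + 1.0
    mast_hi = max(height_um - params.mast_cell_radius - 1.0, mast_lo + 1e-6)
    mast_cells = np.column_stack(
        [
            rng.uniform(params.mast_cell_radius + 1.0,
                        width_um - params.mast_cell_radius - 1.0, n_mast),
            rng.uniform(mast_lo, mast_hi, n_mast),
        ]
    ) if n_mast > 0 else np.empty((0, 2))

    truth = GroundTruth(
        vessels=vessels,
        mast_cells=mast_cells,
        thickness_profile=thickness_profile.astype(np.float64),
        coverage_fraction=coverage_fraction,
        analyzed_area=analyzed_area,
        params=params,
    )

    meso_rows = max(int(round(MESO_BAND_UM / s)), 1)
    sections: dict[str, StainSection] = {}

    def _stain_canvas():
        return np.full((n_rows, n_cols), BACKGROUND_INTENSITY, dtype=np.float32)

    def _finalize(canvas, stain):
        if params.noise_sd > 0:
            canvas += rng.standard_normal(canvas.shape, dtype=np.float32) * np.float32(
                params.noise_sd
            )
            np.clip(canvas, 0.0, 1.0, out=canvas)
        return StainSection(
            image=canvas,
            stain=stain,
            pixel_scale=s,
            section_thickness=params.section_thickness,
            analyzed_area=analyzed_area,
        )

    # vessel centers sit below the mesothelial band
    vdepth = vessels["depth_um"].to_numpy() + MESO_BAND_UM

    for channel in ALL_CHANNELS:  # fixed order keeps the RNG stream stable
        if channel not in channels:
            continue
        if channel == "structural":
            canvas = np.full((n_rows, n_cols), LABEL_SUBMESO, dtype=np.float32)
            canvas[:meso_rows, covered] = LABEL_MESO
            boundary_rows = np.round((MESO_BAND_UM + thickness_profile) / s).astype(int)
            boundary_rows = np.clip(boundary_rows, meso_rows, n_rows)
            row_idx = np.arange(n_rows)[:, None]
            canvas[row_idx >= boundary_rows[None, :]] = LABEL_BOUNDARY
            sections[channel] = StainSection(
                image=canvas, stain="structural", pixel_scale=s,
                section_thickness=params.section_thickness, analyzed_area=analyzed_area,
            )
        elif channel == "cd31":
            canvas = _stain_canvas()
            for x, d, ro, ri in zip(
                vessels["x_um"], vdepth, vessels["r_out_um"], vessels["r_in_um"]
            ):
                _paint_annulus(canvas, (x, d), ro, ri, s, POSITIVE_INTENSITY)
            sections[channel] = _finalize(canvas, "cd31")
        elif channel == "podoplanin":
            canvas = _stain_canvas()
            canvas[:meso_rows, covered] = POSITIVE_INTENSITY
            lymph = vessels["stain_class"] == "lymphatic"
            for x, d, ro, ri in zip(
                vessels.loc[lymph, "x_um"], vdepth[lymph.to_numpy()],
                vessels.loc[lymph, "r_out_um"], vessels.loc[lymph, "r_in_um"],
            ):
                _paint_annulus(canvas, (x, d), ro, ri, s, POSITIVE_INTENSITY)
            sections[channel] = _finalize(canvas, "podoplanin")
        elif channel == "tryptase":
            canvas = _stain_canvas()
            for x, d in mast_cells:
                _paint_annulus(canvas, (x, d), params.mast_cell_radius, 0.0, s,
                               POSITIVE_INTENSITY)
            sections[channel] = _finalize(canvas, "tryptase")
    return sections, truth


# --- cohort -----------------------------------------------------------------

# Printed group medians; submesothelial thickness is printed only for <1 y
# (230 μm), 7-12 y (402 μm) and adults (173 μm) — intermediate groups are
# monotone interpolations used as generator defaults.
_GROUP_DEFAULTS = {
    "group": list(AGE_GROUP_LABELS),
    "n": [14, 10, 15, 15, 18, 21, 14],
    "age_lo": [0.08, 1.0, 2.0, 7.0, 12.0, 18.0, 41.0],
    "age_hi": [1.0, 2.0, 7.0, 12.0, 18.0, 40.0, 60.0],
    "blood_density": [223.0, 89.0, 76.0, 35.0, 89.0, 106.0, 172.0],
    "blood_density_iqr": [106.0, 43.0, 32.0, 41.0, 85.0, 51.0, 113.0],
    "lymph_density": [58.0, 37.0, 33.0, 39.0, 12.0, 44.0, 19.0],
    "lymph_density_iqr": [35.0, 6.0, 23.0, 14.0, 19.0, 32.0, 20.0],
    "wall_thickness": [1.29, 1.12, 1.45, 1.95, 1.48, 1.21, 1.17],
    "submeso_thickness": [230.0, 280.0, 340.0, 402.0, 300.0, 220.0, 173.0],
    "submeso_thickness_iqr": [60.0, 110.0, 140.0, 168.0, 150.0, 140.0, 146.0],
}


def default_group_table() -> pd.DataFrame:
    """Default seven-group cohort design (ages, sizes, per-group medians)."""
    return pd.DataFrame(_GROUP_DEFAULTS)


def _lognormal_sigma_from_iqr_ratio(ratio: float) -> float:
    """Lognormal sigma whose IQR/median equals ``ratio``.

    For Y = median·exp(σZ): IQR/median = exp(0.6745σ) − exp(−0.6745σ)
    = 2·sinh(0.6745σ).
    """
    return float(np.arcsinh(ratio / 2.0) / 0.6745)


@dataclass
class VirtualPatient:
    sample_id: str
    group: str
    age: float
    params: SectionParams
    sections: dict[str, StainSection]
    truth: GroundTruth


def generate_cohort(
    group_table: pd.DataFrame | None = None,
    seed: int = 0,
    base_params: SectionParams | None = None,
    channels: tuple[str, ...] = ALL_CHANNELS,
    patient_variation: bool = True,
    depth_coupling_sd: float = 0.5,
):
    """Yield one synthetic section set per virtual patient.

    Per-patient parameters are the group medians of ``group_table`` (default:
    the seven printed age groups) with median-preserving lognormal
    inter-patient variation scaled from the printed IQRs.  Layer depths are
    coupled to each patient's submesothelial thickness (proportional scaling
    with lognormal noise, sd ``depth_coupling_sd``), which reproduces the
    strong depth-thickness rank correlation seen across real samples.

    This is a generator function: sections are yielded one patient at a time
    so a full-resolution cohort never has to be resident in memory.
    Deterministic for a fixed ``seed``.
    """
    if group_table is None:
        group_table = default_group_table()
    if len(group_table) == 0:
        raise ValueError("empty group table")
    if (group_table["n"] < 1).any():
        raise ValueError("group sizes must be >= 1")
    if base_params is None:
        base_params = SectionParams()

    root = np.random.SeedSequence(seed)
    patient_seeds = root.spawn(int(group_table["n"].sum()))
    i_patient = 0
    for _, row in group_table.iterrows():
        for _ in range(int(row["n"])):
            rng = np.random.default_rng(patient_seeds[i_patient])
            age = float(rng.uniform(row["age_lo"], row["age_hi"]))
            blood = float(row["blood_density"])
            lymph = float(row["lymph_density"])
            thick = float(row["submeso_thickness"])
            if patient_variation:
                for name, med, iqr in (
                    ("blood", blood, row.get("blood_density_iqr", blood * 0.45)),
                    ("lymph", lymph, row.get("lymph_density_iqr", lymph * 0.45)),
                    ("thick", thick, row.get("submeso_thickness_iqr", thick * 0.4)),
                ):
                    sig = _lognormal_sigma_from_iqr_ratio(float(iqr) / med) if med > 0 else 0.0
                    scale = float(np.exp(rng.normal(0.0, sig)))
                    if name == "blood":
                        blood = med * scale
                    elif name == "lymph":
                        lymph = med * scale
                    else:
                        thick = med * scale
            depth_scale = (thick / float(row["submeso_thickness"])) * np.exp(
                rng.normal(0.0, depth_coupling_sd)
            )
            depths = tuple(float(d * depth_scale) for d in base_params.layer_depths)
            iqrs = tuple(float(i * depth_scale) for i in base_params.layer_iqrs)
            params = base_params.replace(
                blood_density_true=blood,
                lymph_density_true=lymph,
                submeso_thickness_true=thick,
                wall_thickness_true=float(row.get("wall_thickness",
                                                  base_params.wall_thickness_true)),
                layer_depths=depths,
                layer_iqrs=iqrs,
            )
            sections, truth = generate_section(params, channels=channels, rng=rng)
            yield VirtualPatient(
                sample_id=f"sample_{i_patient:04d}",
                group=str(row["group"]),
                age=age,
                params=params,
                sections=sections,
                truth=truth,
            )
            i_patient += 1


# --- calibration helpers ----------------------------------------------------


def expected_endothelial_area_per_vessel(params: SectionParams) -> float:
    """Analytic expected endothelial pixel area per vessel, μm².

    Rings contribute π(2·E[r]·E[w] − E[w²]) (exact, since the ring area is
    linear in the outer radius for fixed wall); collapsed discs contribute
    the full π·E[r²].  Radius moments are taken from the truncated-normal
    sampling distribution, wall moments from the lognormal jitter.
    """
    lo = max(2.5, params.wall_thickness_true + 0.5)
    a = (lo - params.vessel_radius_mean) / params.vessel_radius_sd
    dist = truncnorm(a, np.inf, loc=params.vessel_radius_mean, scale=params.vessel_radius_sd)
    m1, m2 = dist.moment(1), dist.moment(2)
    w1 = params.wall_thickness_true * np.exp(params.wall_jitter_sd**2 / 2)
    w2 = params.wall_thickness_true**2 * np.exp(2 * params.wall_jitter_sd**2)
    ring = np.pi * (2 * m1 * w1 - w2)
    disc = np.pi * m2
    cf = params.collapsed_fraction
    return float((1 - cf) * ring + cf * disc)


def params_for_endothelial_fraction(
    fraction_percent: float, base: SectionParams | None = None
) -> SectionParams:
    """Section parameters whose expected endothelial area fraction is given.

    Sets the blood density (lymphatics off) so that density × expected
    endothelial area per vessel equals ``fraction_percent`` of the analyzed
    area.  Used to pose relative-endothelial-area recovery experiments.
    """
    if base is None:
        base = SectionParams()
    base = base.replace(lymph_density_true=0.0)
    per_vessel = expected_endothelial_area_per_vessel(base)
    density = fraction_percent / 100.0 * 1e6 / per_vessel  # vessels per mm²
    return base.replace(blood_density_true=float(density))
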