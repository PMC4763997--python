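"""Pixel-level stain classification and the positivity statistic.

Immunohistochemistry quantification commonly reports *positivity*: the
fraction of analyzed pixels whose stain intensity exceeds a calibrated
threshold, with positive pixels further binned into weak / medium / strong
classes.  This module re-implements that workflow for single-channel
intensity images on [0, 1]: a :class:`StainSection` wraps the image together
with its physical metadata, :func:`classify_pixels` bins every pixel, and
:func:`positivity` computes the positive-pixel fraction.

Default thresholds are calibrated to the synthetic intensity model used by
:mod:`peritomorph.synthetic_tissue` (background 0.1, positive objects 0.8);
real stains require per-stain calibration, which is why the thresholds are
an explicit, validated parameter rather than a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StainSection",
    "IntensityThresholds",
    "PixelClass",
    "classify_pixels",
    "positivity",
]


class PixelClass:
    """Integer codes of the pixel label map."""

    NEGATIVE = 0
    WEAK = 1
    MEDIUM = 2
    STRONG = 3


@dataclass
class StainSection:
    """A single-stain intensity image plus physical metadata.

    Parameters
    ----------
    image
        2-D float array with intensities on [0, 1].  For the structural
        (HE-like) channel the values are discrete tissue-class codes rather
        than stain intensities.
    stain
        Stain name, e.g. ``"cd31"``, ``"podoplanin"``, ``"tryptase"`` or
        ``"structural"``.
    pixel_scale
        Physical pixel edge length in μm/px.
    section_thickness
        Histological section thickness in μm.  Cancels out of every derived
        quantity but is carried for completeness.
    analyzed_area
        Foreground tissue area in mm²; defaults to the full image area.
    sample_id
        Optional identifier tying adjacent sections of one sample together.
    """

    image: np.ndarray
    stain: str
    pixel_scale: float
    section_thickness: float = 4.0
    analyzed_area: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.image.shape}")
        if not np.isfinite(self.pixel_scale) or self.pixel_scale <= 0:
            raise ValueError(f"pixel_scale must be positive, got {self.pixel_scale}")
        full_area = self.image.size * self.pixel_scale**2 / 1e6
        if self.analyzed_area is None:
            self.analyzed_area = full_area
        elif self.analyzed_area > full_area * (1 + 1e-9):
            raise ValueError(
                f"analyzed_area {self.analyzed_area} mm² exceeds image area {full_area:.4g} mm²"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def with_image(self, image: np.ndarray) -> "StainSection":
        return replace(self, image=image)


@dataclass(frozen=True)
class IntensityThresholds:
    """Strictly increasing bin boundaries for negative/weak/medium/strong.

    A pixel with intensity ``v`` is negative when ``v < negative_max``, weak
    on ``[negative_max, weak_max)``, medium on ``[weak_max, medium_max)`` and
    strong at or above ``medium_max``.
    """

    negative_max: float = 0.3
    weak_max: float = 0.5
    medium_max: float = 0.7

    def __post_init__(self) -> None:
        b = (self.negative_max, self.weak_max, self.medium_max)
        if not all(np.isfinite(b)):
            raise ValueError(f"thresholds must be finite, got {b}")
        if not (b[0] < b[1] < b[2]):
            raise ValueError(f"thresholds must be strictly increasing, got {b}")

    @property
    def boundaries(self) -> tuple[float, float, float]:
        return (self.negative_max, self.weak_max, self.medium_max)


def classify_pixels(
    section: StainSection | np.ndarray,
    thresholds: IntensityThresholds | None = None,
) -> np.ndarray:
    """Bin every pixel into negative/weak/medium/strong intensity classes.

    Returns a ``uint8`` label map of the same shape as the input, with codes
    from :class:`PixelClass`.  NaN pixels are rejected with a location
    report because a silent NaN→negative coercion would bias positivity.
    """
    image = section.image if isinstance(section, StainSection) else np.asarray(section)
    if thresholds is None:
        thresholds = IntensityThresholds()
    bad = ~np.isfinite(image)
    if bad.any():
        rows, cols = np.nonzero(bad)
        head = ", ".join(f"({r}, {c})" for r, c in zip(rows[:5], cols[:5]))
        raise ValueError(
            f"{bad.sum()} non-finite pixel(s), first at {head}"
        )
    labels = np.searchsorted(np.asarray(thresholds.boundaries), image, side="right")
    return labels.astype(np.uint8)


def positivity(label_map: np.ndarray) -> float:
    """Positive-pixel fraction: (weak + medium + strong) / all pixels."""
    label_map = np.asarray(label_map)
    if label_map.size == 0:
        raise ValueError("empty label map")
    return float(np.count_nonzero(label_map) / label_map.size)
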