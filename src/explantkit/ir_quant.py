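"""DAB immunoreactivity quantification inside drawn ROIs.

Brightfield sections stained with the brown DAB chromogen are quantified
in two steps: (1) pixels are classified as DAB-positive when they lie in
the include-minus-exclude ROI and their RGB value is within a Euclidean
tolerance of one of a set of trained brown reference shades; (2) the mean
immunoreactivity (IR) of the positive pixels is reported on a 0 (no
staining) to 255 (saturation) scale, with per-pixel
``IR = 255 - round(0.299 R + 0.587 G + 0.114 B)``.

The reference-shade classifier mirrors the shade-training workflow of
interactive histology software; stain-vector deconvolution would be an
alternative but is deliberately not used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask

from ._color import ir_to_rgb, pixel_ir

__all__ = [
    "ReferenceShades",
    "RegionOfInterest",
    "IRResult",
    "default_reference_shades",
    "classify_positive",
    "mean_ir",
    "quantify_panel",
]


@dataclass(frozen=True)
class ReferenceShades:
    """Trained brown shades plus the maximal RGB distance to count a pixel
    as stained."""

    shades: np.ndarray  # (k, 3) float RGB
    tolerance: float = 40.0

    def __post_init__(self) -> None:
        shades = np.atleast_2d(np.asarray(self.shades, dtype=float))
        if shades.shape[0] < 1 or shades.shape[1] != 3:
            raise ValueError("need at least one RGB reference shade")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        object.__setattr__(self, "shades", shades)


def default_reference_shades(tolerance: float = 40.0) -> ReferenceShades:
    """Brown ramp covering light to saturated DAB staining (IR 60–240)."""
    levels = np.arange(60.0, 241.0, 30.0)
    return ReferenceShades(np.array([ir_to_rgb(v) for v in levels]), tolerance)


@dataclass
class RegionOfInterest:
    """Include polygon(s) minus exclusion polygon(s); vertices are (row, col)."""

    include: list[np.ndarray]
    exclude: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.include:
            raise ValueError("ROI needs at least one include polygon")
        self.include = [np.asarray(p, dtype=float) for p in self.include]
        self.exclude = [np.asarray(p, dtype=float) for p in self.exclude]

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for poly in self.include:
            mask |= polygon2mask(shape, poly)
        for poly in self.exclude:
            if np.any(poly < 0) or np.any(poly[:, 0] > shape[0]) or np.any(poly[:, 1] > shape[1]):
                raise ValueError("exclusion polygon outside image bounds")
            mask &= ~polygon2mask(shape, poly)
        return mask


@dataclass(frozen=True)
class IRResult:
    positive_area: float  # µm² if calibrated, else px²
    positive_fraction: float
    mean_ir: float
    flag: str = "none"  # none | no_positive_pixels


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(
            "expected an RGB image of shape (rows, cols, 3); "
            "grayscale input is not supported — convert to RGB first"
        )
    return image.astype(float)


def classify_positive(
    image: np.ndarray,
    shades: ReferenceShades,
    roi: RegionOfInterest,
) -> np.ndarray:
    """Boolean mask of DAB-positive pixels inside the effective ROI."""
    img = _check_rgb(image)
    roi_mask = roi.rasterize(img.shape[:2])
    min_dist = np.full(img.shape[:2], np.inf)
    for shade in shades.shades:
        d = np.sqrt(np.sum((img - shade[None, None, :]) ** 2, axis=-1))
        np.minimum(min_dist, d, out=min_dist)
    return roi_mask & (min_dist < shades.tolerance)


def mean_ir(
    image: np.ndarray,
    mask: np.ndarray,
    roi_mask: Optional[np.ndarray] = None,
    pixel_size_um: Optional[float] = None,
) -> IRResult:
    """Mean IR over the positive pixels of ``mask``.

    The per-pixel luminance is rounded to the nearest integer before the
    float mean is taken. An empty mask reports ``mean_ir = 0`` with the
    ``no_positive_pixels`` flag rather than a NaN.
    """
    img = _check_rgb(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape does not match image")
    n_pos = int(mask.sum())
    unit = pixel_size_um**2 if pixel_size_um else 1.0
    area = n_pos * unit
    denom = int(roi_mask.sum()) if roi_mask is not None else mask.size
    frac = n_pos / denom if denom else 0.0
    if n_pos == 0:
        return IRResult(area, frac, 0.0, flag="no_positive_pixels")
    ir = float(pixel_ir(img[mask]).mean())
    return IRResult(area, frac, ir, flag="none")


def quantify_panel(
    entries: Sequence[dict],
    shades: Optional[ReferenceShades] = None,
    pixel_size_um: Optional[float] = None,
) -> pd.DataFrame:
    """Quantify a panel of sections; one output row per ROI.

    Each entry is a dict with keys ``image`` (RGB array), ``roi``
    (:class:`RegionOfInterest` or None) and any label columns (group,
    turn, replicate ...), which are passed through. An entry with a
    missing ROI yields a flagged row (``missing_roi``), never a dropped
    one.
    """
    if not entries:
        raise ValueError("panel needs at least one entry")
    shades = shades or default_reference_shades()
    rows = []
    for entry in entries:
        labels = {k: v for k, v in entry.items() if k not in ("image", "roi")}
        roi = entry.get("roi")
        if roi is None:
            rows.append(
                {
                    **labels,
                    "positive_area": np.nan,
                    "positive_fraction": np.nan,
                    "mean_ir": np.nan,
                    "flag": "missing_roi",
                }
            )
            continue
        img = entry["image"]
        mask = classify_positive(img, shades, roi)
        res = mean_ir(img, mask, roi_mask=roi.rasterize(np.asarray(img).shape[:2]),
                      pixel_size_um=pixel_size_um)
        rows.append(
            {
                **labels,
                "positive_area": res.positive_area,
                "positive_fraction": res.positive_fraction,
                "mean_ir": res.mean_ir,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(rows)
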