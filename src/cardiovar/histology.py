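"""Picrosirius-red collagen quantification.

The fibrotic-area percentage is the count of red (collagen-stained)
pixels divided by the count of tissue pixels.  "Tissue" is everything
that is not near-white background; "red" is an HSV hue window wrapping
around 0 degrees with a saturation floor.  The original acquisition
macro is unpublished, so the thresholds here are tuned on the synthetic
generator and exposed for configuration; absolute percentages are only
meaningful relative to a fixed threshold set.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, Union

import numpy as np
from skimage import color, morphology

from .core import PipelineError, ValidationError


class NoTissueError(PipelineError):
    """Raised when an image contains no detectable tissue."""


@dataclass(frozen=True)
class StainThresholds:
    """HSV thresholds classifying background and red collagen pixels."""

    hue_lo_deg: float = 330.0       # red window lower edge (wraps past 360)
    hue_hi_deg: float = 25.0        # red window upper edge
    sat_min: float = 0.30
    val_min: float = 0.15
    val_max: float = 0.95
    background_val_min: float = 0.90    # near-white: bright ...
    background_sat_max: float = 0.20    # ... and unsaturated

    def __post_init__(self):
        for name in ("hue_lo_deg", "hue_hi_deg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 360.0):
                raise ValidationError(f"{name} must lie in [0, 360]")


DEFAULT_THRESHOLDS = StainThresholds()


@dataclass
class CollagenQuantification:
    tissue_px: int
    collagen_px: int

    @property
    def fibrotic_pct(self) -> float:
        return 100.0 * self.collagen_px / self.tissue_px

    def __post_init__(self):
        if not (0 <= self.collagen_px <= self.tissue_px):
            raise ValidationError("need 0 <= collagen_px <= tissue_px")


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValidationError("expected an RGB image (H x W x 3)")
    if image.dtype != np.uint8:
        if np.issubdtype(image.dtype, np.floating) and image.max() <= 1.0:
            image = (image * 255).astype(np.uint8)
        else:
            image = np.clip(image, 0, 255).astype(np.uint8)
    return image[:, :, :3]


def segment_tissue(
    image: np.ndarray,
    thresholds: StainThresholds = DEFAULT_THRESHOLDS,
    min_hole_px: int = 100,
    min_object_px: int = 100,
) -> np.ndarray:
    """Boolean mask of tissue (non-background) pixels.

    Background is near-white (high value, low saturation).  Specks
    smaller than ``min_object_px`` are dropped and holes smaller than
    ``min_hole_px`` filled.
    """
    image = _check_rgb(image)
    hsv = color.rgb2hsv(image)
    background = (hsv[:, :, 2] >= thresholds.background_val_min) & (
        hsv[:, :, 1] <= thresholds.background_sat_max
    )
    mask = ~background
    if mask.any():
        mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
        mask = morphology.remove_small_holes(mask, max_size=min_hole_px - 1)
    if not mask.any():
        raise NoTissueError("no tissue detected (image is entirely background)")
    return mask


def quantify_collagen(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    thresholds: StainThresholds = DEFAULT_THRESHOLDS,
) -> CollagenQuantification:
    """Count red-stained pixels inside the tissue mask."""
    image = _check_rgb(image)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != image.shape[:2]:
        raise ValidationError("tissue mask shape does not match the image")
    if not tissue_mask.any():
        raise ValidationError("tissue mask is empty")

    hsv = color.rgb2hsv(image)
    hue_deg = hsv[:, :, 0] * 360.0
    lo, hi = thresholds.hue_lo_deg, thresholds.hue_hi_deg
    if lo <= hi:
        in_hue = (hue_deg >= lo) & (hue_deg <= hi)
    else:  # window wraps through 0 degrees
        in_hue = (hue_deg >= lo) | (hue_deg <= hi)
    red = (
        in_hue
        & (hsv[:, :, 1] >= thresholds.sat_min)
        & (hsv[:, :, 2] >= thresholds.val_min)
        & (hsv[:, :, 2] <= thresholds.val_max)
    )
    return CollagenQuantification(
        tissue_px=int(tissue_mask.sum()),
        collagen_px=int((red & tissue_mask).sum()),
    )


def quantify_image(
    image: np.ndarray,
    thresholds: StainThresholds = DEFAULT_THRESHOLDS,
    total_area: str = "tissue",
) -> CollagenQuantification:
    """Segment then quantify one image.

    ``total_area`` selects the denominator: the tissue mask (default) or
    the full frame (``"frame"``).
    """
    mask = segment_tissue(image, thresholds)
    q = quantify_collagen(image, mask, thresholds)
    if total_area == "frame":
        return CollagenQuantification(tissue_px=int(mask.size),
                                      collagen_px=q.collagen_px)
    if total_area != "tissue":
        raise ValidationError("total_area must be 'tissue' or 'frame'")
    return q


def quantify_directory(
    directory: Union[str, os.PathLike],
    thresholds: StainThresholds = DEFAULT_THRESHOLDS,
    extensions: Iterable[str] = (".png", ".tif", ".tiff"),
) -> "pd.DataFrame":
    """Batch quantification of every stained image in a directory."""
    import imageio.v3 as iio
    import pandas as pd

    rows: list[Dict] = []
    for name in sorted(os.listdir(directory)):
        if os.path.splitext(name)[1].lower() not in extensions:
            continue
        img = iio.imread(os.path.join(directory, name))
        q = quantify_image(img, thresholds)
        rows.append(dict(file=name, tissue_px=q.tissue_px,
                         collagen_px=q.collagen_px, fibrotic_pct=q.fibrotic_pct))
    if not rows:
        raise ValidationError(f"no stained-section images found in {directory}")
    return pd.DataFrame(rows)
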