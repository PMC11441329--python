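"""Confocal synapse-level quantification.

The presynaptic marker (synapsin) channel is thresholded with Otsu's
method, contiguous supra-threshold pixels are grouped into components, and
components smaller than an area floor (default 0.05 μm², boundary
inclusive) are discarded.  The mean intensity of the protein of interest is
then measured inside each retained ROI on the raw image, and images are
summarized as the unweighted mean over their ROI means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .stack import ImageStack

#: ROI area floor in μm²; components at exactly the floor are retained.
DEFAULT_MIN_AREA_UM2 = 0.05


@dataclass
class SegmentationMask:
    """Binary foreground mask plus the threshold that produced it."""

    mask: np.ndarray
    source_role: str
    threshold: float
    pixel_size_nm: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold over an ``nbins``-bin histogram spanning [min, max].

    Pixels strictly above the returned value are foreground (pixels exactly
    at the threshold are background).  A constant image is degenerate.
    """
    values = np.asarray(values)
    if values.size == 0 or np.min(values) == np.max(values):
        raise DegenerateInputError("Otsu threshold undefined for a constant image")
    return float(threshold_otsu(values, nbins=nbins))


def segment_channel(
    stack: ImageStack, role: str = "synapsin", nbins: int = 256
) -> SegmentationMask:
    """Otsu-segment one channel of a stack (per image, as acquired)."""
    img = stack.channel(role)
    t = otsu_threshold(img, nbins=nbins)
    return SegmentationMask(
        mask=img > t, source_role=role, threshold=t, pixel_size_nm=stack.pixel_size_nm
    )


def label_components(mask, connectivity: int = 8):
    """Label maximal connected foreground sets.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent,
    the default).  Labels are assigned in raster order, so labeling is
    deterministic.  Returns ``(labels, n_components)``.
    """
    if isinstance(mask, SegmentationMask):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    elif connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    else:
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = ndimage.label(mask, structure=structure)
    return labels, int(n)


def min_retained_pixels(min_area_um2: float, pixel_size_nm: float) -> int:
    """Smallest pixel count whose area reaches the floor (14.194 nm pixels
    and a 0.05 μm² floor give 249 px)."""
    area_px_um2 = (pixel_size_nm / 1000.0) ** 2
    return int(np.ceil(min_area_um2 / area_px_um2 - 1e-9))


def filter_min_area(
    labels: np.ndarray,
    n_components: int,
    pixel_size_nm: float,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> pd.DataFrame:
    """ROI table of components whose area is at least ``min_area_um2``.

    Columns: ``label``, ``pixel_count``, ``area_um2``.  The boundary is
    inclusive ("at least").
    """
    if pixel_size_nm <= 0:
        raise ValidationError("pixel_size_nm must be > 0")
    area_px_um2 = (pixel_size_nm / 1000.0) ** 2
    if n_components == 0:
        return pd.DataFrame(columns=["label", "pixel_count", "area_um2"])
    counts = np.bincount(labels.ravel(), minlength=n_components + 1)[1:]
    areas = counts * area_px_um2
    keep = areas >= min_area_um2 - 1e-12
    return pd.DataFrame(
        {
            "label": np.arange(1, n_components + 1)[keep],
            "pixel_count": counts[keep].astype(int),
            "area_um2": areas[keep],
        }
    ).reset_index(drop=True)


def measure_rois(
    roi_table: pd.DataFrame,
    labels: np.ndarray,
    stack: ImageStack,
    channels=("channel_of_interest",),
) -> pd.DataFrame:
    """Append per-ROI mean intensities of the requested channels.

    Means are taken over exactly the ROI's pixels on the raw image (no
    background subtraction)."""
    out = roi_table.copy()
    for role in channels:
        img = stack.channel(role)  # raises ConfigurationError if absent
        if len(out) == 0:
            out[f"mean_{role}"] = pd.Series(dtype=float)
            continue
        out[f"mean_{role}"] = ndimage.mean(img, labels=labels, index=out["label"].to_numpy())
    return out


def image_summary(roi_table: pd.DataFrame, image_id=None) -> dict:
    """Per-image summary: ROI count and the unweighted mean over ROI means
    for every measured channel.  With zero ROIs the summary is flagged and
    its means are NaN."""
    mean_cols = [c for c in roi_table.columns if c.startswith("mean_")]
    n = len(roi_table)
    out = {"image_id": image_id, "n_rois": n, "degenerate": n == 0}
    for c in mean_cols:
        out[c] = float(roi_table[c].mean()) if n else float("nan")
    return out


def quantify_image(
    stack: ImageStack,
    *,
    measure_channels=("channel_of_interest",),
    marker_role: str = "synapsin",
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    connectivity: int = 8,
    image_id=None,
):
    """Full confocal quantification of one image: segment the marker,
    label, area-filter, measure.  Returns ``(roi_table, summary, mask)``."""
    seg = segment_channel(stack, role=marker_role)
    labels, n = label_components(seg, connectivity=connectivity)
    table = filter_min_area(labels, n, stack.pixel_size_nm, min_area_um2=min_area_um2)
    table = measure_rois(table, labels, stack, channels=measure_channels)
    return table, image_summary(table, image_id=image_id), seg
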