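"""Somatic expression quantification.

A somatic ROI is a donut: the soma outline (outer edge of the NeuN signal,
neurites excluded) minus the EGFP-labeled nucleus, clipped to the soma.
The per-cell readout is the mean raw intensity of the HA channel over the
donut pixels.

Somata are usually drawn by hand; this module consumes polygon annotations
(even-odd rasterization at pixel centers, which sit at integer-index
physical coordinates) and also offers an automated surrogate (Otsu on NeuN
and on the nucleus channel, largest component each) so synthetic fields can
be quantified end-to-end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .errors import DegenerateInputError, FormatError, ValidationError
from .roiquant import label_components, segment_channel
from .stack import ImageStack


@dataclass
class SomaAnnotation:
    """One cell's soma and nucleus regions, as polygons (N×2 arrays of
    (x, y) in nm) or as boolean masks."""

    cell_id: str
    soma: object
    nucleus: object


def _rasterize(region, shape, pixel_size_nm) -> np.ndarray:
    """Region -> boolean mask.  Polygons include a pixel iff its center is
    inside under the even-odd rule."""
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.shape != tuple(shape):
            raise ValidationError("mask shape mismatch")
        return region
    poly = np.asarray(region, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValidationError("polygon must be an (N>=3, 2) array of (x, y) nm")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel() * pixel_size_nm, yy.ravel() * pixel_size_nm])
    path = MplPath(poly, closed=True)
    inside = path.contains_points(pts)
    return inside.reshape(h, w)


def build_donut_mask(soma, nucleus, shape, pixel_size_nm) -> np.ndarray:
    """Donut = soma minus (soma ∩ nucleus); an empty donut (nucleus covers
    the soma, or an empty soma) is a degenerate ROI."""
    soma_mask = _rasterize(soma, shape, pixel_size_nm)
    nuc_mask = _rasterize(nucleus, shape, pixel_size_nm)
    donut = soma_mask & ~(soma_mask & nuc_mask)
    if not donut.any():
        raise DegenerateInputError("empty donut ROI (nucleus covers the soma?)")
    return donut


def measure_soma(stack: ImageStack, donut: np.ndarray,
                 channel: str = "channel_of_interest") -> float:
    """Mean raw intensity of ``channel`` over the donut pixels."""
    img = stack.channel(channel)
    if donut.shape != img.shape:
        raise ValidationError("donut mask shape mismatch")
    if not donut.any():
        raise DegenerateInputError("empty donut ROI")
    return float(img[donut].mean())


def quantify_somata(stack: ImageStack, annotations) -> pd.DataFrame:
    """Per-cell HA means for a list of :class:`SomaAnnotation`."""
    rows = []
    for a in annotations:
        donut = build_donut_mask(a.soma, a.nucleus, stack.shape, stack.pixel_size_nm)
        rows.append(
            {
                "cell_id": a.cell_id,
                "donut_px": int(donut.sum()),
                "mean_channel_of_interest": measure_soma(stack, donut),
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "donut_px", "mean_channel_of_interest"])


def auto_soma_annotation(stack: ImageStack, cell_id: str = "cell1") -> SomaAnnotation:
    """Automated surrogate for manual drawing: Otsu on the NeuN channel
    (largest component = soma) and on the nucleus channel (largest
    component = nucleus).  Intended for single-soma synthetic fields."""
    masks = {}
    for role in ("neun", "nucleus"):
        seg = segment_channel(stack, role=role)
        labels, n = label_components(seg, connectivity=8)
        if n == 0:
            raise DegenerateInputError(f"no {role} component found")
        counts = np.bincount(labels.ravel())[1:]
        masks[role] = labels == (int(np.argmax(counts)) + 1)
    return SomaAnnotation(cell_id=cell_id, soma=masks["neun"], nucleus=masks["nucleus"])


# -- annotation files -------------------------------------------------------


def write_soma_annotations(annotations, path) -> Path:
    """Polygon annotations as JSON (masks are not serialized)."""
    path = Path(path)
    recs = []
    for a in annotations:
        soma = np.asarray(a.soma, dtype=float)
        nuc = np.asarray(a.nucleus, dtype=float)
        recs.append(
            {"cell_id": a.cell_id, "soma_xy_nm": soma.tolist(), "nucleus_xy_nm": nuc.tolist()}
        )
    path.write_text(json.dumps(recs, indent=1))
    return path


def read_soma_annotations(path):
    recs = json.loads(Path(path).read_text())
    out = []
    for r in recs:
        for key in ("cell_id", "soma_xy_nm", "nucleus_xy_nm"):
            if key not in r:
                raise FormatError(f"soma annotation missing {key!r}")
        out.append(
            SomaAnnotation(
                cell_id=str(r["cell_id"]),
                soma=np.asarray(r["soma_xy_nm"], dtype=float),
                nucleus=np.asarray(r["nucleus_xy_nm"], dtype=float),
            )
        )
    return out
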