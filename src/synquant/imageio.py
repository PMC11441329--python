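"""Read/write the image, annotation, and result formats the pipeline touches.

Images travel as multi-page TIFF (one page per channel) with a sidecar JSON
carrying the pixel size and per-channel role/modality.  The pixel size is
resolved in a strict order — sidecar JSON, then TIFF resolution tags, then
an explicit override — and a conflict between sidecar and tags is an error:
silent unit mistakes are the dominant failure mode of nm-calibrated profile
analyses, so the reader fails loudly rather than guessing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, MetadataError, ValidationError
from .stack import ImageStack

_ANNOT_REQUIRED = ("synapse_id", "anchor_x_nm", "anchor_y_nm", "axis_angle_rad", "accepted")


@dataclass
class SideViewAnnotation:
    """A manually (or automatically) selected side-view synapse: an anchor
    point on the PSD structure, the PSD elongation axis, and whether the
    synapse was accepted for analysis."""

    synapse_id: str
    anchor_nm: tuple
    axis_angle_rad: float
    accepted: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.axis_angle_rad < math.pi):
            raise ValidationError(
                f"axis_angle_rad must lie in [0, pi); got {self.axis_angle_rad}"
            )
        if self.anchor_nm[0] < 0 or self.anchor_nm[1] < 0:
            raise ValidationError("anchor coordinates must be nonnegative")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a multi-page TIFF (one page per channel) plus a sidecar JSON
    with pixel size and channel roles/modalities.  Lossless for any dtype
    tifffile can store (integer data round-trips exactly)."""
    path = Path(path)
    tifffile.imwrite(path, stack.pixels, photometric="minisblack")
    sidecar = {
        "pixel_size_nm": float(stack.pixel_size_nm),
        "channels": [
            {"role": r, "modality": m}
            for r, m in zip(stack.roles, stack.modalities)
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _pixel_size_from_tags(tif: tifffile.TiffFile):
    """Pixel size (nm) from XResolution/ResolutionUnit tags, if present."""
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value  # 2=inch, 3=cm
    per_unit = num / den
    unit_nm = {2: 25.4e6, 3: 1.0e7}.get(int(unit))
    if unit_nm is None:
        return None
    return unit_nm / per_unit


def read_stack(path, *, sidecar=None, pixel_size_nm=None, channels=None) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Channel roles/modalities come from the sidecar JSON (default:
    ``<path>.json``) or the ``channels`` argument (list of ``(role,
    modality)``); the pixel size from the sidecar, the TIFF resolution
    tags, or the ``pixel_size_nm`` override, in that order.  Missing pixel
    size raises :class:`MetadataError`; a channel-count mismatch raises
    :class:`FormatError`.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tag_px = _pixel_size_from_tags(tif)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a 2-D multi-page TIFF, got shape {data.shape}")

    side = None
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sidecar.exists():
        side = json.loads(sidecar.read_text())

    if side is not None and "pixel_size_nm" in side:
        px = float(side["pixel_size_nm"])
        if tag_px is not None and abs(tag_px - px) > 1e-3 * px:
            raise MetadataError(
                f"pixel size conflict: sidecar says {px} nm, TIFF tags say "
                f"{tag_px:.4f} nm"
            )
    elif tag_px is not None:
        px = float(tag_px)
    elif pixel_size_nm is not None:
        px = float(pixel_size_nm)
    else:
        raise MetadataError(
            f"{path}: no pixel size in sidecar or TIFF tags and no override given"
        )

    if channels is not None:
        roles = tuple(r for r, _ in channels)
        modalities = tuple(m for _, m in channels)
    elif side is not None and "channels" in side:
        roles = tuple(c["role"] for c in side["channels"])
        modalities = tuple(c["modality"] for c in side["channels"])
    else:
        raise MetadataError(f"{path}: channel roles unresolvable (no sidecar/override)")

    if len(roles) != data.shape[0]:
        raise FormatError(
            f"{path}: file has {data.shape[0]} channels but {len(roles)} roles declared"
        )
    return ImageStack(
        pixels=np.asarray(data, dtype=float),
        roles=roles,
        modalities=modalities,
        pixel_size_nm=px,
    )


# ---------------------------------------------------------------------------
# side-view annotations
# ---------------------------------------------------------------------------


def write_annotations(annotations, path) -> Path:
    """Write annotations to CSV (or JSON if the suffix is ``.json``);
    unknown extra columns are preserved."""
    path = Path(path)
    rows = []
    for a in annotations:
        rows.append(
            {
                "synapse_id": a.synapse_id,
                "anchor_x_nm": a.anchor_nm[0],
                "anchor_y_nm": a.anchor_nm[1],
                "axis_angle_rad": a.axis_angle_rad,
                "accepted": bool(a.accepted),
                **a.extra,
            }
        )
    df = pd.DataFrame(rows, columns=list(_ANNOT_REQUIRED) + sorted(
        {k for r in rows for k in r} - set(_ANNOT_REQUIRED)
    ))
    if path.suffix == ".json":
        path.write_text(df.to_json(orient="records", indent=1))
    else:
        df.to_csv(path, index=False)
    return path


def read_annotations(path):
    """Read side-view annotations from CSV/JSON; missing required columns
    raise :class:`FormatError`, invalid values :class:`ValidationError`.
    An empty file yields an empty list."""
    path = Path(path)
    if path.suffix == ".json":
        text = path.read_text().strip()
        df = pd.read_json(path, orient="records") if text not in ("", "[]") else pd.DataFrame()
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame()
    if df.empty and len(df.columns) == 0:
        return []
    missing = [c for c in _ANNOT_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    extras = [c for c in df.columns if c not in _ANNOT_REQUIRED]
    out = []
    for _, row in df.iterrows():
        out.append(
            SideViewAnnotation(
                synapse_id=str(row["synapse_id"]),
                anchor_nm=(float(row["anchor_x_nm"]), float(row["anchor_y_nm"])),
                axis_angle_rad=float(row["axis_angle_rad"]),
                accepted=bool(row["accepted"]),
                extra={c: row[c] for c in extras},
            )
        )
    return out
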