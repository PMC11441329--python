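"""STED side-view line-profile analysis.

For each side-view synapse — one whose elongated PSD-95 bar lies at the
edge of a synapsin vesicle cloud — a ~1000 nm long, 200 nm wide rectangular
ROI is drawn perpendicular to and across the center of the PSD-95
structure.  Intensity profiles along the trans-synaptic axis are computed
for the protein of interest and PSD-95 (mean across the 200 nm width,
bilinear sampling, one sample per pixel of physical length).  The PSD-95
profile alone is smoothed with a 5-pixel rolling average; its maximum
defines position 0; profiles are aligned to that peak, averaged across
synapses, and the per-synapse peak of the protein of interest is read out
inside a 200 nm window around the PSD-95 peak.

Negative positions are the presynaptic side, determined per synapse by
which side of the PSD axis carries more synapsin signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    BoundaryError,
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
    ValidationError,
)
from .roiquant import label_components, otsu_threshold, segment_channel
from .stack import ImageStack

DEFAULT_LENGTH_NM = 1000.0
DEFAULT_WIDTH_NM = 200.0
DEFAULT_WINDOW_NM = 200.0
DEFAULT_SMOOTH_PX = 5
DEFAULT_MIN_ELONGATION = 2.0
DEFAULT_ADJACENCY_NM = 150.0


@dataclass
class SideViewSynapse:
    """A detected (or annotated) side-view synapse."""

    synapse_id: str
    anchor_nm: tuple  # PSD center
    axis_angle_rad: float  # PSD elongation axis, [0, pi)
    elongation: float = float("nan")
    synapsin_adjacent: bool = True

    def __post_init__(self):
        if not (0.0 <= self.axis_angle_rad < math.pi):
            raise ValidationError("axis_angle_rad must lie in [0, pi)")
        if not math.isnan(self.elongation) and self.elongation < 1.0:
            raise ValidationError("elongation is major/minor and must be >= 1")


@dataclass
class IntensityProfile:
    """Per-channel intensity versus signed position (nm) along the
    trans-synaptic axis; positions are an increasing uniform grid centered
    on the extraction anchor, negative side presynaptic."""

    positions_nm: np.ndarray
    values: dict  # role -> 1-D array
    synapse_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        d = np.diff(self.positions_nm)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValidationError("positions must be strictly increasing and uniform")
        for role, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.positions_nm.shape:
                raise ValidationError(f"channel {role!r} length mismatch")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"channel {role!r} has non-finite values")
            self.values[role] = v

    @property
    def step_nm(self) -> float:
        return float(self.positions_nm[1] - self.positions_nm[0])


@dataclass
class AlignedProfileSet:
    """Profiles on a common grid with 0 at each member's smoothed PSD-95
    peak, plus per-position mean and SEM per channel.  Member arrays hold
    NaN where a synapse does not cover a position."""

    positions_nm: np.ndarray
    members: dict  # role -> 2-D array (n_synapses, n_positions) with NaN padding
    mean: dict  # role -> 1-D array
    sem: dict  # role -> 1-D array
    synapse_ids: list

    @property
    def n_synapses(self) -> int:
        return len(self.synapse_ids)


@dataclass
class PeakMeasurement:
    """Maximum of a profile restricted to a window around the PSD-95 peak."""

    synapse_id: str
    channel: str
    peak_value: float
    peak_position_nm: float
    window_nm: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _component_axis(rows, cols):
    """Principal axis (angle in [0, pi), x along columns) and elongation
    (sqrt of second-moment eigenvalue ratio) of a pixel set."""
    x = cols - cols.mean()
    y = rows - rows.mean()
    # +1/12 per-pixel variance keeps 1-px-wide bars non-degenerate
    cxx = np.mean(x * x) + 1.0 / 12.0
    cyy = np.mean(y * y) + 1.0 / 12.0
    cxy = np.mean(x * y)
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, 1]  # eigenvector of the larger eigenvalue
    angle = math.atan2(major[1], major[0]) % math.pi
    elongation = math.sqrt(evals[1] / evals[0]) if evals[0] > 0 else float("inf")
    return angle, elongation


def detect_side_view_synapses(
    stack: ImageStack,
    min_elongation: float = DEFAULT_MIN_ELONGATION,
    adjacency_radius_nm: float = DEFAULT_ADJACENCY_NM,
    min_pixels: int = 8,
):
    """Automated surrogate for manual side-view selection.

    The PSD-95 channel is Otsu-segmented and each connected component is
    kept if (a) its second-moment elongation reaches ``min_elongation`` and
    (b) it lies within ``adjacency_radius_nm`` of the Otsu synapsin mask —
    an elongated PSD bar at the edge of a vesicle cloud.
    """
    if not stack.has_role("psd95") or not stack.has_role("synapsin"):
        raise ConfigurationError("detection needs 'psd95' and 'synapsin' channels")
    px = stack.pixel_size_nm
    psd = stack.channel("psd95")
    try:
        seg = segment_channel(stack, role="psd95")
    except DegenerateInputError:
        return []
    labels, n = label_components(seg, connectivity=8)
    if n == 0:
        return []
    try:
        syn_mask = segment_channel(stack, role="synapsin").mask
    except DegenerateInputError:
        syn_mask = np.zeros_like(psd, dtype=bool)
    # distance (px) from every pixel to the nearest synapsin-mask pixel
    if syn_mask.any():
        dist_px = ndimage.distance_transform_edt(~syn_mask)
    else:
        dist_px = np.full(psd.shape, np.inf)

    out = []
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        rows, cols = np.nonzero(labels[sl] == lab)
        if len(rows) < min_pixels:
            continue
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        angle, elong = _component_axis(rows.astype(float), cols.astype(float))
        if elong < min_elongation:
            continue
        adjacent = float(dist_px[rows, cols].min()) * px <= adjacency_radius_nm
        if not adjacent:
            continue
        out.append(
            SideViewSynapse(
                synapse_id=f"syn{lab:04d}",
                anchor_nm=(float(cols.mean() * px), float(rows.mean() * px)),
                axis_angle_rad=angle,
                elongation=elong,
                synapsin_adjacent=True,
            )
        )
    return out


def synapses_from_annotations(annotations):
    """Accepted annotations as :class:`SideViewSynapse` objects (the
    annotation-driven analysis mode)."""
    return [
        SideViewSynapse(
            synapse_id=a.synapse_id,
            anchor_nm=a.anchor_nm,
            axis_angle_rad=a.axis_angle_rad,
        )
        for a in annotations
        if a.accepted
    ]


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_profile(
    stack: ImageStack,
    synapse: SideViewSynapse,
    length_nm: float = DEFAULT_LENGTH_NM,
    width_nm: float = DEFAULT_WIDTH_NM,
    channels=None,
) -> IntensityProfile:
    """Sample the rotated rectangular ROI into per-channel 1-D profiles.

    The long axis (length ``length_nm``) runs perpendicular to the PSD
    elongation axis through the anchor; the short axis (``width_nm``) runs
    along the PSD.  Sampling uses bilinear interpolation on a grid with one
    step per pixel in both directions; the profile value at each position
    is the mean across the width.  The sign of the position axis is chosen
    so that the synapsin-heavier side is negative (presynaptic).
    """
    if channels is None:
        channels = [r for r in stack.roles]
    px = stack.pixel_size_nm
    n_len = int(round(length_nm / px)) + 1
    n_wid = max(1, int(round(width_nm / px)) + 1)
    p = (np.arange(n_len) - (n_len - 1) / 2.0) * px
    wgrid = (np.arange(n_wid) - (n_wid - 1) / 2.0) * px

    ax, ay = synapse.anchor_nm
    theta = synapse.axis_angle_rad
    dx, dy = math.cos(theta), math.sin(theta)  # along the PSD axis (width)
    nx, ny = math.sin(theta), -math.cos(theta)  # trans-synaptic axis (length)

    X = ax + np.outer(p, [nx] * n_wid) + np.outer([1.0] * n_len, wgrid * dx)
    Y = ay + np.outer(p, [ny] * n_wid) + np.outer([1.0] * n_len, wgrid * dy)
    ci = X / px  # column index
    ri = Y / px  # row index
    h, w = stack.shape
    if ri.min() < 0 or ci.min() < 0 or ri.max() > h - 1 or ci.max() > w - 1:
        raise BoundaryError(
            f"profile rectangle for {synapse.synapse_id} exits the image"
        )

    values = {}
    for role in channels:
        img = stack.channel(role)
        samp = ndimage.map_coordinates(img, [ri.ravel(), ci.ravel()], order=1)
        values[role] = samp.reshape(n_len, n_wid).mean(axis=1)

    flipped = False
    if "synapsin" in values:
        neg = values["synapsin"][p < 0].sum()
        pos = values["synapsin"][p > 0].sum()
        if pos > neg:
            values = {r: v[::-1].copy() for r, v in values.items()}
            flipped = True
    return IntensityProfile(
        positions_nm=p,
        values=values,
        synapse_id=synapse.synapse_id,
        meta={"flipped": flipped, "length_nm": length_nm, "width_nm": width_nm},
    )


# ---------------------------------------------------------------------------
# smoothing / alignment / peaks
# ---------------------------------------------------------------------------


def smooth_rolling_average(values, window: int = DEFAULT_SMOOTH_PX) -> np.ndarray:
    """Centered moving mean; near the edges the window is clipped to the
    available samples, so output length equals input length and a constant
    signal is preserved exactly."""
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    if window > len(values):
        raise ParameterError(f"window {window} exceeds profile length {len(values)}")
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones(len(values)), kernel, mode="same")
    return sums / counts


@dataclass
class PeakLocation:
    position_nm: float
    index: int
    degenerate: bool = False


def locate_psd_peak(
    profile: IntensityProfile, smooth_px: int = DEFAULT_SMOOTH_PX
) -> PeakLocation:
    """Position of the maximum of the smoothed PSD-95 profile.

    Ties are broken by the smallest position (first grid index).  An
    all-zero PSD channel is degenerate and raises; a flat nonzero profile
    returns the first position flagged degenerate.
    """
    if "psd95" not in profile.values:
        raise ConfigurationError("profile has no 'psd95' channel")
    sm = smooth_rolling_average(profile.values["psd95"], smooth_px)
    if np.all(profile.values["psd95"] == 0):
        raise DegenerateInputError(
            f"all-zero PSD-95 profile for {profile.synapse_id}"
        )
    idx = int(np.argmax(sm))
    flat = bool(np.all(sm == sm[0]))
    return PeakLocation(
        position_nm=float(profile.positions_nm[idx]), index=idx, degenerate=flat
    )


def align_profiles(
    profiles,
    smooth_px: int = DEFAULT_SMOOTH_PX,
    min_coverage: float = 0.5,
) -> AlignedProfileSet:
    """Shift every profile so its smoothed PSD-95 peak sits at position 0,
    then average across synapses per position and channel.

    The PSD-95 channel enters the aligned set in its smoothed form; all
    other channels stay raw.  Positions covered by fewer than
    ``min_coverage`` of the synapses are dropped.  SEM is the sample
    standard deviation over covering synapses divided by sqrt(n); it is 0
    where only one synapse covers a position.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("align_profiles needs at least one profile")
    step = profiles[0].step_nm
    for pr in profiles[1:]:
        if not math.isclose(pr.step_nm, step, rel_tol=1e-9):
            raise ValidationError("profiles must share a grid spacing")
    roles = list(profiles[0].values)

    shifted = []  # (offsets in grid steps, values dict)
    for pr in profiles:
        loc = locate_psd_peak(pr, smooth_px)
        vals = dict(pr.values)
        vals["psd95"] = smooth_rolling_average(vals["psd95"], smooth_px)
        n = len(pr.positions_nm)
        offs = np.arange(n) - loc.index
        shifted.append((offs, vals, pr.synapse_id))

    lo = min(int(offs[0]) for offs, _, _ in shifted)
    hi = max(int(offs[-1]) for offs, _, _ in shifted)
    grid = np.arange(lo, hi + 1)
    positions = grid * step
    n_syn = len(shifted)
    members = {r: np.full((n_syn, len(grid)), np.nan) for r in roles}
    for i, (offs, vals, _) in enumerate(shifted):
        j0 = int(offs[0]) - lo
        for r in roles:
            members[r][i, j0 : j0 + len(offs)] = vals[r]

    coverage = np.sum(~np.isnan(members[roles[0]]), axis=0)
    keep = coverage >= max(1, math.ceil(min_coverage * n_syn))
    positions = positions[keep]
    mean, sem = {}, {}
    for r in roles:
        members[r] = members[r][:, keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(members[r], axis=0)
            counts = np.sum(~np.isnan(members[r]), axis=0)
            sd = np.nanstd(members[r], axis=0, ddof=1)
        sd = np.where(counts > 1, sd, 0.0)
        mean[r] = m
        sem[r] = np.where(counts > 0, sd / np.sqrt(np.maximum(counts, 1)), 0.0)
    return AlignedProfileSet(
        positions_nm=positions,
        members=members,
        mean=mean,
        sem=sem,
        synapse_ids=[sid for _, _, sid in shifted],
    )


def peak_in_window(
    positions_nm: np.ndarray,
    values: np.ndarray,
    window_nm: float = DEFAULT_WINDOW_NM,
    synapse_id: str = "",
    channel: str = "",
) -> PeakMeasurement:
    """Maximum value (and its position) within ±window/2 of position 0.

    Ties are broken toward the position nearest 0, then toward the negative
    (presynaptic) side.  NaN entries (positions a synapse does not cover)
    are ignored; an all-NaN or all-zero window is flagged degenerate.
    """
    positions_nm = np.asarray(positions_nm, dtype=float)
    values = np.asarray(values, dtype=float)
    half = window_nm / 2.0
    if (
        positions_nm.size == 0
        or positions_nm.min() > -half + 1e-9
        or positions_nm.max() < half - 1e-9
    ):
        raise ParameterError(
            f"window {window_nm} nm exceeds the aligned grid "
            f"[{positions_nm.min() if positions_nm.size else float('nan')}, "
            f"{positions_nm.max() if positions_nm.size else float('nan')}]"
        )
    sel = np.abs(positions_nm) <= half + 1e-9
    pos = positions_nm[sel]
    val = values[sel]
    ok = ~np.isnan(val)
    if not ok.any():
        return PeakMeasurement(synapse_id, channel, float("nan"), float("nan"),
                               window_nm, degenerate=True)
    pos, val = pos[ok], val[ok]
    vmax = val.max()
    cand = np.flatnonzero(val == vmax)
    # nearest zero, then negative side
    order = sorted(cand, key=lambda i: (abs(pos[i]), pos[i]))
    i = order[0]
    return PeakMeasurement(
        synapse_id=synapse_id,
        channel=channel,
        peak_value=float(vmax),
        peak_position_nm=float(pos[i]),
        window_nm=window_nm,
        degenerate=bool(vmax == 0),
    )


def member_peaks(
    aligned: AlignedProfileSet,
    channel: str = "channel_of_interest",
    window_nm: float = DEFAULT_WINDOW_NM,
):
    """Per-synapse in-window peak of one channel of an aligned set."""
    return [
        peak_in_window(
            aligned.positions_nm,
            aligned.members[channel][i],
            window_nm=window_nm,
            synapse_id=sid,
            channel=channel,
        )
        for i, sid in enumerate(aligned.synapse_ids)
    ]


def summarize_peaks(groups: dict) -> pd.DataFrame:
    """Tidy per-synapse peak table across conditions.

    ``groups`` maps condition label -> list of :class:`PeakMeasurement`.
    Empty groups are dropped with a warning.  One row per measurement,
    ready for the group statistics (unit of analysis: synapse).
    """
    rows = []
    for cond, measurements in groups.items():
        if not measurements:
            warnings.warn(f"condition {cond!r} has no peak measurements; dropped")
            continue
        for m in measurements:
            rows.append(
                {
                    "condition": cond,
                    "synapse_id": m.synapse_id,
                    "channel": m.channel,
                    "peak_value": m.peak_value,
                    "peak_position_nm": m.peak_position_nm,
                    "degenerate": m.degenerate,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["condition", "synapse_id", "channel", "peak_value",
                 "peak_position_nm", "degenerate"],
    )
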