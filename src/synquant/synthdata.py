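"""Synthetic two-/three-channel synapse and soma images with exact ground truth.

The generator emulates the imaging regime of dual-color STED / confocal
synapse fields: an elongated postsynaptic density (PSD-95) bar, a presynaptic
channel band apposed to it at a configurable nanometer offset, and a synapsin
vesicle cloud on the presynaptic side, each convolved with a channel- and
modality-specific Gaussian PSF, on a constant background, optionally
Poisson-sampled.

Rendering is analytic: a sharp rectangular structure convolved with an
isotropic Gaussian separates along its own axes into a product of
erf-differences, and a Gaussian cloud convolves into a wider Gaussian, so
the noiseless image is evaluated in closed form on the pixel grid (no
numerical convolution error).  Structures are only evaluated inside a
bounding window of ±5σ, which keeps large fields cheap.

Seeding: a single top-level scene seed; per-synapse child streams are spawned
as ``SeedSequence((seed, TAG, index))`` so adding synapse ``n+1`` never
perturbs synapses ``1..n``, and the Poisson render stream is independent of
the placement streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import ConfigurationError, PlacementError, ValidationError
from .stack import ImageStack

_SQRT2 = math.sqrt(2.0)

# stream tags for SeedSequence splitting
_TAG_SYNAPSE = 101
_TAG_RENDER = 202
_TAG_SOMA = 303

#: Default PSF FWHM (nm) per (channel role, modality).  STED lateral
#: resolution on a gated SP8 is a few tens of nm; confocal is
#: diffraction-limited (~250 nm at these wavelengths).
DEFAULT_PSF_FWHM_NM = {
    ("channel_of_interest", "sted"): 60.0,
    ("psd95", "sted"): 60.0,
    ("channel_of_interest", "confocal"): 250.0,
    ("psd95", "confocal"): 250.0,
    ("synapsin", "confocal"): 250.0,
    ("neun", "confocal"): 300.0,
    ("nucleus", "confocal"): 300.0,
}


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class OpticsSpec:
    """Acquisition geometry and noise model.

    Defaults reproduce the synapse-imaging regime: a 58.14 × 58.14 μm²
    field at 4096 × 4096 px (14.194 nm pixels).  ``background_counts`` is
    the constant offset every channel carries; ``photon_scale`` converts
    structure amplitude (arbitrary units) to expected counts, so Poisson
    noise scales as sqrt(photon_scale · amplitude).
    """

    pixel_size_nm: float = 58.14 * 1000.0 / 4096  # 14.194 nm
    field_px: tuple = (4096, 4096)
    psf_fwhm_nm: dict = field(default_factory=lambda: dict(DEFAULT_PSF_FWHM_NM))
    background_counts: float = 2.0
    photon_scale: float = 1.0

    def __post_init__(self):
        if not (self.pixel_size_nm > 0):
            raise ValidationError("pixel_size_nm must be > 0")
        h, w = self.field_px
        if h <= 0 or w <= 0:
            raise ValidationError("field_px must be positive")
        if self.background_counts < 0 or not (self.photon_scale > 0):
            raise ValidationError("background_counts >= 0 and photon_scale > 0 required")
        for key, v in self.psf_fwhm_nm.items():
            if not (v > 0):
                raise ValidationError(f"PSF FWHM for {key} must be > 0")
        # STED never worse than confocal for the same fluorophore
        for (role, mod), v in self.psf_fwhm_nm.items():
            if mod == "sted":
                conf = self.psf_fwhm_nm.get((role, "confocal"))
                if conf is not None and v > conf:
                    raise ValidationError(
                        f"STED FWHM ({v}) exceeds confocal FWHM ({conf}) for {role!r}"
                    )

    def psf_sigma_nm(self, role: str, modality: str) -> float:
        try:
            return fwhm_to_sigma(self.psf_fwhm_nm[(role, modality)])
        except KeyError:
            raise ConfigurationError(
                f"no PSF configured for role={role!r}, modality={modality!r}"
            ) from None

    @property
    def field_nm(self) -> tuple:
        h, w = self.field_px
        return (h * self.pixel_size_nm, w * self.pixel_size_nm)


@dataclass(frozen=True)
class SynapseTruth:
    """Ground-truth geometry and intensity of one simulated synapse.

    The PSD bar is centered at ``center_nm`` with its elongation axis at
    ``axis_angle_rad`` (in [0, π), x toward columns, y toward rows).  The
    trans-synaptic axis is perpendicular; *negative* perpendicular
    coordinates are the presynaptic side, where the vesicle cloud sits at
    ``-vesicle_cloud_offset_nm`` and the channel band at
    ``channel_offset_nm`` (negative for presynaptically targeted channels).
    ``channel_amplitude = 0`` encodes the "not expressed / not targeted"
    condition.
    """

    center_nm: tuple
    axis_angle_rad: float
    psd_length_nm: float = 400.0
    psd_thickness_nm: float = 80.0
    channel_offset_nm: float = -50.0
    channel_length_nm: float = 300.0
    channel_thickness_nm: float = 60.0
    channel_amplitude: float = 80.0
    psd_amplitude: float = 100.0
    synapsin_amplitude: float = 120.0
    vesicle_cloud_radius_nm: float = 200.0
    vesicle_cloud_offset_nm: float = 250.0
    edge_softness_nm: float = 0.0
    view: str = "side"

    def __post_init__(self):
        if self.view not in ("side", "face"):
            raise ValidationError(f"view must be 'side' or 'face', got {self.view!r}")
        if not (0.0 <= self.axis_angle_rad < math.pi):
            raise ValidationError("axis_angle_rad must lie in [0, pi)")
        for name in (
            "psd_length_nm",
            "psd_thickness_nm",
            "channel_length_nm",
            "channel_thickness_nm",
            "vesicle_cloud_radius_nm",
            "vesicle_cloud_offset_nm",
        ):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be > 0")
        for name in ("channel_amplitude", "psd_amplitude", "synapsin_amplitude"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.view == "side" and self.psd_length_nm <= self.psd_thickness_nm:
            raise ValidationError("side view requires psd_length_nm > psd_thickness_nm")


@dataclass(frozen=True)
class SceneTruth:
    """A field's optics, its synapse ground truths, and the scene seed."""

    optics: OpticsSpec
    synapses: tuple
    seed: int

    def __post_init__(self):
        h_nm, w_nm = self.optics.field_nm
        for s in self.synapses:
            x, y = s.center_nm
            if not (0 <= x <= w_nm and 0 <= y <= h_nm):
                raise ValidationError(f"synapse center {s.center_nm} outside field")


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

#: Per-regime channel-band amplitude distribution (mean, sd); "targeted"
#: mirrors a robustly active-zone-localized channel, "reduced" a partially
#: targeted one, "absent" a channel not detected at the active zone.
AMPLITUDE_REGIMES = {
    "targeted": (80.0, 10.0),
    "reduced": (20.0, 5.0),
    "absent": (0.0, 0.0),
}

#: Default targeted-regime offset: tens of nanometers on the presynaptic
#: side of the PSD-95 peak.
DEFAULT_OFFSET_MEAN_NM = -50.0
DEFAULT_OFFSET_SD_NM = 15.0


def build_scene(
    optics: OpticsSpec,
    n_synapses: int,
    *,
    offset_mean_nm: float = DEFAULT_OFFSET_MEAN_NM,
    offset_sd_nm: float = DEFAULT_OFFSET_SD_NM,
    amplitude_regime: str = "targeted",
    seed: int = 0,
    min_spacing_nm: float = 1500.0,
    margin_nm: float = 800.0,
    fixed_offsets_nm=None,
    fixed_angle_rad: float | None = None,
    **synapse_kwargs,
) -> SceneTruth:
    """Place ``n_synapses`` non-overlapping side-view synapses in the field.

    Offsets are drawn Normal(``offset_mean_nm``, ``offset_sd_nm``) unless
    ``fixed_offsets_nm`` gives one explicit offset per synapse.  Amplitudes
    follow ``amplitude_regime`` (see :data:`AMPLITUDE_REGIMES`).  Placement
    is sequential rejection sampling with per-synapse child seeds, so a
    scene of n synapses is a prefix of the scene of n+1.
    """
    if n_synapses < 0:
        raise ValidationError("n_synapses must be >= 0")
    if amplitude_regime not in AMPLITUDE_REGIMES:
        raise ConfigurationError(
            f"unknown amplitude_regime {amplitude_regime!r}; "
            f"choose from {sorted(AMPLITUDE_REGIMES)}"
        )
    if fixed_offsets_nm is not None and len(fixed_offsets_nm) != n_synapses:
        raise ValidationError("fixed_offsets_nm must have one entry per synapse")
    amp_mean, amp_sd = AMPLITUDE_REGIMES[amplitude_regime]
    h_nm, w_nm = optics.field_nm
    if n_synapses > 0 and (w_nm <= 2 * margin_nm or h_nm <= 2 * margin_nm):
        raise PlacementError(
            f"field {w_nm:.0f}x{h_nm:.0f} nm too small for margin {margin_nm} nm"
        )

    centers: list[tuple] = []
    synapses = []
    for i in range(n_synapses):
        rng = np.random.default_rng(np.random.SeedSequence((seed, _TAG_SYNAPSE, i)))
        placed = False
        for _ in range(2000):
            x = rng.uniform(margin_nm, w_nm - margin_nm)
            y = rng.uniform(margin_nm, h_nm - margin_nm)
            if all(math.hypot(x - cx, y - cy) >= min_spacing_nm for cx, cy in centers):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place synapse {i + 1}/{n_synapses} at spacing "
                f"{min_spacing_nm} nm in a {w_nm:.0f}x{h_nm:.0f} nm field"
            )
        centers.append((x, y))
        angle = (
            fixed_angle_rad
            if fixed_angle_rad is not None
            else rng.uniform(0.0, math.pi)
        )
        offset = (
            float(fixed_offsets_nm[i])
            if fixed_offsets_nm is not None
            else rng.normal(offset_mean_nm, offset_sd_nm)
        )
        amplitude = max(0.0, rng.normal(amp_mean, amp_sd)) if amp_mean > 0 else 0.0
        synapses.append(
            SynapseTruth(
                center_nm=(x, y),
                axis_angle_rad=angle,
                channel_offset_nm=offset,
                channel_amplitude=amplitude,
                **synapse_kwargs,
            )
        )
    return SceneTruth(optics=optics, synapses=tuple(synapses), seed=seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _soft_box(u: np.ndarray, full_len: float, sigma: float) -> np.ndarray:
    """1-D cross-section of a sharp box of length ``full_len`` convolved
    with a Gaussian of standard deviation ``sigma`` (unit plateau)."""
    h = 0.5 * full_len
    if sigma <= 0:
        return ((u >= -h) & (u <= h)).astype(float)
    return 0.5 * (erf((u + h) / (_SQRT2 * sigma)) - erf((u - h) / (_SQRT2 * sigma)))


def _add_box(
    img: np.ndarray,
    px: float,
    center_nm,
    angle: float,
    length_nm: float,
    thickness_nm: float,
    amplitude: float,
    sigma_nm: float,
):
    """Accumulate a rotated PSF-convolved box; evaluated on a local window."""
    if amplitude == 0:
        return
    cx, cy = center_nm
    half_extent = 0.5 * max(length_nm, thickness_nm) + 5.0 * sigma_nm
    r0 = max(0, int((cy - half_extent) / px))
    r1 = min(img.shape[0], int((cy + half_extent) / px) + 2)
    c0 = max(0, int((cx - half_extent) / px))
    c1 = min(img.shape[1], int((cx + half_extent) / px) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx * px - cx
    dy = yy * px - cy
    # coordinates along (u) and across (v) the elongation axis
    u = dx * math.cos(angle) + dy * math.sin(angle)
    v = -dx * math.sin(angle) + dy * math.cos(angle)
    img[r0:r1, c0:c1] += (
        amplitude * _soft_box(u, length_nm, sigma_nm) * _soft_box(v, thickness_nm, sigma_nm)
    )


def _add_gaussian(
    img: np.ndarray,
    px: float,
    center_nm,
    radius_nm: float,
    amplitude: float,
    sigma_psf_nm: float,
):
    """Accumulate an isotropic Gaussian cloud (sd = radius) ⊗ PSF."""
    if amplitude == 0:
        return
    s2 = radius_nm**2 + sigma_psf_nm**2
    # peak of the convolved cloud, preserving integral
    peak = amplitude * radius_nm**2 / s2
    cx, cy = center_nm
    half_extent = 5.0 * math.sqrt(s2)
    r0 = max(0, int((cy - half_extent) / px))
    r1 = min(img.shape[0], int((cy + half_extent) / px) + 2)
    c0 = max(0, int((cx - half_extent) / px))
    c1 = min(img.shape[1], int((cx + half_extent) / px) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (xx * px - cx) ** 2 + (yy * px - cy) ** 2
    img[r0:r1, c0:c1] += peak * np.exp(-0.5 * d2 / s2)


#: Channel layout rendered for synapse fields: STED for the protein of
#: interest and PSD-95, confocal for synapsin (the acquisition scheme the
#: side-view selection relies on).
SYNAPSE_CHANNELS = (
    ("channel_of_interest", "sted"),
    ("psd95", "sted"),
    ("synapsin", "confocal"),
)


def _perp_unit(angle: float) -> tuple:
    """Unit vector perpendicular to the elongation axis; negative multiples
    of it are the presynaptic side by construction."""
    return (math.sin(angle), -math.cos(angle))


def structure_centers_nm(s: SynapseTruth) -> dict:
    """Continuous centers of the three structures of a synapse."""
    cx, cy = s.center_nm
    nx, ny = _perp_unit(s.axis_angle_rad)
    return {
        "psd95": (cx, cy),
        "channel_of_interest": (
            cx + nx * s.channel_offset_nm,
            cy + ny * s.channel_offset_nm,
        ),
        "synapsin": (
            cx - nx * s.vesicle_cloud_offset_nm,
            cy - ny * s.vesicle_cloud_offset_nm,
        ),
    }


def render_stack(
    scene: SceneTruth,
    noise: str = "poisson",
    channels=SYNAPSE_CHANNELS,
) -> ImageStack:
    """Render a scene to an :class:`ImageStack`.

    Each channel is ``background + photon_scale · Σ structures ⊗ PSF``; with
    ``noise='poisson'`` every pixel is an independent Poisson draw with that
    expectation, seeded from the scene seed (same scene, same pixels).  The
    noiseless render is the exact pixel-wise expectation of the noisy one.
    """
    if noise not in ("none", "poisson"):
        raise ConfigurationError(f"noise must be 'none' or 'poisson', got {noise!r}")
    opt = scene.optics
    px = opt.pixel_size_nm
    h, w = opt.field_px
    planes = []
    for ci, (role, modality) in enumerate(channels):
        sigma = opt.psf_sigma_nm(role, modality)
        img = np.zeros((h, w), dtype=float)
        for s in scene.synapses:
            centers = structure_centers_nm(s)
            soft = math.hypot(s.edge_softness_nm, sigma)
            if role == "psd95":
                _add_box(
                    img, px, centers["psd95"], s.axis_angle_rad,
                    s.psd_length_nm, s.psd_thickness_nm, s.psd_amplitude, soft,
                )
            elif role == "channel_of_interest":
                _add_box(
                    img, px, centers["channel_of_interest"], s.axis_angle_rad,
                    s.channel_length_nm, s.channel_thickness_nm,
                    s.channel_amplitude, soft,
                )
            elif role == "synapsin":
                _add_gaussian(
                    img, px, centers["synapsin"],
                    s.vesicle_cloud_radius_nm, s.synapsin_amplitude, sigma,
                )
            else:
                raise ConfigurationError(f"no synapse structure for role {role!r}")
        expect = opt.background_counts + opt.photon_scale * img
        if noise == "poisson":
            rng = np.random.default_rng(
                np.random.SeedSequence((scene.seed, _TAG_RENDER, ci))
            )
            expect = rng.poisson(expect).astype(float)
        planes.append(expect)
    return ImageStack(
        pixels=np.stack(planes),
        roles=tuple(r for r, _ in channels),
        modalities=tuple(m for _, m in channels),
        pixel_size_nm=px,
        meta={"scene_seed": scene.seed, "noise": noise},
    )


def truth_table(scene: SceneTruth) -> pd.DataFrame:
    """One row of ground truth per synapse (lossless CSV round-trip)."""
    rows = []
    for i, s in enumerate(scene.synapses):
        d = asdict(s)
        x, y = d.pop("center_nm")
        rows.append({"synapse_id": i, "center_x_nm": x, "center_y_nm": y, **d})
    cols = [
        "synapse_id", "center_x_nm", "center_y_nm", "axis_angle_rad",
        "psd_length_nm", "psd_thickness_nm", "channel_offset_nm",
        "channel_length_nm", "channel_thickness_nm", "channel_amplitude",
        "psd_amplitude", "synapsin_amplitude", "vesicle_cloud_radius_nm",
        "vesicle_cloud_offset_nm", "edge_softness_nm", "view",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# soma fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SomaTruth:
    """Ground truth of one simulated neuronal soma: a NeuN-filled disk with
    an EGFP nucleus disk inside and an HA signal over the cytoplasm."""

    cell_id: int
    center_nm: tuple
    soma_radius_nm: float = 8000.0
    nucleus_radius_nm: float = 4000.0
    neun_amplitude: float = 100.0
    nucleus_amplitude: float = 100.0
    ha_amplitude: float = 60.0


def build_soma_scene(
    optics: OpticsSpec,
    n_cells: int,
    *,
    ha_amplitude: float = 60.0,
    seed: int = 0,
    min_spacing_nm: float = 20000.0,
) -> tuple:
    """Place ``n_cells`` somata; returns (optics, tuple of SomaTruth, seed)."""
    if n_cells < 0:
        raise ValidationError("n_cells must be >= 0")
    h_nm, w_nm = optics.field_nm
    cells = []
    centers: list[tuple] = []
    for i in range(n_cells):
        rng = np.random.default_rng(np.random.SeedSequence((seed, _TAG_SOMA, i)))
        soma_r = rng.uniform(7000.0, 9000.0)
        margin = soma_r + 1000.0
        placed = False
        for _ in range(2000):
            x = rng.uniform(margin, w_nm - margin)
            y = rng.uniform(margin, h_nm - margin)
            if all(math.hypot(x - cx, y - cy) >= min_spacing_nm for cx, cy in centers):
                placed = True
                break
        if not placed:
            raise PlacementError(f"could not place soma {i + 1}/{n_cells}")
        centers.append((x, y))
        cells.append(
            SomaTruth(
                cell_id=i,
                center_nm=(x, y),
                soma_radius_nm=soma_r,
                nucleus_radius_nm=soma_r * rng.uniform(0.40, 0.55),
                ha_amplitude=max(0.0, rng.normal(ha_amplitude, 0.1 * ha_amplitude))
                if ha_amplitude > 0
                else 0.0,
            )
        )
    return optics, tuple(cells), seed


#: Soma fields are single confocal sections: NeuN (soma fill), the EGFP
#: nuclear fill, and the HA channel of interest.
SOMA_CHANNELS = (
    ("neun", "confocal"),
    ("nucleus", "confocal"),
    ("channel_of_interest", "confocal"),
)


def render_soma_stack(soma_scene, noise: str = "poisson") -> ImageStack:
    """Render a soma scene; HA fills the cytoplasmic annulus (soma minus
    nucleus), emulating a membrane/cytoplasmic protein excluded from the
    nucleus."""
    optics, cells, seed = soma_scene
    if noise not in ("none", "poisson"):
        raise ConfigurationError(f"noise must be 'none' or 'poisson', got {noise!r}")
    px = optics.pixel_size_nm
    h, w = optics.field_px
    planes = []
    for ci, (role, modality) in enumerate(SOMA_CHANNELS):
        sigma = optics.psf_sigma_nm(role, modality)
        img = np.zeros((h, w), dtype=float)
        for c in cells:
            if role == "neun":
                _add_disk(img, px, c.center_nm, c.soma_radius_nm, c.neun_amplitude, sigma)
            elif role == "nucleus":
                _add_disk(
                    img, px, c.center_nm, c.nucleus_radius_nm, c.nucleus_amplitude, sigma
                )
            else:  # channel_of_interest: cytoplasmic annulus
                _add_disk(img, px, c.center_nm, c.soma_radius_nm, c.ha_amplitude, sigma)
                _add_disk(
                    img, px, c.center_nm, c.nucleus_radius_nm, -c.ha_amplitude, sigma
                )
        expect = optics.background_counts + optics.photon_scale * img
        expect = np.clip(expect, 0.0, None)
        if noise == "poisson":
            rng = np.random.default_rng(np.random.SeedSequence((seed, _TAG_RENDER, ci)))
            expect = rng.poisson(expect).astype(float)
        planes.append(expect)
    return ImageStack(
        pixels=np.stack(planes),
        roles=tuple(r for r, _ in SOMA_CHANNELS),
        modalities=tuple(m for _, m in SOMA_CHANNELS),
        pixel_size_nm=px,
        meta={"scene_seed": seed, "noise": noise},
    )


def _add_disk(img, px, center_nm, radius_nm, amplitude, sigma_nm):
    """Accumulate a PSF-blurred filled disk (radial erf edge approximation;
    exact in the large radius/sigma ratio regime somata live in)."""
    if amplitude == 0:
        return
    cx, cy = center_nm
    half_extent = radius_nm + 5.0 * sigma_nm
    r0 = max(0, int((cy - half_extent) / px))
    r1 = min(img.shape[0], int((cy + half_extent) / px) + 2)
    c0 = max(0, int((cx - half_extent) / px))
    c1 = min(img.shape[1], int((cx + half_extent) / px) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    r = np.sqrt((xx * px - cx) ** 2 + (yy * px - cy) ** 2)
    if sigma_nm <= 0:
        img[r0:r1, c0:c1] += amplitude * (r <= radius_nm)
    else:
        img[r0:r1, c0:c1] += amplitude * 0.5 * (
            1.0 + erf((radius_nm - r) / (_SQRT2 * sigma_nm))
        )


def soma_truth_table(soma_scene) -> pd.DataFrame:
    _, cells, _ = soma_scene
    rows = []
    for c in cells:
        d = asdict(c)
        x, y = d.pop("center_nm")
        rows.append({**{"cell_id": d.pop("cell_id")}, "center_x_nm": x, "center_y_nm": y, **d})
    return pd.DataFrame(rows)
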