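"""Seeded end-to-end workflow: simulate → quantify → compare → report.

One :class:`RunConfig` describes a multi-condition experiment (each
condition a synthetic scene regime), the analysis parameters, and the seed.
:func:`run_experiment` renders every condition, runs the side-view profile
analysis and the confocal ROI quantification, compares per-synapse peak
levels across conditions (Kruskal–Wallis + Dunn vs the reference
condition), and writes tidy CSVs.  Outputs are deterministic for a fixed
seed, every CSV carries the config hash in a leading comment line, and a
blinding mode hides condition labels behind stable codes until the stats
stage (the key is written alongside).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import profiles as prof
from . import roiquant, synthdata
from .errors import ValidationError
from .stats import kruskal_dunn

_CONDITION_KEYS = {"regime", "n_synapses", "offset_mean_nm", "offset_sd_nm"}
_PARAM_DEFAULTS = {
    "length_nm": 1000.0,
    "width_nm": 200.0,
    "window_nm": 200.0,
    "smooth_px": 5,
    "min_area_um2": 0.05,
    "connectivity": 8,
    "min_elongation": 2.0,
    "adjacency_radius_nm": 150.0,
    "min_coverage": 0.5,
}
_OPTICS_KEYS = {
    "pixel_size_nm",
    "field_px",
    "psf_fwhm_nm",
    "background_counts",
    "photon_scale",
}


@dataclass
class RunConfig:
    """Validated experiment description.

    ``conditions`` maps a label to a scene regime:
    ``{regime: targeted|absent|reduced, n_synapses: int,
    offset_mean_nm: float, offset_sd_nm: float}``.
    """

    conditions: dict
    reference: str
    seed: int = 0
    alpha: float = 0.05
    blind: bool = False
    noise: str = "poisson"
    optics: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.conditions:
            raise ValidationError("need at least one condition")
        for label, spec in self.conditions.items():
            unknown = set(spec) - _CONDITION_KEYS
            if unknown:
                raise ValidationError(
                    f"unknown condition key(s) {sorted(unknown)} in {label!r}"
                )
            if spec.get("regime", "targeted") not in synthdata.AMPLITUDE_REGIMES:
                raise ValidationError(f"unknown regime in condition {label!r}")
        if self.reference not in self.conditions:
            raise ValidationError(f"reference {self.reference!r} not a condition")
        unknown = set(self.params) - set(_PARAM_DEFAULTS)
        if unknown:
            raise ValidationError(f"unknown analysis parameter(s) {sorted(unknown)}")
        unknown = set(self.optics) - _OPTICS_KEYS
        if unknown:
            raise ValidationError(f"unknown optics key(s) {sorted(unknown)}")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.noise not in ("none", "poisson"):
            raise ValidationError("noise must be 'none' or 'poisson'")
        self.params = {**_PARAM_DEFAULTS, **self.params}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {"conditions", "reference", "seed", "alpha", "blind", "noise",
                 "optics", "params"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def optics_spec(self) -> synthdata.OpticsSpec:
        kw = dict(self.optics)
        if "field_px" in kw:
            kw["field_px"] = tuple(kw["field_px"])
        if "psf_fwhm_nm" in kw:
            kw["psf_fwhm_nm"] = {
                tuple(k.split("/")) if isinstance(k, str) else tuple(k): v
                for k, v in kw["psf_fwhm_nm"].items()
            }
        return synthdata.OpticsSpec(**kw)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, tuple):
                return list(o)
            raise TypeError

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config(
    seed: int = 0, n_synapses: int = 30, field_px: int = 1024, **kwargs
) -> RunConfig:
    """The four-condition comparison the pipeline demonstrates: an
    endogenous-channel control, the channel-null background (cTKO-like), a
    presynaptically targeted rescue, and a non-targeted construct."""
    conditions = {
        "control": {"regime": "targeted", "n_synapses": n_synapses},
        "cTKO": {"regime": "absent", "n_synapses": n_synapses},
        "cTKO+rescue": {"regime": "targeted", "n_synapses": n_synapses},
        "cTKO+nontargeted": {"regime": "absent", "n_synapses": n_synapses},
    }
    return RunConfig(
        conditions=conditions,
        reference="cTKO",
        seed=seed,
        optics={"field_px": (field_px, field_px)},
        **kwargs,
    )


def _blind_code(label: str, seed: int) -> str:
    h = hashlib.sha256(f"{seed}:{label}".encode()).hexdigest()[:8]
    return f"cond_{h}"


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str):
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_result_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_experiment(config: RunConfig, outdir) -> dict:
    """Run the full simulated experiment; returns the result bundle and
    writes CSVs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    optics = config.optics_spec()
    p = config.params

    labels = list(config.conditions)
    codes = {
        l: (_blind_code(l, config.seed) if config.blind else l) for l in labels
    }

    truth_rows, peak_groups, aligned_rows, roi_rows, log = [], {}, [], [], []
    for idx, label in enumerate(labels):
        spec = config.conditions[label]
        scene = synthdata.build_scene(
            optics,
            spec.get("n_synapses", 30),
            offset_mean_nm=spec.get("offset_mean_nm", synthdata.DEFAULT_OFFSET_MEAN_NM),
            offset_sd_nm=spec.get("offset_sd_nm", synthdata.DEFAULT_OFFSET_SD_NM),
            amplitude_regime=spec.get("regime", "targeted"),
            seed=int(np.random.SeedSequence((config.seed, 7, idx)).generate_state(1)[0] % (2**31)),
        )
        stack = synthdata.render_stack(scene, noise=config.noise)
        tt = synthdata.truth_table(scene)
        tt.insert(0, "condition", codes[label])
        truth_rows.append(tt)

        detections = prof.detect_side_view_synapses(
            stack,
            min_elongation=p["min_elongation"],
            adjacency_radius_nm=p["adjacency_radius_nm"],
        )
        extracted = []
        for det in detections:
            try:
                extracted.append(
                    prof.extract_profile(
                        stack, det, length_nm=p["length_nm"], width_nm=p["width_nm"]
                    )
                )
            except Exception as e:  # boundary exclusions are logged, not fatal
                log.append(f"{codes[label]}: excluded {det.synapse_id}: {e}")
        if not extracted:
            log.append(f"{codes[label]}: no side-view synapses detected")
            peak_groups[codes[label]] = []
            continue
        aligned = prof.align_profiles(
            extracted, smooth_px=p["smooth_px"], min_coverage=p["min_coverage"]
        )
        for role in aligned.mean:
            aligned_rows.append(
                pd.DataFrame(
                    {
                        "condition": codes[label],
                        "channel": role,
                        "position_nm": aligned.positions_nm,
                        "mean": aligned.mean[role],
                        "sem": aligned.sem[role],
                    }
                )
            )
        peak_groups[codes[label]] = prof.member_peaks(
            aligned, channel="channel_of_interest", window_nm=p["window_nm"]
        )

        table, summary, _ = roiquant.quantify_image(
            stack,
            min_area_um2=p["min_area_um2"],
            connectivity=p["connectivity"],
            image_id=codes[label],
        )
        roi_rows.append(
            {
                "condition": codes[label],
                "n_rois": summary["n_rois"],
                "mean_channel_of_interest": summary.get("mean_channel_of_interest"),
            }
        )

    peaks = prof.summarize_peaks(peak_groups)
    truth = pd.concat(truth_rows, ignore_index=True)
    aligned_df = (
        pd.concat(aligned_rows, ignore_index=True)
        if aligned_rows
        else pd.DataFrame(columns=["condition", "channel", "position_nm", "mean", "sem"])
    )
    roi_df = pd.DataFrame(roi_rows)

    # stats run on true labels (unblinded at this stage, per the workflow)
    decode = {v: k for k, v in codes.items()}
    peaks_unblinded = peaks.assign(condition=peaks["condition"].map(decode))
    groups = {
        c: g["peak_value"].to_numpy()
        for c, g in peaks_unblinded.groupby("condition", sort=False)
    }
    stats_res = None
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        stats_res = kruskal_dunn(groups, reference=config.reference, alpha=config.alpha)
        stats_df = stats_res.posthoc.copy()
        stats_df.insert(0, "kw_p", stats_res.p_value)
        stats_df.insert(0, "kw_H", stats_res.statistic)
    else:
        stats_df = pd.DataFrame()

    _write_csv(truth, outdir / "truth.csv", chash)
    _write_csv(aligned_df, outdir / "aligned_profiles.csv", chash)
    _write_csv(peaks, outdir / "peaks.csv", chash)
    _write_csv(roi_df, outdir / "roi_summary.csv", chash)
    _write_csv(stats_df, outdir / "stats.csv", chash)
    if config.blind:
        key = pd.DataFrame(
            {"code": [codes[l] for l in labels], "condition": labels}
        )
        _write_csv(key, outdir / "blinding_key.csv", chash)
    (outdir / "run.log").write_text(
        "\n".join([f"config_hash={chash}"] + log) + "\n"
    )
    return {
        "config_hash": chash,
        "truth": truth,
        "aligned": aligned_df,
        "peaks": peaks,
        "roi_summary": roi_df,
        "stats": stats_res,
        "log": log,
    }


def plot_profiles(aligned_df: pd.DataFrame, path, channel="channel_of_interest",
                  reference_conditions=()):
    """Mean ± SEM aligned profile figure with dashed reference-condition
    overlays (a regenerated artifact; CSVs are the acceptance surface)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    sub = aligned_df[aligned_df["channel"] == channel]
    for cond, g in sub.groupby("condition", sort=False):
        style = {"linestyle": "--", "color": "gray"} if cond in reference_conditions else {}
        ax.plot(g["position_nm"], g["mean"], label=str(cond), **style)
        ax.fill_between(
            g["position_nm"], g["mean"] - g["sem"], g["mean"] + g["sem"], alpha=0.25
        )
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("position vs PSD-95 peak (nm)")
    ax.set_ylabel(f"{channel} intensity (a.u.)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
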