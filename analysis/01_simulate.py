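"""Simulate the four-condition synapse-imaging experiment.

Renders one synthetic field per condition — an endogenous-channel control,
the channel-null background (cTKO-like), a presynaptically targeted rescue,
and a non-targeted construct — with Poisson noise at the synapse-imaging
pixel size (14.194 nm).  Image stacks (TIFF + sidecar) go to scratch/sim/;
the per-synapse ground-truth tables go to results/sim/.

Run from the repository root:  python analysis/01_simulate.py
"""

from pathlib import Path

from synquant import imageio, synthdata as sd

ROOT = Path(__file__).resolve().parents[1]
IMG_DIR = ROOT / "scratch" / "sim"
OUT_DIR = ROOT / "results" / "sim"

SEED = 11
N_SYNAPSES = 30
FIELD_PX = 1024

CONDITIONS = {
    "control": "targeted",
    "cTKO": "absent",
    "cTKO+rescue": "targeted",
    "cTKO+nontargeted": "absent",
}


def main():
    IMG_DIR.mkdir(parents=True, exist_ok=True)
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    optics = sd.OpticsSpec(field_px=(FIELD_PX, FIELD_PX))
    for i, (label, regime) in enumerate(CONDITIONS.items()):
        scene = sd.build_scene(
            optics, N_SYNAPSES, amplitude_regime=regime, seed=SEED * 100 + i
        )
        stack = sd.render_stack(scene, noise="poisson")
        safe = label.replace("+", "_")
        imageio.write_stack(stack, IMG_DIR / f"{safe}.tif")
        sd.truth_table(scene).to_csv(OUT_DIR / f"{safe}_truth.csv", index=False)
        print(f"{label:>18}: {N_SYNAPSES} synapses ({regime}), "
              f"field {FIELD_PX} px @ {optics.pixel_size_nm:.3f} nm")
    print(f"images -> {IMG_DIR}, truth -> {OUT_DIR}")


if __name__ == "__main__":
    main()
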