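#!/usr/bin/env python
"""Render a cells-free dermal background and recover the elastin lifetime.

The extracellular matrix of the papillary dermis is dominated by elastin
autofluorescence (tau_m 1,600 +- 110 ps).  This script renders a small
cells-free scene, runs the binned bi-exponential fit, and reports the mean
recovered tau_m over unmasked pixels.  Writes the cube, the per-pixel
parameter maps and a one-line summary under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from mcflim import synthetic
from mcflim.decay import FitConfig, fit_image
from mcflim.io import write_cube, write_fit_maps


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--size", type=int, default=32, help="image side in pixels")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    fov = args.size * 150.0 / 512.0  # keep the instrument pixel pitch
    cfg = synthetic.SceneConfig(image_size=(args.size, args.size),
                                field_of_view_um=(fov, fov))
    cube, _ = synthetic.render_scene(cfg, np.random.default_rng(args.seed))
    args.out.mkdir(parents=True, exist_ok=True)
    write_cube(cube, args.out / "elastin_scene.tif")
    maps = fit_image(cube, config=FitConfig())
    write_fit_maps(maps, args.out, stem="elastin_fitmaps")

    tau_m = maps.tau_m[maps.valid]
    summary = {
        "n_pixels_fit": int(tau_m.size),
        "tau_m_mean_ps": float(tau_m.mean()),
        "tau_m_sd_ps": float(tau_m.std()),
        "generator_mean_ps": cfg.elastin_tau_m_mean,
    }
    (args.out / "elastin_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"fit {summary['n_pixels_fit']} pixels: "
          f"tau_m = {summary['tau_m_mean_ps']:.0f} +- {summary['tau_m_sd_ps']:.0f} ps "
          f"(generator mean {cfg.elastin_tau_m_mean:.0f} ps)")


if __name__ == "__main__":
    main()
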