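#!/usr/bin/env python
"""Render a papillary-dermis scene with planted mast cells and run the search.

Places one resting and one activated in vivo mast cell in an elastin
background at 90 um depth, detects bright fluorescent spots, fits their
decays and applies the rule cascade (depth > 70 um, ~10 um size,
tau_m > 1,000 ps resting / < 800 ps activated).  Writes the cell table.
"""

import argparse
from pathlib import Path

import numpy as np

from mcflim import cellscan, synthetic
from mcflim.decay import FitConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    placements = [
        synthetic.CellPlacement("resting_mc/in_vivo/healthy", (9.0, 9.0),
                                params=(344.0, 2301.0, 1.5, 300.0, 10.0, 1)),
        synthetic.CellPlacement("activated_mc/in_vivo/healthy", (26.0, 26.0),
                                params=(241.0, 1947.0, 3.0, 800.0, 9.0, 0)),
    ]
    cfg = synthetic.SceneConfig(image_size=(120, 120), field_of_view_um=(35.2, 35.2),
                                elastin_intensity=100.0, cells=placements,
                                depth_um=90.0)
    cube, truth = synthetic.render_scene(cfg, np.random.default_rng(args.seed))
    records = cellscan.scan_image(cube, fit_config=FitConfig(intensity_threshold=200.0))

    args.out.mkdir(parents=True, exist_ok=True)
    frame = cellscan.records_to_frame(records)
    frame.to_csv(args.out / "detected_cells.csv", index=False)
    print(f"planted {len(truth.table)} cells, detected {len(records)} candidates:")
    for r in records:
        print(f"  d = {r.equivalent_diameter_um:4.1f} um, circularity {r.circularity:.2f}, "
              f"I = {r.mean_intensity:4.0f} photons/mW, tau_m = {r.fit_summary['tau_m']:5.0f} ps "
              f"-> {r.search_label}")


if __name__ == "__main__":
    main()
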