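#!/usr/bin/env python
"""Simulate the reporter screen.

Generates per-cell feature tables for the full labelled compound set under
the default effect model (severe compounds more potent: lower BMC/C-max,
more frequent reporter responses and cytotoxicity). Plates follow the screen
design: one reporter × one concentration (1–100 × C-max) per plate, hourly
frames over 24 h, PI at 24 h, vehicle controls on every plate. The large
cell table goes to scratch/, the latent truth table to results/.
"""

import argparse
from pathlib import Path

from stressdyn.annotation import load_packaged_annotations
from stressdyn.simulate import EffectConfig, LayoutConfig, simulate_screen, write_cells


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-cells", type=int, default=25,
                    help="cells seeded per well (scaled down from 8000 for runtime)")
    ap.add_argument("--replicates", type=int, default=2)
    ap.add_argument("--n-compounds", type=int, default=None,
                    help="optionally restrict to the first N drugs")
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    args.scratch.mkdir(parents=True, exist_ok=True)

    drugs = [a for a in load_packaged_annotations() if not a.is_control]
    if args.n_compounds:
        drugs = drugs[: args.n_compounds]
    layout = LayoutConfig(n_replicates=args.replicates, n_cells_0=args.n_cells)
    cells, truth = simulate_screen(drugs, EffectConfig(), layout, rng_seed=args.seed)

    cells_path = args.scratch / "cells.h5"
    write_cells(cells, cells_path)
    truth.to_csv(args.out / "simulation_truth.csv", index=False)

    n_plates = cells["plate_id"].nunique()
    print(f"simulated {len(drugs)} compounds on {n_plates} plates "
          f"({len(cells):,} cell records) -> {cells_path}")
    resp = truth.groupby("reporter")["responsive"].mean()
    print("responsive fraction per reporter:")
    print(resp.to_string())


if __name__ == "__main__":
    main()
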