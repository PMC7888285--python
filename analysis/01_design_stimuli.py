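#!/usr/bin/env python
"""Enumerate the stimulus designs and map the display gamut.

Writes the matching- and paired-comparison condition sets, the 22 x 22
matching grid (with its displayability audit), and the per-hue maximum
chroma / maximum saturation boundaries of the sRGB gamut.
"""

import argparse
import json
from pathlib import Path

from chromaglint.colorimetry import gamut_boundary
from chromaglint.design import (
    HUES,
    RELIEFS,
    ROUGHNESS_MATCHING,
    ROUGHNESS_PC,
    SLANTS,
    build_matching_grid,
    build_pc_trials,
    conditions_to_frame,
    enumerate_conditions,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/design"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    matching = enumerate_conditions(HUES, RELIEFS, ROUGHNESS_MATCHING, SLANTS)
    conditions_to_frame(matching).to_csv(out / "matching_conditions.csv", index=False)
    print(f"matching design: {len(matching)} conditions "
          f"({len(matching) // len(HUES)} per hue block)")

    pc_block = enumerate_conditions([HUES[0]], RELIEFS, ROUGHNESS_PC, [SLANTS[0]])
    trials = build_pc_trials(pc_block, seed=args.seed)
    trials.to_frame().to_csv(out / "pc_trials_example_block.csv", index=False)
    print(f"paired comparisons: {len(pc_block)} conditions per block -> "
          f"{len(trials)} ordered trials")

    grid_info = {}
    for hue in HUES:
        grid = build_matching_grid(hue, validate_gamut="clip")
        n_out = int(grid.out_of_gamut.sum()) if grid.out_of_gamut is not None else 0
        grid_info[str(hue)] = {
            **grid.to_json_dict(),
            "out_of_gamut_cells": n_out,
            "max_channel_excursion": grid.max_excursion,
        }
        print(f"grid at hue {hue}: 22 x 22 cells, {n_out} outside sRGB "
              f"(worst channel excursion {grid.max_excursion:.2f})")
    (out / "matching_grids.json").write_text(json.dumps(grid_info, indent=2))

    for hue in HUES:
        gb = gamut_boundary(hue)
        gb.to_csv(out / f"gamut_boundary_hue{hue:.3f}.csv")
    print(f"gamut boundaries written for hues {HUES} "
          "(the red hue has the smallest chroma range at high lightness)")


if __name__ == "__main__":
    main()
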