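#!/usr/bin/env python
"""Aggregate the simulated responses into perceptual estimates.

Reads the response CSVs written by 03_simulate_observers.py (regenerating
them if absent), computes per-condition mean matched lightness, chroma and
saturation, win-probability estimates of perceived gloss and coverage, and
the four-way within-subjects ANOVAs on saturation and lightness.
"""

import argparse
import subprocess
import sys
from pathlib import Path

import pandas as pd

from chromaglint.psychophysics import aggregate_matches, pc_probability, rm_anova


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    if not (args.data / "matching.csv").exists():
        subprocess.run(
            [sys.executable, str(Path(__file__).parent / "03_simulate_observers.py"),
             "--seed", str(args.seed), "--out", str(args.data)],
            check=True,
        )

    matching = pd.read_csv(args.data / "matching.csv")
    per_obs = aggregate_matches(matching)
    per_obs.to_csv(args.out / "matching_per_observer.csv", index=False)

    keys = ["hue", "relief", "roughness", "slant"]
    cond_means = per_obs.groupby(keys)[["mean_L", "mean_C", "mean_S"]].mean()
    cond_means.reset_index().to_csv(args.out / "matching_condition_means.csv",
                                    index=False)
    print("mean matched saturation by roughness (averaged over all else):")
    print(per_obs.groupby("roughness")["mean_S"].mean().round(3).to_string())

    for task, fname in (("gloss", "choices_gloss.csv"),
                        ("coverage", "choices_coverage.csv")):
        probs = pc_probability(pd.read_csv(args.data / fname))
        probs.to_csv(args.out / f"p_{task}.csv", index=False)
        print(f"\nmean p_{task} by roughness:")
        print(probs.groupby("roughness")["p"].mean().round(3).to_string())

    for dv, col in (("saturation", "mean_S"), ("lightness", "mean_L")):
        table = rm_anova(per_obs, col, ["hue", "slant", "relief", "roughness"])
        table.to_csv(args.out / f"anova_{dv}.csv", index=False)
        mains = table[table["effect"].isin(["hue", "slant", "relief", "roughness"])]
        print(f"\nfour-way repeated-measures ANOVA on {dv} (main effects):")
        print(mains.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
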