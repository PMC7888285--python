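#!/usr/bin/env python
"""Render the relief x slant sweep and measure physical specular coverage.

Shades displacement-mapped tiles under the overhead area emitter and counts
the pixel fraction whose specular component exceeds a fraction of the
per-image specular peak, across relief heights, slants, seeds, and the
threshold sensitivity set.  The headline pattern: coverage rises with
relief at the 15 deg slant and falls with relief at 45 deg.
"""

import argparse
from pathlib import Path

from chromaglint.render import coverage_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/render"))
    ap.add_argument("--size", type=int, default=128)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    seeds = tuple(args.seed + k for k in range(4))
    frames = []
    for thr in (0.05, 0.1, 0.2):
        t = coverage_table(
            reliefs=(0.025, 0.05, 0.1, 0.2),
            slants=(15.0, 30.0, 45.0),
            roughnesses=(0.1,),
            seeds=seeds,
            frac_threshold=thr,
            image_size=args.size,
        )
        t.insert(0, "threshold", thr)
        frames.append(t)
    import pandas as pd

    table = pd.concat(frames, ignore_index=True)
    table.to_csv(args.out / "coverage.csv", index=False)

    summary = (
        table[table["threshold"] == 0.1]
        .groupby(["slant", "relief"])["coverage"]
        .mean()
        .reset_index()
    )
    summary.to_csv(args.out / "coverage_summary.csv", index=False)
    print(summary.to_string(index=False))
    for slant in (15.0, 45.0):
        c = summary[summary["slant"] == slant]["coverage"].to_numpy()
        trend = "increases" if c[-1] > c[0] else "decreases"
        print(f"coverage {trend} with relief at slant {slant:.0f} deg "
              f"({c[0]:.3f} -> {c[-1]:.3f})")


if __name__ == "__main__":
    main()
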