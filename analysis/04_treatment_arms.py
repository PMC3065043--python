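#!/usr/bin/env python
"""Six-arm treatment comparison on the calibrated study grid.

Simulates the control (V), the monotherapies (NC[D], L[C]), the
co-encapsulating liposome (L[CD]), the sequential-release nanocell
(NC[CD]), and the delayed-release nanocell (NC[CD]_mod) at a matched seed,
and reports the day-17 detectable volumes.  The expected phenomenology:
the combined arms beat the monotherapies, the nanocell clearly beats the
conventional combination with the same delivered dose, and delaying the
core release further improves it.
"""

import argparse
from pathlib import Path

import pandas as pd

from nanocell import ARM_NAMES, Grid, default_parameters, run_arm


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cancer", choices=("lung", "melanoma"), default="lung")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--h", type=float, default=0.6)
    parser.add_argument("--shape", type=int, default=50)
    parser.add_argument("--dt", type=float, default=0.05)
    parser.add_argument("--t-end", type=float, default=17.0)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    params = default_parameters(args.cancer)
    grid = Grid.for_params(params, shape=(args.shape,) * 3, h=args.h)
    frames = []
    summary = []
    for arm in ARM_NAMES:
        curve = run_arm(arm, params, grid, seed=args.seed, t_end_day=args.t_end,
                        dt=args.dt)
        frames.append(curve.to_frame(args.seed))
        summary.append({"arm": arm, "volume_day17_mm3": round(curve.final_volume(), 1)})
        print(f"{arm:>10}: day-17 volume = {curve.final_volume():8.1f} mm^3")
    args.out_dir.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(
        args.out_dir / f"volume_curves_{args.cancer}.csv", index=False)
    pd.DataFrame(summary).to_csv(
        args.out_dir / f"day17_volumes_{args.cancer}.csv", index=False)

    v = {row["arm"]: row["volume_day17_mm3"] for row in summary}
    print(f"\nCombination gain: V - L_CD = {v['V'] - v['L_CD']:.0f} mm^3 vs "
          f"V - NC_D = {v['V'] - v['NC_D']:.0f} and V - L_C = {v['V'] - v['L_C']:.0f}")
    print(f"Nanocell vs conventional combination: NC_CD = {v['NC_CD']:.0f} "
          f"vs L_CD = {v['L_CD']:.0f} mm^3 (same total dose)")
    print(f"Delayed-release nanocell: NC_CD_mod = {v['NC_CD_mod']:.0f} mm^3")


if __name__ == "__main__":
    main()
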