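#!/usr/bin/env python
"""Free-growth calibration: when does the untreated tumor reach 50 mm^3?

Scans the grid spacing h and records the day the untreated lung tumor
crosses the 50 mm^3 enrolment volume on a fixed clock (simulation time =
days).  The experimental protocol reports enrolment "after about 8 days";
the scan shows how close the model gets and which spacing is adopted as the
calibrated default.
"""

import argparse
from pathlib import Path

from nanocell import calibrate_grid, default_parameters


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/grid_calibration.csv"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--shape", type=int, default=50, help="grid points per axis")
    parser.add_argument("--h", type=float, nargs="*",
                        default=[0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
    args = parser.parse_args()

    lung = default_parameters("lung")
    best, table, achieved = calibrate_grid(
        lung, args.h, shape=(args.shape,) * 3, seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(table.to_string(index=False))
    print(f"\nbest h = {best} (crossing closest to day 8); "
          f"within +/-0.5 day of the protocol's ~8 days: {achieved}")
    if not achieved:
        print("The crossing day varies only weakly with h (the front speed is "
              "set by the continuum dynamics), so the anchor is approached "
              "but not hit; treatment-day anchoring is available via "
              "run_arm(align='crossing').")


if __name__ == "__main__":
    main()
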