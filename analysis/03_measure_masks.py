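#!/usr/bin/env python
"""Stage 3 — measure the synthetic masks back into a per-case table.

Runs contour extraction and calibrated area/perimeter measurement over
every field written by stage 2, keeps the ≤ 7 largest cells per field,
averages to one record per case, and writes the standard measurement CSV
to results/synthetic_measurements.csv.
"""

import argparse
from pathlib import Path

from basalmorph.imaging import measure_dataset, read_dataset
from basalmorph.morphometry import write_measurements

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "synthetic_dataset"
OUT = ROOT / "results" / "synthetic_measurements.csv"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--masks", type=Path, default=SCRATCH)
    parser.add_argument("--out", type=Path, default=OUT)
    args = parser.parse_args()

    fields = read_dataset(args.masks)
    records = measure_dataset(fields)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_measurements(records, args.out)
    groups = sorted({r.group for r in records})
    print(f"measured {len(fields)} fields -> {len(records)} case records ({', '.join(groups)})")
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
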