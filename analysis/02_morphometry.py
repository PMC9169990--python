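#!/usr/bin/env python
"""Per-animal testicular morphometry: tubule diameter (STD), epithelium
height (GEH), gonadosomatic/leydigosomatic/tubulosomal indices, volume
densities and total tubule length (TLST).

Reads results/raw/, writes results/morphometry.csv, and prints group means
so the vaccine effect (roughly halved tubule diameter, ~77% epithelium
loss) is visible at a glance.
"""

import argparse
from pathlib import Path

from ovistereo.io import read_raw_dataset
from ovistereo.stereology import morphometry_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--raw", type=Path, default=ROOT / "results" / "raw")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "morphometry.csv")
    args = parser.parse_args()

    raw = read_raw_dataset(args.raw)
    table = morphometry_table(raw)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    means = table.groupby("group")[["TW", "GSI", "STD", "GEH", "TLST"]].mean().round(2)
    print("group means:")
    print(means.to_string())
    print(f"\nwrote per-animal morphometry to {args.out}")


if __name__ == "__main__":
    main()
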