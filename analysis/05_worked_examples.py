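#!/usr/bin/env python
"""Recompute the derived effect percentages from the published group means:
tubule-diameter reductions (55.23% / 57.02%), the 80.3% gonadosomatic drop,
the 21.01% general spermatogenic yield, the 21% meiotic loss, and the
production-estimate consistency plug-ins.

Writes results/worked_examples.json and prints each value.
"""

import argparse
import json
from pathlib import Path

from ovistereo.worked import worked_examples

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "worked_examples.json")
    args = parser.parse_args()

    values = worked_examples()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps({k: round(v, 4) for k, v in values.items()}, indent=2) + "\n")
    for name, value in values.items():
        print(f"{name}: {value:.2f}")
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
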