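#!/usr/bin/env python
"""Validate the statistical machinery at study-condition scale.

Re-runs the package's property measurements — scanner-vs-oracle agreement,
planted-correlation recovery power at n = 48, enrichment calibration and
power, the normal-vs-exact binomial gap, promoter planting, and end-to-end
determinism — and writes the summary table to results/validation.json.
"""

import argparse
import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "scripts"))

import acceptance  # the measurement battery; see scripts/acceptance.py


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "validation.json")
    args = parser.parse_args()
    acceptance.main(["--seed", str(args.seed), "--out", str(args.out)])
    print(f"summary written to {args.out}")


if __name__ == "__main__":
    main()
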