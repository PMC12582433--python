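#!/usr/bin/env python
"""Absolute survivor counts by year, sex and age.

Multiplies the estimated prevalence surface by the synthetic population to
get survivor counts, and prints the per-year totals — the shape of the
curve (rise to the baby-boom cohorts, dip, rebound) follows the population
age structure, while its level follows the prevalence.
"""

import argparse
from pathlib import Path

import pandas as pd

import prevpde as pp


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--estimate", type=Path, default=Path("results/estimate"))
    args = parser.parse_args()

    summary = pd.read_csv(args.estimate / "summary.csv")
    print((args.estimate / "report.txt").read_text().rstrip())
    both = summary.query("sex == 'both'").sort_values("year")
    first, last = both.iloc[0], both.iloc[-1]
    ratio = last["survivors_total"] / first["survivors_total"]
    print(
        f"\nboth-sex total: {first['survivors_total']:.0f} ({int(first['year'])}) "
        f"-> {last['survivors_total']:.0f} ({int(last['year'])}), x{ratio:.2f}"
    )


if __name__ == "__main__":
    main()
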