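#!/usr/bin/env python
"""Generate the synthetic study inputs.

The real analysis consumed claims prevalence, registry incidence,
cause-of-death mortality and official population projections, none of
which are redistributable.  This step writes their synthetic stand-ins:
registry-style 5-year age-group tables (2010-2019, both sexes, open 85+
group), a population with a baby-boom bump, and the exact truth surface
the later steps are judged against.
"""

import argparse
from pathlib import Path

import prevpde as pp


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scenario", default="default", choices=sorted(pp.SCENARIOS))
    parser.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = parser.parse_args()

    scenario = pp.get_scenario(args.scenario)
    print(f"building truth for scenario {scenario.name!r} "
          f"({scenario.t0}-{scenario.t1}, ages 0-{scenario.max_age}) ...")
    truth = pp.build_truth(scenario, step=1e-3)
    paths = pp.write_bundle(truth, args.out, base_cohort=100_000.0, boom_year=1964)
    for name, path in sorted(paths.items()):
        print(f"  wrote {name:<26} -> {path}")
    for sex in scenario.sexes:
        p85 = truth.p_star_grid(sex)[-1, 85]
        print(f"truth prevalence at age 85 in {scenario.t1}, {sex}: {100 * p85:.1f}%")


if __name__ == "__main__":
    main()
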