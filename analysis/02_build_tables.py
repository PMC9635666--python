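#!/usr/bin/env python
"""Build the demography-aware two-locus lookup tables used by the grid.

One table per demographic context: equilibrium (constant size), continuous
gene flow and secondary contact (both: present subpopulation size with a
doubling back to the ancestral size at the depth of the split, measured at
the midpoint of the sampling window).  Tables are written to
results/tables/ as versioned text archives and reused by 03_run_grid.py.

Usage: python analysis/02_build_tables.py [--seed 2] [--mc 12000]
"""

import argparse
from pathlib import Path

from rhoflow import experiment as ex


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--mc", type=int, default=12_000)
    ap.add_argument("--out-dir", type=Path, default=Path("results/tables"))
    args = ap.parse_args()

    args.out_dir.mkdir(parents=True, exist_ok=True)
    jobs = [
        ("equilibrium", ex.desk_preset(n_model=100, table_mc=args.mc), ("equilibrium",)),
        ("secondary", ex.desk_preset(n_model=200, table_mc=args.mc), ("secondary",)),
        ("continuous", ex.desk_preset(n_model=250, table_mc=args.mc), ("continuous",)),
    ]
    for name, preset, scenarios in jobs:
        tables = ex.build_scenario_tables(preset, args.seed, scenarios=scenarios)
        path = args.out_dir / f"{name}_n{preset.table_n}.tsv"
        tables[scenarios[0]].save(path)
        tab = tables[scenarios[0]]
        print(f"{name}: n={tab.table_n}, {len(tab.configs)} configs, "
              f"history={tab.size_history} -> {path}")


if __name__ == "__main__":
    main()
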