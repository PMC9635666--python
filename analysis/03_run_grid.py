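#!/usr/bin/env python
"""Run the isolation-with-migration scenario grid and estimate rho.

Default cells mirror the bias study: secondary contact at
Nem in {0, 0.1, 1, 10, 100} with constant recombination and
Nem in {0, 1, 10, 100} with recombination doubled in p2 (N_model = 200),
plus continuous gene flow at Nem in {0, 100} (N_model = 250, where
Nem = 100 still maps to a migration probability below 1).  ``--full``
additionally runs the low-gene-flow continuous cells.  Writes one row per
(cell, replicate, sampling time, population) to results/grid_results.tsv.

Usage: python analysis/03_run_grid.py [--replicates 10] [--seed 3] [--full]
"""

import argparse
import time
from pathlib import Path

import pandas as pd

from rhoflow import experiment as ex
from rhoflow.twolocus import LookupTable


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=10)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--mc", type=int, default=12_000)
    ap.add_argument("--full", action="store_true",
                    help="also run continuous cells at Nem 0.01-10")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table_dir = args.out_dir / "tables"
    frames = []
    jobs = [
        (
            "secondary", 200,
            [ex.ExperimentCell("secondary", n, 1.0) for n in (0.0, 0.1, 1.0, 10.0, 100.0)]
            + [ex.ExperimentCell("secondary", n, 2.0) for n in (0.0, 1.0, 10.0, 100.0)],
        ),
        (
            "continuous", 250,
            [ex.ExperimentCell("continuous", n, 1.0)
             for n in ((0.0, 0.01, 0.1, 1.0, 10.0, 100.0) if args.full else (0.0, 100.0))],
        ),
    ]
    for scen, n_model, cells in jobs:
        t0 = time.time()
        preset = ex.desk_preset(n_model=n_model, table_mc=args.mc)
        table_path = table_dir / f"{scen}_n{preset.table_n}.tsv"
        if table_path.exists():
            tables = {scen: LookupTable.load(table_path)}
            print(f"{scen}: loaded table {table_path}")
        else:
            tables = ex.build_scenario_tables(preset, args.seed + 1, scenarios=(scen,))
            print(f"{scen}: built table (mc={args.mc})")
        res = ex.run_grid(cells, preset, args.replicates, args.seed, tables)
        res.insert(0, "n_model", n_model)
        frames.append(res)
        print(f"{scen}: {len(cells)} cells x {args.replicates} replicates "
              f"-> {len(res)} rows in {time.time()-t0:.0f}s")
    out = pd.concat(frames, ignore_index=True)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    path = args.out_dir / "grid_results.tsv"
    with open(path, "w") as fh:
        fh.write(f"# rhoflow grid seed={args.seed} replicates={args.replicates} "
                 f"mc={args.mc}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
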