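#!/usr/bin/env python
"""Aggregate the grid estimates into the study's headline statistics.

Reads results/grid_results.tsv and writes: percent bias of each cell
against its Nem = 0 baseline (percent_bias.tsv), the inferred p2 - p1
differences (population_difference.tsv), one-sided variance-ratio tests
for the secondary-contact variance inflation (variance_tests.tsv), and
standardized fixed-effect coefficients for gene-flow magnitude and the
recombination change (standardized_lm.tsv).

Usage: python analysis/04_bias_statistics.py [--results results/grid_results.tsv]
"""

import argparse
from pathlib import Path

import pandas as pd

from rhoflow import experiment as ex


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results/grid_results.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    res = pd.read_csv(args.results, sep="\t", comment="#")
    args.out_dir.mkdir(parents=True, exist_ok=True)

    bias = ex.percent_bias(res)
    bias.to_csv(args.out_dir / "percent_bias.tsv", sep="\t", index=False,
                float_format="%.6g")
    print("== percent bias vs the Nem = 0 baseline (pooled over populations "
          "and sampling times) ==")
    print(bias[["scenario", "recomb_factor_p2", "nem", "mean", "sd", "bias_pct"]]
          .to_string(index=False))

    per, diff = ex.population_difference(res)
    diff.to_csv(args.out_dir / "population_difference.tsv", sep="\t", index=False,
                float_format="%.6g")
    print("\n== inferred p2 - p1 difference (cM/Mb) ==")
    print(diff.to_string(index=False))

    # variance inflation under secondary contact: Nem in {1, 10} vs <= 0.1
    sec = res[(res["scenario"] == "secondary") & (res["recomb_factor_p2"] == 1.0)]
    rows = []
    for hi in (1.0, 10.0):
        for lo in (0.0, 0.1):
            a = sec[sec["nem"] == hi]["r_cmmb"]
            b = sec[sec["nem"] == lo]["r_cmmb"]
            if a.empty or b.empty:
                continue
            out = ex.variance_ratio_test(a, b)
            rows.append(dict(nem_high=hi, nem_low=lo, F=out["F"],
                             df1=out["df"][0], df2=out["df"][1],
                             p_one_sided=out["p"] / 2))
    vt = pd.DataFrame(rows)
    vt.to_csv(args.out_dir / "variance_tests.tsv", sep="\t", index=False,
              float_format="%.4g")
    print("\n== variance inflation (one-sided F-tests, secondary contact) ==")
    print(vt.to_string(index=False))

    # standardized linear model needs both recombination settings per scenario
    lm_frames = []
    for scen, grp in res.groupby("scenario"):
        if grp["recomb_factor_p2"].nunique() < 2 or grp["nem"].nunique() < 2:
            print(f"\n(standardized model skipped for {scen}: needs both "
                  "recombination settings and several Nem levels)")
            continue
        lm_frames.append(ex.standardized_lm(grp))
    if lm_frames:
        lm = pd.concat(lm_frames, ignore_index=True)
        lm.to_csv(args.out_dir / "standardized_lm.tsv", sep="\t", index=False,
                  float_format="%.4g")
        print("\n== standardized fixed-effect coefficients ==")
        print(lm[["scenario", "term", "coef", "se", "t", "p"]].to_string(index=False))


if __name__ == "__main__":
    main()
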