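#!/usr/bin/env python
"""Reduce the 28 crest descriptors by the three selection strategies.

Loads results/feature_table.csv (from 02_extract_features.py), runs SKB
(mutual-information top 10), RFE (forest-driven recursive elimination with
5-fold CV) and SFM (mean-importance threshold), and writes the crest-by-
method selection matrix to results/selection_table.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from raman_rice.classify import ForestConfig
from raman_rice.selection import initial_select, rfe_select, select_k_best, selection_table, sfm_select

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    table = pd.read_csv(ROOT / "results" / "feature_table.csv")
    results = [
        initial_select(table),
        select_k_best(table, k=10),
        rfe_select(table, forest=ForestConfig(n_trees=50, seed=args.seed),
                   cv_folds=5, seed=args.seed),
        sfm_select(table, forest=ForestConfig(n_trees=100, seed=args.seed), seed=args.seed),
    ]
    out = ROOT / "results" / "selection_table.csv"
    selection_table(results).to_csv(out, index=False)
    for r in results:
        print(f"{r.method:7s}: {r.n_selected:2d}/28 features "
              f"({r.feature_select_rate}%), crest coverage {r.crest_select_rate}%")
    print(f"selection matrix -> {out}")


if __name__ == "__main__":
    main()
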