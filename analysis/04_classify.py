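#!/usr/bin/env python
"""Fit the two discriminant models on each selected feature set.

Splits the feature table 7:3 (stratified, 156 -> 109 train / 47 test),
fits the logistic regression and the Gini/CART random forest on the columns
retained by each selector, and writes the selector x model accuracy grid to
results/accuracy_grid.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from raman_rice.classify import ForestConfig, evaluate_grid, train_test_split
from raman_rice.selection import initial_select, rfe_select, select_k_best, sfm_select

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    table = pd.read_csv(ROOT / "results" / "feature_table.csv")
    split = train_test_split(table, 0.7, seed=args.seed)
    print(f"split: {split.train_index.size} train / {split.test_index.size} test")
    selectors = {
        "Initial": initial_select,
        "SKB": lambda t: select_k_best(t, k=10),
        "RFE": lambda t: rfe_select(t, forest=ForestConfig(n_trees=50, seed=args.seed),
                                    cv_folds=5, seed=args.seed),
        "SFM": lambda t: sfm_select(t, forest=ForestConfig(n_trees=100, seed=args.seed),
                                    seed=args.seed),
    }
    grid = evaluate_grid(table, selectors, split,
                         forest=ForestConfig(n_trees=100, seed=args.seed))
    out = ROOT / "results" / "accuracy_grid.csv"
    grid.to_csv(out, index=False)
    print(grid.to_string(index=False))
    print(f"accuracy grid -> {out}")


if __name__ == "__main__":
    main()
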