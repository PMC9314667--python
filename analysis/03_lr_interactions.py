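"""Score state-pair ligand-receptor interactions against the permutation null.

Integrates the per-resource pair tables (support >= 2), applies the >20%
expressed rule, scores every pair x sender-state x receiver-state combination
in both directions, and assigns empirical p-values from 1,000 within-
compartment label permutations.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from statecrosstalk.io import cpm_normalize, read_cell_meta, read_expression
from statecrosstalk.lrcomm import integrate_pairs, permutation_test, summarize_network
from statecrosstalk.states import StateAssignment


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path, default=Path("results/analysis/data"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--n-perm", type=int, default=1000)
    args = ap.parse_args()

    meta = read_cell_meta(args.data / "cell_meta.tsv")
    x = cpm_normalize(read_expression(args.data / "counts.mtx", args.data / "genes.tsv",
                                      args.data / "cells.tsv", layer="counts",
                                      cell_meta=meta))
    labels = pd.read_csv(args.out / "state_assignment.tsv", sep="\t",
                         index_col="cell_id")["state"]
    assign = StateAssignment(labels=labels.loc[list(x.cell_ids)], k=labels.nunique())

    res_df = pd.read_csv(args.data / "pair_resources.tsv", sep="\t")
    tables = [list(zip(sub["ligand"], sub["receptor"]))
              for _, sub in res_df.groupby("resource")]
    pairs = integrate_pairs(tables, min_support=2)
    print(f"{len(pairs)} ligand-receptor pairs supported by >= 2 resources")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = permutation_test(x, assign, pairs, n_perm=args.n_perm,
                                   seed=args.seed)
    counts, edges = summarize_network(results, p_max=0.05)
    results.to_csv(args.out / "lr_interactions.tsv", sep="\t", index=False)
    counts.to_csv(args.out / "lr_network_counts.tsv", sep="\t", index=False)
    edges.to_csv(args.out / "lr_network_edges.tsv", sep="\t", index=False)

    print(f"{len(edges)} significant interactions at p < 0.05 "
          f"({args.n_perm} permutations)")
    top = counts.sort_values("n_significant", ascending=False).head(5)
    print("busiest directed state pairs:")
    for _, row in top.iterrows():
        print(f"  {row['sender_state']:>18} -> {row['receiver_state']:<14} "
              f"({row['direction']}): {row['n_significant']}")


if __name__ == "__main__":
    main()
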