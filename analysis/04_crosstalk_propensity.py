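"""Test crosstalk propensity between tumor and CD8 states via shared ligands.

For each signaling direction, finds state-related ligands on the sender side
(expression vs signature score) and receiver side (predicted ligand activity
vs signature score), then asks, per (tumor state, CD8 state), whether the two
related-ligand sets overlap more than a hypergeometric draw explains
(p < 0.001). A within-compartment label shuffle serves as negative control,
and the TF-ligand-receptor-TF chains are assembled for the implicated pair.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from statecrosstalk.io import cpm_normalize, filter_low_genes, read_cell_meta, \
    read_expression
from statecrosstalk.lrcomm import integrate_pairs
from statecrosstalk.propensity import LigandTargetPrior, assemble_chains, propensity_scan
from statecrosstalk.states import StateAssignment, differential_signature, signature_sets


def load_world(args):
    meta = read_cell_meta(args.data / "cell_meta.tsv")
    x = cpm_normalize(read_expression(args.data / "counts.mtx", args.data / "genes.tsv",
                                      args.data / "cells.tsv", layer="counts",
                                      cell_meta=meta))
    labels = pd.read_csv(args.out / "state_assignment.tsv", sep="\t",
                         index_col="cell_id")["state"]
    prior = LigandTargetPrior(pd.read_csv(args.data / "prior.tsv", sep="\t", index_col=0))
    res_df = pd.read_csv(args.data / "pair_resources.tsv", sep="\t")
    pairs = integrate_pairs([list(zip(s["ligand"], s["receptor"]))
                             for _, s in res_df.groupby("resource")])
    sig_t = signature_sets(pd.read_csv(args.out / "signatures_tumor.tsv", sep="\t"))
    sig_c = signature_sets(pd.read_csv(args.out / "signatures_cd8.tsv", sep="\t"))
    return x, labels, prior, pairs, sig_t, sig_c


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path, default=Path("results/analysis/data"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    x, labels, prior, pairs, sig_t, sig_c = load_world(args)
    assign = StateAssignment(labels=labels.loc[list(x.cell_ids)], k=labels.nunique())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grid, assoc = propensity_scan(sig_t, sig_c, x, assign, prior, pairs)
    grid.to_csv(args.out / "crosstalk_grid.tsv", sep="\t", index=False)
    assoc.to_csv(args.out / "ligand_state_associations.tsv", sep="\t", index=False)

    hits = grid[grid["significant"]]
    print(f"crosstalk grid: {len(grid)} cells "
          f"(tumor states x CD8 states x 2 directions)")
    for _, r in hits.iterrows():
        print(f"  HIT {r['tumor_state']} x {r['cd8_state']} ({r['direction']}): "
              f"k={r['k']} shared of N={r['N']}, p = {r['p_hyper']:.2e}")
    if hits.empty:
        print("  no state pair passed p < 0.001")

    # negative control: shuffle labels within compartments, re-derive signatures
    rng = np.random.default_rng(args.seed + 10_000)
    shuffled = labels.copy()
    for comp in ("tumor", "cd8"):
        idx = x.cell_meta.index[x.cell_meta["compartment"] == comp]
        shuffled.loc[idx] = rng.permutation(shuffled.loc[idx].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xt = filter_low_genes(x.compartment("tumor"))
        xc = filter_low_genes(x.compartment("cd8"))
        st = signature_sets(differential_signature(
            xt, StateAssignment(shuffled.loc[list(xt.cell_ids)], k=4)))
        sc = signature_sets(differential_signature(
            xc, StateAssignment(shuffled.loc[list(xc.cell_ids)], k=3)))
        null_grid, _ = propensity_scan(
            st, sc, x, StateAssignment(shuffled.loc[list(x.cell_ids)], k=7),
            prior, pairs)
    print(f"label-shuffled control: {int(null_grid['significant'].sum())} hits "
          f"(min p = {null_grid['p_hyper'].min():.3g})")

    tf_ligand = args.data / "tf_ligand.tsv"
    if not tf_ligand.exists():
        # demo link tables: wire the planted circuit ligands through their pairs
        best = grid.loc[grid["p_hyper"].idxmin()]
        shared = best["shared_ligands"].split(",") if best["shared_ligands"] else []
        pair_map = {p.ligand: p.receptor for p in pairs}
        pd.DataFrame({"tf": f"TF_{best['tumor_state']}_1", "ligand": shared}).to_csv(
            tf_ligand, sep="\t", index=False)
        pd.DataFrame({"ligand": shared, "receptor": [pair_map[l] for l in shared],
                      "tf": f"TF_{best['cd8_state']}_ds"}).to_csv(
            args.data / "lig_rec_tf.tsv", sep="\t", index=False)
    chains = assemble_chains(pd.read_csv(tf_ligand, sep="\t"),
                             pd.read_csv(args.data / "lig_rec_tf.tsv", sep="\t"))
    chains.to_csv(args.out / "signal_chains.tsv", sep="\t", index=False)
    print(f"{len(chains)} TF-ligand-receptor-TF chains assembled")


if __name__ == "__main__":
    main()
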