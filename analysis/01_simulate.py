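"""Generate the synthetic melanoma-like world every later step analyses.

Writes the single-cell counts (Matrix Market + name files), cell metadata with
true compartments/states, regulon and marker GMTs, the ligand-target prior,
and the per-resource ligand-receptor tables under results/analysis/data/.
"""

import argparse
from pathlib import Path

import pandas as pd

from statecrosstalk.io import write_cell_meta, write_expression, write_gene_sets
from statecrosstalk.synth import (SimConfig, simulate_pair_resources, simulate_prior,
                                  simulate_sc)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/analysis/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=args.seed)
    x, truth, regulons, markers = simulate_sc(cfg)
    write_expression(x, args.out / "counts.mtx", args.out / "genes.tsv",
                     args.out / "cells.tsv")
    write_cell_meta(x.cell_meta, args.out / "cell_meta.tsv")
    write_gene_sets(regulons, args.out / "regulons.gmt")
    write_gene_sets(markers, args.out / "markers.gmt")
    simulate_prior(cfg).potential.rename_axis("ligand").to_csv(
        args.out / "prior.tsv", sep="\t")
    rows = [(l, r, i + 1) for i, tab in enumerate(simulate_pair_resources(cfg))
            for l, r in tab]
    pd.DataFrame(rows, columns=["ligand", "receptor", "resource"]).to_csv(
        args.out / "pair_resources.tsv", sep="\t", index=False)

    comp = x.cell_meta["compartment"].value_counts()
    print(f"simulated {x.n_genes} genes x {x.n_cells} cells "
          f"({comp['tumor']} tumor, {comp['cd8']} CD8) at seed {args.seed}")
    print(f"planted circuit: {truth.circuit_sender} -> {truth.circuit_receiver} "
          f"({len(truth.circuit_ligand_genes)} ligands)")
    print(f"inputs written to {args.out}")


if __name__ == "__main__":
    main()
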