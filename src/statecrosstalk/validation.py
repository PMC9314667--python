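"""Planted-truth validation experiments shared by the test suite and drivers.

These routines run the genuine analysis path (simulate -> preprocess -> state
inference -> signatures -> crosstalk scan) on a reduced synthetic world small
enough to repeat across many seeds: 1,000 genes and 30 cells per state instead
of the default 2,000 x 50, and a lighter consensus (n_runs configurable). The
reduction is a compute budget choice; effect sizes and thresholds are the
defaults of the stated world.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .io import cpm_normalize, filter_low_genes
from .propensity import propensity_scan
from .states import (StateAssignment, annotate_states, assign_by_markers, aucell_score,
                     consensus_kmeans, differential_signature, maxdiff_scale,
                     signature_sets)
from .synth import SimConfig, shuffled_assignment, simulate_prior, simulate_sc, true_pairs

SMALL_WORLD = dict(n_genes=1000, cells_per_state=30, regulons_per_state=3,
                   targets_per_regulon=12, markers_per_state=12, n_ligands=40,
                   targets_per_ligand=8)


def small_config(seed: int, **overrides) -> SimConfig:
    params = {**SMALL_WORLD, **overrides}
    return SimConfig(seed=seed, **params)


def regulon_reference(regulons) -> dict[str, list[str]]:
    """state -> regulon names, from the ``regulon_<state>_<i>`` convention."""
    ref: dict[str, list[str]] = {}
    for r in regulons:
        state = r.name.replace("regulon_", "").rsplit("_", 1)[0]
        ref.setdefault(state, []).append(r.name)
    return ref


def infer_states(x_tumor, x_cd8, regulons, markers, k: int = 4, n_runs: int = 200,
                 top_frac: float = 0.05, seed: int = 0):
    """Tumor consensus clustering + annotation and CD8 marker argmax."""
    act = maxdiff_scale(aucell_score(x_tumor, regulons, top_frac=top_frac, seed=seed))
    clusters = consensus_kmeans(act, k=k, n_runs=n_runs, seed=seed)
    tumor_assign, _ = annotate_states(clusters, act, regulon_reference(regulons))
    cd8_assign = assign_by_markers(
        x_cd8, {m.name.replace("markers_", ""): m.genes for m in markers})
    return tumor_assign, cd8_assign


def crosstalk_recovery(seed: int, shuffle: bool = False, n_runs: int = 30,
                       use_true_labels: bool = False, **world_overrides) -> dict:
    """One end-to-end crosstalk-propensity run against planted truth.

    With ``shuffle`` the state labels are permuted once within each compartment
    before signatures and the scan — the negative control. Returns the grid,
    the planted grid cell, and whether it is the unique significant hit.
    """
    cfg = small_config(seed, **world_overrides)
    x, truth, regulons, markers = simulate_sc(cfg)
    cpm = cpm_normalize(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        x_tumor = filter_low_genes(cpm.compartment("tumor"))
        x_cd8 = filter_low_genes(cpm.compartment("cd8"))
        if shuffle:
            labels = shuffled_assignment(truth, seed + 10_000)
            tumor_assign = StateAssignment(labels.loc[list(x_tumor.cell_ids)],
                                           k=len(cfg.tumor_states))
            cd8_assign = StateAssignment(labels.loc[list(x_cd8.cell_ids)],
                                         k=len(cfg.cd8_states))
        elif use_true_labels:
            labels = truth.cell_states
            tumor_assign = StateAssignment(labels.loc[list(x_tumor.cell_ids)],
                                           k=len(cfg.tumor_states))
            cd8_assign = StateAssignment(labels.loc[list(x_cd8.cell_ids)],
                                         k=len(cfg.cd8_states))
        else:
            tumor_assign, cd8_assign = infer_states(x_tumor, x_cd8, regulons, markers,
                                                    n_runs=n_runs, seed=seed)
            labels = pd.concat([tumor_assign.labels, cd8_assign.labels])
        sig_tumor = signature_sets(differential_signature(x_tumor, tumor_assign))
        sig_cd8 = signature_sets(differential_signature(x_cd8, cd8_assign))
        kept = [g for g in cpm.gene_names
                if g in set(x_tumor.gene_names) | set(x_cd8.gene_names)]
        x_all = cpm.subset_genes(kept)
        assign = StateAssignment(labels.loc[list(x_all.cell_ids)],
                                 k=len(cfg.tumor_states) + len(cfg.cd8_states))
        grid, assoc = propensity_scan(sig_tumor, sig_cd8, x_all, assign,
                                      simulate_prior(cfg), true_pairs(cfg))
    hits = grid[grid["significant"]]
    planted = grid[(grid["direction"] == truth.circuit_direction)
                   & (grid["tumor_state"] == truth.circuit_sender)
                   & (grid["cd8_state"] == truth.circuit_receiver)]
    planted_p = float(planted["p_hyper"].iloc[0]) if len(planted) else 1.0
    unique_hit = (len(hits) == 1 and len(planted) == 1
                  and bool(planted["significant"].iloc[0]))
    return {"grid": grid, "associations": assoc, "n_hits": int(len(hits)),
            "planted_p": planted_p, "unique_planted_hit": unique_hit,
            "truth": truth, "config": cfg}
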