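"""Stage orchestration: run the whole analysis reproducibly from one config.

Stages: simulate (optional) -> preprocess (CPM + per-compartment gene filter)
-> states (AUCell + consensus k-means for tumor, marker argmax for CD8,
differential signatures) -> lrscan (pair integration + permutation test) ->
propensity (ligand activities, state-related ligands, shared-ligand grid,
TF-ligand-receptor-TF chains) -> cohort (pseudobulk ssGSEA, Cox/KM, risk
groups, Fisher). Every stage writes TSVs under the run directory and the run
ends with a manifest recording parameters, seed and per-file checksums, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (ExpressionMatrix, GeneSet, Regulon, cpm_normalize, filter_low_genes,
                 read_cell_meta, read_expression, read_gene_sets, write_cell_meta,
                 write_expression, write_gene_sets)
from .lrcomm import integrate_pairs, pairs_frame, permutation_test, summarize_network
from .propensity import LigandTargetPrior, assemble_chains, propensity_scan
from .states import (StateAssignment, assign_by_markers, annotate_states, aucell_score,
                     consensus_kmeans, differential_signature, maxdiff_scale,
                     signature_sets)
from .synth import SimConfig, simulate_cohort, simulate_pair_resources, simulate_prior, \
    simulate_sc
from . import cohort as cohort_mod


@dataclass
class PipelineConfig:
    """All stage parameters, with the published defaults."""

    out_dir: str = "results/run"
    seed: int = 0
    simulate: bool = True
    # input paths, used when simulate is off
    path_matrix: str = ""
    path_genes: str = ""
    path_cells: str = ""
    path_meta: str = ""
    path_regulons: str = ""
    path_markers: str = ""
    path_pairs: str = ""
    path_prior: str = ""
    path_tf_ligand: str = ""
    path_lig_rec_tf: str = ""
    # synthetic-world scale
    n_genes: int = 2000
    cells_per_state: int = 50
    n_samples: int = 200
    hr_per_unit: float = 0.5
    censor_rate: float = 0.01
    # stage parameters (published defaults of the procedure)
    filter_min_frac: float = 0.10
    top_frac: float = 0.05
    k: int = 4
    n_runs: int = 200          # demo profile; the full-fidelity value is 1000
    logfc_min: float = 0.25
    fdr_max: float = 0.05
    min_support: int = 2
    expressed_min_frac: float = 0.20
    n_perm: int = 1000
    p_max: float = 0.05
    alpha_crosstalk: float = 0.001
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True   # GSVA-style min-max across the cohort
    cohort_tumor_state: str = "intermediate"
    cohort_cd8_state: str = "exhausted"

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (t.strip() for t in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            t = types[key]
            if t in ("bool", bool):
                kwargs[key] = val.lower() in ("1", "true", "yes", "on")
            elif t in ("int", int):
                kwargs[key] = int(val)
            elif t in ("float", float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


STAGES = ("simulate", "preprocess", "states", "lrscan", "propensity", "cohort")


def run_pipeline(config: PipelineConfig, log=print) -> Path:
    """Execute every stage; returns the run directory containing the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df, name, index=True):
        p = out / name
        _write_tsv(df, p, index=index)
        written.append(p)
        return p

    # ---- simulate / load -------------------------------------------------
    if config.simulate:
        log("[simulate] generating synthetic single-cell data")
        sim = SimConfig(n_genes=config.n_genes, cells_per_state=config.cells_per_state,
                        seed=config.seed)
        x_counts, truth, regulons, markers = simulate_sc(sim)
        resources = simulate_pair_resources(sim)
        prior = simulate_prior(sim)
        write_expression(x_counts, out / "counts.mtx", out / "genes.tsv", out / "cells.tsv")
        written += [out / "counts.mtx", out / "genes.tsv", out / "cells.tsv"]
        write_cell_meta(x_counts.cell_meta, out / "cell_meta.tsv")
        written.append(out / "cell_meta.tsv")
        write_gene_sets(regulons, out / "regulons.gmt")
        write_gene_sets(markers, out / "markers.gmt")
        written += [out / "regulons.gmt", out / "markers.gmt"]
        save(prior.potential.rename_axis("ligand"), "prior.tsv")
        pair_rows = [(l, r, i + 1) for i, tab in enumerate(resources) for l, r in tab]
        save(pd.DataFrame(pair_rows, columns=["ligand", "receptor", "resource"]),
             "pair_resources.tsv", index=False)
        # demo link tables wired through the planted circuit
        tf_ligand = pd.DataFrame({
            "tf": f"TF_{truth.circuit_sender}_1", "ligand": truth.circuit_ligand_genes})
        lig_rec_tf = pd.DataFrame({
            "ligand": truth.circuit_ligand_genes,
            "receptor": truth.circuit_receptor_genes,
            "tf": f"TF_{truth.circuit_receiver}_ds",
        })
        save(tf_ligand, "tf_ligand.tsv", index=False)
        save(lig_rec_tf, "lig_rec_tf.tsv", index=False)
        resources_tables = resources
    else:
        for key in ("path_matrix", "path_meta", "path_regulons", "path_markers",
                    "path_pairs", "path_prior"):
            p = getattr(config, key)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{key} = {p!r} does not exist")
        log("[simulate] skipped; loading inputs")
        meta = read_cell_meta(config.path_meta)
        x_counts = read_expression(config.path_matrix, config.path_genes or None,
                                   config.path_cells or None, layer="counts",
                                   cell_meta=meta)
        truth = None
        regulons = [r for r in read_gene_sets(config.path_regulons) if isinstance(r, Regulon)]
        markers = [m for m in read_gene_sets(config.path_markers, as_regulons=False)]
        prior_df = pd.read_csv(config.path_prior, sep="\t", index_col=0)
        prior = LigandTargetPrior(prior_df)
        res_df = pd.read_csv(config.path_pairs, sep="\t")
        resources_tables = [
            list(zip(sub["ligand"], sub["receptor"]))
            for _, sub in res_df.groupby("resource")
        ]
        tf_ligand = (pd.read_csv(config.path_tf_ligand, sep="\t")
                     if config.path_tf_ligand else None)
        lig_rec_tf = (pd.read_csv(config.path_lig_rec_tf, sep="\t")
                      if config.path_lig_rec_tf else None)

    # ---- preprocess ------------------------------------------------------
    log("[preprocess] CPM normalization and per-compartment gene filter")
    cpm = cpm_normalize(x_counts)
    x_tumor = filter_low_genes(cpm.compartment("tumor"), config.filter_min_frac)
    x_cd8 = filter_low_genes(cpm.compartment("cd8"), config.filter_min_frac)
    kept = [g for g in cpm.gene_names
            if g in set(x_tumor.gene_names) | set(x_cd8.gene_names)]
    x_all = cpm.subset_genes(kept)
    log(f"[preprocess] kept {len(x_tumor.gene_names)} tumor / "
        f"{len(x_cd8.gene_names)} cd8 genes ({len(kept)} union)")

    # ---- states ----------------------------------------------------------
    log("[states] AUCell + consensus k-means (tumor), marker argmax (cd8)")
    act = aucell_score(x_tumor, regulons, top_frac=config.top_frac, seed=config.seed)
    act_scaled = maxdiff_scale(act)
    clusters = consensus_kmeans(act_scaled, k=config.k, n_runs=config.n_runs,
                                seed=config.seed)
    reference = {}
    for r in regulons:
        state = r.name.replace("regulon_", "").rsplit("_", 1)[0]
        reference.setdefault(state, []).append(r.name)
    tumor_assign, score_matrix = annotate_states(clusters, act_scaled, reference)
    cd8_assign = assign_by_markers(
        x_cd8, {m.name.replace("markers_", ""): m.genes for m in markers})
    labels = pd.concat([tumor_assign.labels, cd8_assign.labels])
    assign = StateAssignment(labels=labels.loc[list(x_all.cell_ids)],
                             k=config.k + len(markers))
    save(labels.rename("state").to_frame(), "state_assignment.tsv")
    save(score_matrix.rename_axis("state"), "annotation_scores.tsv")
    sig_tumor_tab = differential_signature(x_tumor, tumor_assign, config.logfc_min,
                                           config.fdr_max)
    sig_cd8_tab = differential_signature(x_cd8, cd8_assign, config.logfc_min,
                                         config.fdr_max)
    save(sig_tumor_tab, "signatures_tumor.tsv", index=False)
    save(sig_cd8_tab, "signatures_cd8.tsv", index=False)
    signatures_tumor = signature_sets(sig_tumor_tab)
    signatures_cd8 = signature_sets(sig_cd8_tab)

    # ---- lrscan ----------------------------------------------------------
    log("[lrscan] integrating pairs and running the permutation test")
    pairs = integrate_pairs(resources_tables, min_support=config.min_support)
    log(f"[lrscan] {len(pairs)} integrated pairs (support >= {config.min_support})")
    save(pairs_frame(pairs), "pairs_integrated.tsv", index=False)
    results = permutation_test(x_all, assign, pairs, n_perm=config.n_perm,
                               seed=config.seed, min_frac=config.expressed_min_frac)
    save(results, "lr_interactions.tsv", index=False)
    counts, edges = summarize_network(results, p_max=config.p_max)
    save(counts, "lr_network_counts.tsv", index=False)
    save(edges, "lr_network_edges.tsv", index=False)
    log(f"[lrscan] {len(edges)} significant pair x state-pair interactions "
        f"(p < {config.p_max})")

    # ---- propensity ------------------------------------------------------
    log("[propensity] state-related ligands and shared-ligand grid")
    grid, assoc = propensity_scan(signatures_tumor, signatures_cd8, x_all, assign,
                                  prior, pairs, min_frac=config.expressed_min_frac,
                                  fdr_max=config.fdr_max, alpha=config.alpha_crosstalk)
    save(grid, "crosstalk_grid.tsv", index=False)
    save(assoc, "ligand_state_associations.tsv", index=False)
    hits = grid[grid["significant"]]
    for _, row in hits.iterrows():
        log(f"[propensity] crosstalk hit: {row['tumor_state']} x {row['cd8_state']} "
            f"({row['direction']}), p = {row['p_hyper']:.2e}, k = {row['k']}")
    if tf_ligand is not None and lig_rec_tf is not None:
        chains = assemble_chains(tf_ligand, lig_rec_tf)
        save(chains, "signal_chains.tsv", index=False)

    # ---- cohort ----------------------------------------------------------
    log("[cohort] pseudobulk ssGSEA, survival and risk groups")
    if config.simulate:
        bulk, clinical = simulate_cohort(x_all, truth, n_samples=config.n_samples,
                                         hr_per_unit=config.hr_per_unit,
                                         censor_rate=config.censor_rate,
                                         seed=config.seed + 3)
        save(clinical, "cohort_clinical.tsv")
    else:
        log("[cohort] skipped: cohort stage requires the synthetic world or "
            "external bulk inputs")
        return _finish(out, config, written, log)
    sets = []
    for name, genes in (("intermediate_signature",
                         signatures_tumor.get(config.cohort_tumor_state, [])),
                        ("exhausted_signature",
                         signatures_cd8.get(config.cohort_cd8_state, []))):
        genes = [g for g in genes if g in set(bulk.gene_names)]
        if len(genes) >= 2:
            sets.append(GeneSet(name, tuple(genes)))
    if len(sets) < 2:
        log("[cohort] warning: empty inferred signatures; falling back to planted sets")
        sets = [GeneSet("intermediate_signature",
                        tuple(truth.signature_genes[config.cohort_tumor_state])),
                GeneSet("exhausted_signature",
                        tuple(truth.signature_genes[config.cohort_cd8_state]))]
    scores = cohort_mod.ssgsea_score(bulk, sets, alpha=config.ssgsea_alpha,
                                     normalize=config.ssgsea_normalize)
    save(scores, "ssgsea_scores.tsv")
    surv_rows = []
    for col in scores.columns:
        res = cohort_mod.survival_assoc(scores[col], clinical["time"], clinical["event"])
        surv_rows.append({"score": col, **{k: v for k, v in res.items() if k != "CI95"},
                          "ci_lo": res["CI95"][0], "ci_hi": res["CI95"][1]})
        log(f"[cohort] {col}: HR = {res['HR']:.3g} "
            f"({res['CI95'][0]:.3g}-{res['CI95'][1]:.3g}), cox p = {res['wald_p']:.3g}, "
            f"log-rank p = {res['logrank_p']:.3g}")
    inter = cohort_mod.survival_assoc(scores.iloc[:, 0], clinical["time"],
                                      clinical["event"], second_scores=scores.iloc[:, 1])
    surv_rows.append({"score": "interaction",
                      **{k: v for k, v in inter.items() if k != "CI95"},
                      "ci_lo": inter["CI95"][0], "ci_hi": inter["CI95"][1]})
    save(pd.DataFrame(surv_rows), "survival_assoc.tsv", index=False)
    groups, medians = cohort_mod.risk_groups(scores.iloc[:, 0], scores.iloc[:, 1])
    save(groups.rename("risk_group").to_frame(), "risk_groups.tsv")
    fisher = cohort_mod.categorical_assoc(groups, clinical["mutation"])
    log(f"[cohort] risk-group x mutation {fisher['test']} p = {fisher['p']:.3g}")
    save(fisher["table"], "risk_mutation_table.tsv")
    km = cohort_mod.km_curve_data(clinical["time"], clinical["event"], groups)
    save(km, "km_curves.tsv", index=False)
    return _finish(out, config, written, log)


def _finish(out: Path, config: PipelineConfig, written: list[Path], log) -> Path:
    manifest = {
        "package": "statecrosstalk",
        "version": __version__,
        "stages": list(STAGES),
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "checksums": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log(f"[done] run directory: {out}")
    return out
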