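# statecrosstalk

Tumor cells and tumor-infiltrating CD8+ T cells occupy discrete transcriptional
states — melanoma tumor cells range from melanocytic through intermediate to
mesenchymal-like programs, while CD8+ T cells progress from naive through
transitional to exhausted phenotypes — and they talk to each other through
ligand–receptor signaling. `statecrosstalk` asks a specific question of
single-cell expression data: **is cell–cell communication biased toward
particular state pairs**, and does the abundance of the implicated states
carry prognostic information in bulk cohorts?

The package implements the full chain of analyses, exercised end-to-end on a
synthetic world with planted ground truth:

1. **State inference.** Regulon activities per tumor cell by AUCell — the
   normalized area under the recovery curve of the regulon's targets among the
   cell's top-ranked genes, `AUC = Σ_{r≤T} hits(r) / max`, with `T` the top 5%
   of genes — min–max ("maximum difference") scaled, then consensus-clustered:
   many randomly initialized k-means runs aggregated into a co-clustering
   matrix, cut by average linkage at `k = 4`. CD8 states are called by
   canonical-marker argmax. Per-state signatures come from one-vs-rest
   Wilcoxon rank-sum screens (`logFC > 0.25`, BH `FDR < 0.05`).
2. **Ligand–receptor scoring.** Pairs supported by ≥ 2 annotation resources;
   a gene is *expressed* in a state when > 20% of its cells are positive
   (unexpressed genes are zeroed); the score of pair (L, R) from state A to
   state B is `mean(L | A) · mean(R | B)`; empirical p-values from 1,000
   permutations of state labels within the tumor and CD8 compartments.
3. **Crosstalk propensity.** Per signaling direction, a ligand is *related*
   to a sender state when its expression correlates with the state's signature
   score across sender cells (Pearson, BH FDR < 0.05, r > 0), and to a
   receiver state when its predicted activity — the correlation of a
   ligand→target regulatory-potential row with each receiver cell's binary
   expressed-gene indicator — does the same. For each (tumor state, CD8
   state), the overlap `k` of the two related-ligand sets is tested against
   Hypergeometric(N, K, n) drawn from the tested ligand universe:
   `p = P(X ≥ k)`, called at `p < 0.001`. TF–ligand–receptor–TF chains are
   assembled by joining link tables on shared ligands.
4. **Cohort propagation.** Bulk samples scored for state abundance by ssGSEA
   (rank-weighted running sum, `α = 0.25`); Cox proportional-hazards fits on
   the scores and on their multiplicative interaction; Kaplan–Meier/log-rank
   on median splits; dual-median risk groups (low risk = above the median on
   *both* scores) tested against categorical features by Fisher's exact test.

The synthetic generator (`statecrosstalk.synth`) plants all of this:
negative-binomial counts, state-specific regulon/marker over-expression with
per-cell latent intensity, an 8-ligand circuit wiring the tumor intermediate
state to the CD8 exhausted state, and pseudobulk cohorts whose exponential
survival has log-hazard linear in the planted states' abundance.

## Worked example

```sh
python analysis/01_simulate.py --seed 0
python analysis/02_cell_states.py --seed 0
python analysis/03_lr_interactions.py --seed 0
python analysis/04_crosstalk_propensity.py --seed 0
python analysis/05_cohort_survival.py --seed 0
```

produces (abridged):

```
simulated 2000 genes x 350 cells (200 tumor, 150 CD8) at seed 0
planted circuit: intermediate -> exhausted (8 ligands)
tumor consensus clustering (k=4, 200 runs): ARI vs planted states = 0.920
CD8 marker-argmax annotation accuracy = 0.960
60 ligand-receptor pairs supported by >= 2 resources
89 significant interactions at p < 0.05 (1000 permutations)
crosstalk grid: 24 cells (tumor states x CD8 states x 2 directions)
  HIT intermediate x exhausted (tumor->cd8): k=8 shared of N=58, p = 5.22e-10
label-shuffled control: 0 hits (min p = 1)
intermediate_signature: HR = 0.655 [0.282, 1.52], cox p = 0.325, log-rank p = 0.524
```

Reading: state inference recovers the planted partition (ARI 0.92); the
permutation scan finds the intermediate → exhausted direction busiest; the
propensity grid flags exactly the planted (intermediate, exhausted,
tumor→cd8) cell — all 8 circuit ligands are related to both sides, an overlap
a hypergeometric draw from the 58-ligand universe essentially never produces —
and the shuffled control flags nothing. The cohort Cox fit points protective
(HR < 1) but is under-powered at 200 samples with a planted hazard ratio of
0.5 per unit abundance; the parameter-recovery tests in
`tests/test_acceptance.py` quantify coverage properly over 100 seeds.

The same run is available as one command (`statecrosstalk run --seed 0
--out results/run`) or from a config file (`statecrosstalk run --config
my_run.cfg`); every stage writes TSVs plus a manifest with parameter values
and per-file checksums, and a rerun with the same config is byte-identical.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch at the given seed (all stages, default
scale) with intermediate tables under `results/acceptance_run/`, and writes
the results JSON to the requested path.
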