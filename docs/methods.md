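# Methods

This note records the models, the parameter choices that matter, the design
decisions taken where the procedure was genuinely open, and what the synthetic
world does and does not establish.

## Expression model and preprocessing

Expression lives in a genes × cells container with a layer tag: raw `counts`,
`cpm` (each cell scaled to a library of 10⁶), or `lognorm`
(`log(1 + CPM/100)`, used only where correlation statistics benefit from
variance stabilization). Gene identifiers are opaque, case-sensitive strings;
no symbol aliasing is attempted. Matrix Market indices are 1-based on disk,
0-based in memory.

Low-expression filtering drops genes positive in **less than** 10% of cells —
a gene at exactly 10% is kept — and is applied per compartment (tumor and CD8
separately), so the two compartments can retain different gene sets.
"Expressed" means strictly `> 0` on the stored layer throughout the package;
no other detection threshold is defined anywhere in the procedure, so one
convention is used uniformly.

## Tumor state inference

**AUCell.** Genes are ranked per cell by descending expression; ties are
broken by a single seeded permutation of gene order applied before a stable
sort, so ranks are deterministic and identical across gene sets. With
`T = ceil(top_frac · n_genes)` (default `top_frac = 0.05`, exposed because the
canonical threshold is a convention, not a derivation), the raw AUC is
`Σ_{r=1..T} hits(r)`; it is normalized by the AUC of a set whose
`m = min(|set|, T)` genes occupy ranks 1..m, giving values in [0, 1]. The
implementation is checked exactly against a per-rank recovery-curve loop.

**Scaling.** "Maximum difference normalization" is read as per-regulon
min–max scaling (the range *is* the maximum difference). Constant rows map to
zeros with a warning rather than NaN.

**Consensus.** `n_runs` k-means partitions (random initialization, seeded;
demo profile 200 runs, full profile 1,000) are aggregated into
`consensus[i,j]` = co-clustering fraction; final labels cut an average-linkage
tree of `1 − consensus` at `k = 4` groups. Average linkage on the consensus
complement is the concrete choice behind the published heatmap-package
workflow; it is deterministic given the seed and stable under cell reordering
up to relabeling. Clusters are then renamed to the reference state whose
regulon set has the highest mean activity in them; the mapping may be
non-injective (warned), which is the honest outcome when two clusters express
the same program.

## CD8 state inference

CD8 states are assigned by marker-set argmax on per-gene min–max-scaled
expression rather than by re-running a graph-clustering backend: the
clustering internals are not reproducible bit-for-bit across toolkits, and
marker annotation is the step that defines the states used downstream. A hook
accepts externally computed cluster labels (any cell → label series can be
wrapped in a `StateAssignment`).

## Differential signatures

One-vs-rest per state: two-sided Wilcoxon rank-sum per gene (tie-corrected
asymptotic Mann–Whitney; genes constant across all cells short-circuit to
p = 1, since identical samples carry no evidence), log fold change
`ln((mean_in + 1)/(mean_out + 1))` on the stored layer (the natural-log,
pseudocount-1 convention; the upstream toolkit's base is unstated), BH
adjustment across genes within each state. The signature is the set with
`logFC > 0.25` and `FDR < 0.05`.

## Ligand–receptor permutation test

Pairs are deduplicated within each resource before support counting;
orientation matters. A ligand/receptor is expressed in a state when strictly
more than 20% of the state's cells are positive; unexpressed genes are zeroed,
so the score — `mean(ligand | sender state) × mean(receptor | receiver
state)` — can be exactly 0. Each permutation shuffles state labels within the
tumor compartment and within the CD8 compartment independently (both
re-shuffled every iteration), and the expressed masks are recomputed under the
permuted labels, since the labels define the mask. The default p-value is the
+1-corrected form `p = (1 + #{perm ≥ obs})/(1 + n_perm)` so that p ∈ (0, 1];
the literal "fraction larger than real" is available behind a flag
(`plus_one=False`). The significance threshold for counting network edges
defaults to p < 0.05 and is configurable.

## Crosstalk propensity

Per-cell ligand activity in receiver cells is the Pearson correlation of the
ligand's regulatory-potential row with the cell's **binary expressed-gene
indicator** over the shared target universe (≥ 10 shared targets required).
The binary indicator mirrors gene-set-vs-background activity prediction at
single-cell granularity; continuous-expression correlation is available via
`binary=False`. Cells with a constant indicator get activity 0 with a warning.

State-related ligands require BH FDR < 0.05 **and r > 0** within each
(state, side, direction) family: anti-correlated ligands would contaminate the
overlap that the hypergeometric test interprets as shared influence. A flag
admits negative associations.

The hypergeometric universe is the set of integrated-pair ligands expressed
(> 20% rule) in the sender compartment *and present in the prior* — the set
actually screened on both sides; a universe larger than what was tested would
inflate significance. `p = P(X ≥ k)` for X ~ Hypergeometric(N, K, n), flagged
at p < 0.001. States with empty signatures contribute empty related sets and
grid cells with p = 1. The function/TF-set variant substitutes the per-cell
correlate (mean marker expression on the CD8 side; mean regulon **activity**
on the tumor side when an activity matrix covering the sets is supplied,
since "TF set" activity is better captured by regulon activity than by TF
transcript level); with expression correlates and sets equal to the state
signatures it reproduces the state-based scan exactly, which is tested.

Signal chains are a plain inner join of TF→ligand and ligand→receptor→TF link
tables on the shared ligand, deduplicated. The upstream inference of those
tables (regulon discovery, multilayer network inference) is out of scope; the
package consumes their outputs.

## Cohort stage

ssGSEA walks each sample's genes in decreasing-expression order; in-set genes
accumulate weight `(n − r + 1)^α` with `r` the tie-averaged rank and
`α = 0.25`; out-set genes accumulate uniformly; the enrichment score is the
sum of running differences. The raw operation applies no cross-sample
rescaling; the pipeline's cohort stage min–max normalizes scores across the
cohort (the common implementation's default), which changes nothing rank-based
(median splits, risk groups) and only rescales Cox coefficients to a per-unit-
range interpretation.

Survival: Cox PH on the continuous score; the "synergy" model is
`score1 + score2 + score1·score2` with the interaction term reported.
Median-split groups (high ⇔ strictly above the median; ties go to low, so the
partition is deterministic) feed the Kaplan–Meier/log-rank comparison. Risk
groups: low risk ⇔ above the median on both scores. Categorical association
uses two-sided Fisher's exact on 2×2 tables and chi-squared otherwise.
Mutation-style comparisons reduce to this operation on caller-supplied binary
labels; no variant parsing is implemented.

## Synthetic world

Counts are negative binomial (`var = μ + d·μ²`, dispersion `d = 0.3`) with
lognormal library sizes (mean 5,000) — overdispersion and library variation
are the two first-order properties of droplet/plate counts. Four tumor states
(melanocytic, intermediate, neural-crest-like, mesenchymal-like; 3 regulons ×
15 targets each) and three CD8 states (naive, transitional, exhausted; 15
markers each), 50 cells per state. State genes are over-expressed by
`exp(logfc · z_c)` with `z_c ~ U(0.5, 1.5)` per cell and `logfc = ln 2`
(2-fold at the latent mean): the latent intensity gives within-state
variation, which is what lets the correlation screens fire rather than only
the state contrast. The planted circuit wires 8 ligands from the intermediate
state (ligand expression scales with the sender cells' latent intensity) to
the exhausted state (the ligands' prior targets and the partner receptors
scale with the receiver cells' latent intensity). The regulatory-potential
prior gives every ligand a designated target block at potential ≈ 1 over
|N(0, 0.1)| background. An 8-ligand circuit is the smallest that can reach
the p < 0.001 call: a single shared ligand cannot, hypergeometrically.

Pseudobulk cohorts draw Dirichlet(2) state fractions, average the CPM
profiles of a with-replacement cell mixture, and attach exponential survival
with log-hazard `log(hr) · (intermediate fraction + exhausted fraction)` over
baseline rate 0.02, with independent exponential censoring (default rate
0.01, ≈ one third censored) and a binary mutation label whose frequency rises
with the planted abundance.

What the generator does **not** emulate: real gene symbols, batch and donor
effects, dropout-rate/mean curves beyond NB sparsity, doublets, and
cross-sample technical variation in cohorts. A green end-to-end test
establishes that the statistics recover the structure they assume, at
realistic noise — not that the assumptions hold in any particular real
dataset.

## Numerical choices and degenerate inputs

- Permutation p-values never reach 0 (+1 correction); observed scores are
  seed-independent.
- Pearson p-values come from the t distribution on n − 2 df; |r| = 1 maps to
  p = 0; constant vectors are skipped with warnings, not silently dropped.
- Hypergeometric tails use the survival function at k − 1, verified against
  full combinatorial enumeration for all N ≤ 12.
- k-means uses a fresh random initialization per run with run seeds drawn
  from one generator, so consensus matrices are reproducible.
- Zero-total cells are an error naming the cell (CPM undefined), all-zero
  filter results warn, empty ligand universes warn and return p = 1 grids.

## Scale profiles

The demo profile (200 consensus runs, 2,000 genes, 350 cells, 1,000
permutations, 200 cohort samples) runs in seconds on one CPU; the
full-fidelity profile restores 1,000 consensus runs. Validation experiments
(`statecrosstalk.validation`) use a reduced world — 1,000 genes, 30 cells per
state, lighter consensus — so planted-recovery and calibration checks can
repeat across 50–100 seeds inside a test budget; effect sizes and thresholds
are never reduced, only problem size.

## Known limitations

- CD8 state calling by marker argmax will blur states that differ only in
  programs outside the marker sets; supplying external cluster labels is the
  remedy.
- The permutation null conditions on state sizes; very small states give
  coarse p-value grids.
- The cohort Cox fit on ssGSEA scores inherits measurement attenuation from
  pseudobulk mixing; parameter-recovery guarantees are stated for the true
  abundance covariate.
- Multi-subunit receptor complexes are not modeled; pairs are gene–gene.
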