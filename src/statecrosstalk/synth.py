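"""Synthetic single-cell and cohort data with planted ground truth.

The generator emulates the statistical structure the analysis stages assume:
negative-binomial counts with overdispersion and library-size variation,
state-specific regulon-target / marker over-expression driven by a per-cell
latent intensity, a planted ligand-receptor circuit wiring one tumor state to
one CD8+ T state (sender ligands and receiver responses share the latent
mechanism, so both the sender-side expression screen and the receiver-side
activity screen can fire), and pseudobulk cohorts whose proportional-hazards
survival is tied to the planted states' abundance.

Defaults mirror a small melanoma-like world: four tumor states (melanocytic,
intermediate, neural-crest-like, mesenchymal-like), three CD8 states (naive,
transitional, exhausted), 50 cells per state, 2-fold (ln 2) state
over-expression, and an 8-ligand intermediate -> exhausted circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, Regulon, cpm_normalize
from .lrcomm import LRPair
from .propensity import LigandTargetPrior

LN2 = float(np.log(2.0))


@dataclass
class SimConfig:
    """Parameters of the synthetic world; ``seed`` fixes all randomness."""

    n_genes: int = 2000
    tumor_states: tuple[str, ...] = (
        "melanocytic", "intermediate", "neural_crest_like", "mesenchymal_like")
    cd8_states: tuple[str, ...] = ("naive", "transitional", "exhausted")
    cells_per_state: int = 50
    regulons_per_state: int = 3
    targets_per_regulon: int = 15
    markers_per_state: int = 15
    n_ligands: int = 60
    circuit_ligands: int = 8
    circuit_sender: str = "intermediate"
    circuit_receiver: str = "exhausted"
    targets_per_ligand: int = 10
    overexpr_logfc: float = LN2
    circuit_effect: float = 1.0
    nb_dispersion: float = 0.3
    library_size_mean: float = 5000.0
    seed: int = 0

    def __post_init__(self):
        if self.cells_per_state <= 0:
            raise ValueError("cells_per_state must be positive")
        if self.circuit_effect < 0 or self.overexpr_logfc < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.circuit_sender not in self.tumor_states:
            raise ValueError("circuit_sender must be a tumor state")
        if self.circuit_receiver not in self.cd8_states:
            raise ValueError("circuit_receiver must be a CD8 state")
        if self.circuit_ligands > self.n_ligands:
            raise ValueError("circuit_ligands cannot exceed n_ligands")
        if self.n_genes < self._n_special:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the designated gene blocks "
                f"({self._n_special})")

    @property
    def _n_special(self) -> int:
        return (len(self.tumor_states) * self.regulons_per_state * self.targets_per_regulon
                + len(self.cd8_states) * self.markers_per_state
                + 2 * self.n_ligands
                + self.n_ligands * self.targets_per_ligand)

    @property
    def states(self) -> list[tuple[str, str]]:
        return ([(s, "tumor") for s in self.tumor_states]
                + [(s, "cd8") for s in self.cd8_states])


@dataclass
class GeneLayout:
    """Deterministic block assignment of gene names to roles."""

    gene_names: np.ndarray
    regulon_targets: dict[str, list[list[str]]]  # tumor state -> per-regulon target lists
    markers: dict[str, list[str]]                # cd8 state -> marker genes
    ligands: list[str]
    receptors: list[str]
    ligand_targets: dict[str, list[str]]         # ligand gene -> designated prior targets


def _layout(config: SimConfig) -> GeneLayout:
    names = np.array([f"G{i:04d}" for i in range(config.n_genes)], dtype=object)
    cursor = 0

    def take(n):
        nonlocal cursor
        block = list(names[cursor:cursor + n])
        cursor += n
        return block

    regulon_targets = {
        s: [take(config.targets_per_regulon) for _ in range(config.regulons_per_state)]
        for s in config.tumor_states
    }
    markers = {s: take(config.markers_per_state) for s in config.cd8_states}
    ligands = take(config.n_ligands)
    receptors = take(config.n_ligands)
    ligand_targets = {l: take(config.targets_per_ligand) for l in ligands}
    return GeneLayout(names, regulon_targets, markers, ligands, receptors, ligand_targets)


@dataclass
class GroundTruth:
    """What was planted: per-cell states, per-state gene lists, the circuit."""

    cell_states: pd.Series
    compartments: pd.Series
    signature_genes: dict[str, list[str]]   # markers / regulon targets only
    de_genes: dict[str, list[str]]          # everything over-expressed in the state
    circuit_sender: str
    circuit_receiver: str
    circuit_direction: str
    circuit_ligand_genes: list[str]
    circuit_receptor_genes: list[str]
    ligand_targets: dict[str, list[str]]
    latent: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def simulate_sc(config: SimConfig
                ) -> tuple[ExpressionMatrix, GroundTruth, list[Regulon], list[GeneSet]]:
    """Negative-binomial counts with planted states and the planted circuit."""
    rng = np.random.default_rng(config.seed)
    lay = _layout(config)
    n_states = len(config.states)
    n_cells = n_states * config.cells_per_state
    cell_ids = np.array([f"cell{i:04d}" for i in range(n_cells)], dtype=object)
    state_of = np.repeat([s for s, _ in config.states], config.cells_per_state)
    comp_of = np.repeat([c for _, c in config.states], config.cells_per_state)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    gene_pos = {g: i for i, g in enumerate(lay.gene_names)}
    boost = np.ones(config.n_genes)
    sig_genes: dict[str, list[str]] = {}
    for s in config.tumor_states:
        sig_genes[s] = [g for block in lay.regulon_targets[s] for g in block]
    for s in config.cd8_states:
        sig_genes[s] = list(lay.markers[s])
    for genes in sig_genes.values():
        boost[[gene_pos[g] for g in genes]] *= 3.0
    boost[[gene_pos[g] for g in lay.ligands]] *= 3.0
    boost[[gene_pos[g] for g in lay.receptors]] *= 3.0
    base = base * boost

    circuit_lig = lay.ligands[:config.circuit_ligands]
    circuit_rec = lay.receptors[:config.circuit_ligands]
    circuit_targets = sorted({g for l in circuit_lig for g in lay.ligand_targets[l]})

    latent = rng.uniform(0.5, 1.5, size=n_cells)
    rel = np.tile(base[:, None], (1, n_cells))
    for s, comp in config.states:
        cols = np.flatnonzero(state_of == s)
        idx = [gene_pos[g] for g in sig_genes[s]]
        rel[np.ix_(idx, cols)] *= np.exp(config.overexpr_logfc * latent[cols])[None, :]
        if s == config.circuit_sender:
            li = [gene_pos[g] for g in circuit_lig]
            rel[np.ix_(li, cols)] *= np.exp(config.circuit_effect * latent[cols])[None, :]
        if s == config.circuit_receiver:
            ti = [gene_pos[g] for g in circuit_targets]
            rel[np.ix_(ti, cols)] *= np.exp(config.circuit_effect * latent[cols])[None, :]
            ri = [gene_pos[g] for g in circuit_rec]
            rel[np.ix_(ri, cols)] *= np.exp(config.circuit_effect * latent[cols])[None, :]

    lib = rng.lognormal(np.log(config.library_size_mean), 0.25, size=n_cells)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]
    d = config.nb_dispersion
    counts = rng.negative_binomial(n=1.0 / d, p=1.0 / (1.0 + d * mu)).astype(float)

    meta = pd.DataFrame({"compartment": comp_of, "state": state_of},
                        index=pd.Index(cell_ids, name="cell_id"))
    x = ExpressionMatrix(counts, lay.gene_names, cell_ids, layer="counts", cell_meta=meta)

    de = {s: list(g) for s, g in sig_genes.items()}
    de[config.circuit_sender] = de[config.circuit_sender] + list(circuit_lig)
    de[config.circuit_receiver] = (de[config.circuit_receiver] + circuit_targets
                                   + list(circuit_rec))
    truth = GroundTruth(
        cell_states=pd.Series(state_of, index=meta.index),
        compartments=pd.Series(comp_of, index=meta.index),
        signature_genes=sig_genes,
        de_genes=de,
        circuit_sender=config.circuit_sender,
        circuit_receiver=config.circuit_receiver,
        circuit_direction="tumor->cd8",
        circuit_ligand_genes=list(circuit_lig),
        circuit_receptor_genes=list(circuit_rec),
        ligand_targets={l: list(t) for l, t in lay.ligand_targets.items()},
        latent=pd.Series(latent, index=meta.index),
    )
    regulons = [
        Regulon(tf=f"TF_{s}_{i + 1}",
                targets=GeneSet(f"regulon_{s}_{i + 1}", tuple(block)))
        for s in config.tumor_states
        for i, block in enumerate(lay.regulon_targets[s])
    ]
    markers = [GeneSet(f"markers_{s}", tuple(lay.markers[s])) for s in config.cd8_states]
    return x, truth, regulons, markers


def simulate_pair_resources(config: SimConfig, n_resources: int = 3,
                            n_decoys: int = 10) -> list[list[tuple[str, str]]]:
    """Per-resource L-R tables: every true pair in >= 2 resources, decoys in one.

    Decoy pairs shuffle ligand/receptor partners so they are dropped by the
    two-resource support rule.
    """
    rng = np.random.default_rng(config.seed + 1)
    lay = _layout(config)
    true_pairs = list(zip(lay.ligands, lay.receptors))
    tables: list[list[tuple[str, str]]] = [[] for _ in range(n_resources)]
    for pair in true_pairs:
        k = 2 + int(rng.integers(0, n_resources - 1))  # support 2..n_resources
        for t in rng.choice(n_resources, size=k, replace=False):
            tables[t].append(pair)
    for _ in range(n_decoys):
        l = lay.ligands[int(rng.integers(len(lay.ligands)))]
        r = lay.receptors[int(rng.integers(len(lay.receptors)))]
        if (l, r) in true_pairs:
            continue
        tables[int(rng.integers(n_resources))].append((l, r))
    return tables


def true_pairs(config: SimConfig) -> list[LRPair]:
    lay = _layout(config)
    return [LRPair(l, r, 2) for l, r in zip(lay.ligands, lay.receptors)]


def simulate_prior(config: SimConfig) -> LigandTargetPrior:
    """Ligand x target-gene regulatory potential.

    Every ligand's designated target block gets potential ~1; the rest of the
    target universe carries |N(0, 0.1)| background, so no row is all zero.
    """
    rng = np.random.default_rng(config.seed + 2)
    lay = _layout(config)
    universe = [g for l in lay.ligands for g in lay.ligand_targets[l]]
    pot = np.abs(rng.normal(0.0, 0.1, size=(len(lay.ligands), len(universe))))
    col = {g: j for j, g in enumerate(universe)}
    for i, l in enumerate(lay.ligands):
        for g in lay.ligand_targets[l]:
            pot[i, col[g]] = 1.0 + abs(rng.normal(0.0, 0.05))
    return LigandTargetPrior(pd.DataFrame(pot, index=lay.ligands, columns=universe))


def simulate_cohort(sc: ExpressionMatrix, truth: GroundTruth, n_samples: int = 200,
                    hr_per_unit: float = 0.5, censor_rate: float = 0.01, seed: int = 0,
                    cells_per_sample: int = 150, baseline_hazard: float = 0.02,
                    dirichlet_alpha: float = 2.0
                    ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Pseudobulk cohort with survival tied to the planted states' abundance.

    Each sample averages the CPM profiles of a with-replacement cell mixture
    drawn at Dirichlet state fractions. Survival time is exponential with
    log-hazard log(hr_per_unit) * (sender fraction + receiver fraction) over a
    baseline rate; censoring is an independent exponential at ``censor_rate``.
    The clinical table also carries a binary ``mutation`` label whose frequency
    rises with the planted risk fraction.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    rng = np.random.default_rng(seed)
    cpm = sc if sc.layer == "cpm" else cpm_normalize(sc)
    states = sorted(truth.cell_states.unique())
    state_cols = {s: np.flatnonzero(truth.cell_states.to_numpy() == s) for s in states}
    fracs = rng.dirichlet(np.full(len(states), dirichlet_alpha), size=n_samples)
    sample_ids = np.array([f"sample{i:04d}" for i in range(n_samples)], dtype=object)

    bulk = np.empty((cpm.n_genes, n_samples))
    for i in range(n_samples):
        n_per = rng.multinomial(cells_per_sample, fracs[i])
        cols = np.concatenate([
            rng.choice(state_cols[s], size=n, replace=True)
            for s, n in zip(states, n_per) if n > 0
        ])
        bulk[:, i] = cpm.values[:, cols].mean(axis=1)

    risk_frac = (fracs[:, states.index(truth.circuit_sender)]
                 + fracs[:, states.index(truth.circuit_receiver)])
    hazard = baseline_hazard * np.exp(np.log(hr_per_unit) * risk_frac)
    t_event = rng.exponential(1.0 / hazard)
    with np.errstate(divide="ignore"):
        t_censor = (rng.exponential(1.0 / censor_rate, size=n_samples)
                    if censor_rate > 0 else np.full(n_samples, np.inf))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    mutation = (rng.uniform(size=n_samples) < 0.2 + 0.5 * risk_frac).astype(int)

    clinical = pd.DataFrame({
        "time": time, "event": event, "mutation": mutation, "risk_fraction": risk_frac,
        **{f"frac_{s}": fracs[:, j] for j, s in enumerate(states)},
    }, index=pd.Index(sample_ids, name="sample_id"))
    bulk_x = ExpressionMatrix(bulk, cpm.gene_names, sample_ids, layer="cpm")
    return bulk_x, clinical


def shuffled_assignment(truth: GroundTruth, seed: int) -> pd.Series:
    """State labels permuted within each compartment — the scan's null world."""
    rng = np.random.default_rng(seed)
    labels = truth.cell_states.copy()
    for comp in ("tumor", "cd8"):
        idx = truth.compartments[truth.compartments == comp].index
        labels.loc[idx] = rng.permutation(labels.loc[idx].to_numpy())
    return labels
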