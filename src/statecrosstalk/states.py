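"""Cell-state inference: AUCell regulon activity, consensus k-means, marker
annotation, and state-specific differential signatures.

Tumor states are called by scoring transcription-factor regulons per cell with
AUCell, min-max ("maximum difference") scaling each regulon's activity, running
many randomly initialized k-means partitions of the cells, aggregating them
into a co-clustering consensus matrix, and cutting an average-linkage tree of
1 - consensus at k groups. CD8+ T states are called by canonical-marker argmax.
Per-state signatures are one-vs-rest Wilcoxon rank-sum screens with a log
fold-change floor and BH FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


@dataclass
class ActivityMatrix:
    """Gene-set (regulon/marker) activities per cell, values in [0, 1]."""

    values: np.ndarray  # n_sets x n_cells
    set_names: np.ndarray
    cell_ids: np.ndarray
    scaled: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.set_names = np.asarray(self.set_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.set_names), len(self.cell_ids)):
            raise ValueError("activity shape does not match names")
        if len(set(self.set_names)) != len(self.set_names):
            raise ValueError("duplicate set names")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("activities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.set_names, columns=self.cell_ids)


@dataclass
class StateAssignment:
    """A cell -> state labeling, optionally with the consensus matrix behind it."""

    labels: pd.Series  # index: cell_id, values: state label
    k: int
    consensus: np.ndarray | None = None  # n_cells x n_cells, order of labels.index

    def __post_init__(self):
        self.labels = self.labels.astype(str)
        self.labels.index.name = "cell_id"
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate cell ids in assignment")
        if self.consensus is not None:
            c = np.asarray(self.consensus, dtype=float)
            n = len(self.labels)
            if c.shape != (n, n) or not np.allclose(c, c.T):
                raise ValueError("consensus must be a symmetric n_cells x n_cells matrix")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("consensus diagonal must be 1")
            self.consensus = c

    @property
    def states(self) -> list[str]:
        return sorted(self.labels.unique())

    def cells_of(self, state: str) -> list[str]:
        return list(self.labels.index[self.labels == state])


# ---------------------------------------------------------------------------
# AUCell
# ---------------------------------------------------------------------------

def rank_genes(x: ExpressionMatrix, seed: int = 0) -> np.ndarray:
    """Per-cell 1-based ranks by descending expression.

    Ties are broken by a single seeded permutation of gene order applied
    before a stable sort, identically for every cell, so ranks are
    deterministic given the seed and identical across gene sets.
    """
    n_genes, n_cells = x.values.shape
    perm = np.random.default_rng(seed).permutation(n_genes)
    ranks = np.empty((n_genes, n_cells), dtype=np.int64)
    shuffled = x.values[perm]
    positions = np.arange(1, n_genes + 1)
    for j in range(n_cells):
        order = np.argsort(-shuffled[:, j], kind="stable")
        ranks[perm[order], j] = positions
    return ranks


def aucell_score(x: ExpressionMatrix, sets: Sequence, top_frac: float = 0.05,
                 seed: int = 0) -> ActivityMatrix:
    """AUCell: normalized area under the recovery curve of set genes.

    With per-cell ranks (1 = highest expression) and T = ceil(top_frac * n_genes),
    the raw AUC is sum_{r=1..T} hits(r), hits(r) = number of set genes with rank
    <= r; equivalently each set gene at rank rho <= T contributes T - rho + 1.
    It is normalized by the AUC of a set whose m = min(|set ∩ genes|, T) genes
    occupy ranks 1..m, so scores lie in [0, 1].
    """
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must be in (0, 1)")
    n_genes = x.n_genes
    T = ceil(top_frac * n_genes)
    ranks = rank_genes(x, seed=seed)
    gene_pos = {g: i for i, g in enumerate(x.gene_names)}
    values = np.empty((len(sets), x.n_cells))
    names = []
    positions = np.arange(1, T + 1)
    for i, s in enumerate(sets):
        idx = [gene_pos[g] for g in s.genes if g in gene_pos]
        if not idx:
            raise ValueError(f"gene set {s.name!r} has no genes in the matrix")
        m = min(len(idx), T)
        max_auc = np.minimum(positions, m).sum()
        r = ranks[idx]
        values[i] = np.clip(T - r + 1, 0, None).sum(axis=0) / max_auc
        names.append(s.name)
    return ActivityMatrix(values, np.asarray(names, dtype=object), x.cell_ids, scaled=False)


def maxdiff_scale(a: ActivityMatrix) -> ActivityMatrix:
    """Per-set min-max scaling (range = "maximum difference") to [0, 1].

    Constant rows map to all zeros with a warning.
    """
    if a.scaled:
        raise ValueError("activity matrix is already scaled")
    lo = a.values.min(axis=1, keepdims=True)
    hi = a.values.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"constant activity row(s) mapped to zero: {list(a.set_names[flat][:5])}",
            stacklevel=2,
        )
    span[flat] = 1.0
    return ActivityMatrix((a.values - lo) / span, a.set_names, a.cell_ids, scaled=True)


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

def consensus_kmeans(a: ActivityMatrix, k: int = 4, n_runs: int = 1000,
                     seed: int = 0) -> StateAssignment:
    """Consensus of many randomly initialized k-means partitions of the cells.

    consensus[i, j] is the fraction of runs in which cells i and j co-cluster;
    final labels come from cutting an average-linkage tree of 1 - consensus at
    k groups. Labels are ``C1..Ck`` in order of first appearance.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X = a.values.T  # cells x sets
    n_cells = X.shape[0]
    if k > n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({n_cells})")
    rng = np.random.default_rng(seed)
    co = np.zeros((n_cells, n_cells))
    for _ in range(n_runs):
        rs = int(rng.integers(0, 2**31 - 1))
        labels = KMeans(n_clusters=k, n_init=1, init="random", random_state=rs).fit_predict(X)
        co += labels[:, None] == labels[None, :]
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)
    if n_cells > k:
        dist = squareform(1.0 - consensus, checks=False)
        tree = linkage(dist, method="average")
        raw = fcluster(tree, t=k, criterion="maxclust")
    else:
        raw = np.arange(1, n_cells + 1)
    # stable relabeling by order of first appearance
    remap: dict[int, str] = {}
    final = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = f"C{len(remap) + 1}"
        final.append(remap[lab])
    labels = pd.Series(final, index=pd.Index(a.cell_ids, name="cell_id"))
    return StateAssignment(labels=labels, k=k, consensus=consensus)


def annotate_states(assign: StateAssignment, a: ActivityMatrix,
                    reference: Mapping[str, Sequence[str]]) -> tuple[StateAssignment, pd.DataFrame]:
    """Rename clusters to the reference state whose set scores highest in them.

    ``reference`` maps state name -> row names of ``a`` (regulon or marker-set
    names). Each cluster takes the state with the highest mean activity over
    that state's rows and the cluster's cells; the mapping may be
    non-injective (warned). Returns the relabeled assignment and the
    state x cluster score matrix.
    """
    name_pos = {n: i for i, n in enumerate(a.set_names)}
    cell_pos = {c: i for i, c in enumerate(a.cell_ids)}
    clusters = assign.states
    scores = pd.DataFrame(index=list(reference), columns=clusters, dtype=float)
    for state, rows in reference.items():
        idx = [name_pos[r] for r in rows if r in name_pos]
        if not idx:
            raise ValueError(f"reference state {state!r} has no rows in the activity matrix")
        for cl in clusters:
            cols = [cell_pos[c] for c in assign.cells_of(cl)]
            scores.loc[state, cl] = a.values[np.ix_(idx, cols)].mean()
    mapping = scores.idxmax(axis=0)
    if mapping.duplicated().any():
        warnings.warn(
            f"non-injective annotation: {mapping.to_dict()}", stacklevel=2
        )
    labels = assign.labels.map(mapping.to_dict())
    return StateAssignment(labels=labels, k=assign.k, consensus=assign.consensus), scores


def mean_set_expression(x: ExpressionMatrix, sets: Sequence, scale: bool = True) -> ActivityMatrix:
    """Mean (optionally per-gene min-max scaled) expression of each set per cell.

    The scaled variant is the CD8 marker score used for state annotation; with
    scaling the values lie in [0, 1] so the result is a valid ActivityMatrix.
    """
    vals = x.values
    if scale:
        lo = vals.min(axis=1, keepdims=True)
        span = vals.max(axis=1, keepdims=True) - lo
        span[span == 0] = 1.0
        vals = (vals - lo) / span
    gene_pos = {g: i for i, g in enumerate(x.gene_names)}
    out = np.empty((len(sets), x.n_cells))
    names = []
    for i, s in enumerate(sets):
        idx = [gene_pos[g] for g in s.genes if g in gene_pos]
        if not idx:
            raise ValueError(f"marker set {s.name!r} has no genes in the matrix")
        out[i] = vals[idx].mean(axis=0)
        names.append(s.name)
    if not scale:  # unscaled means are not bounded by 1
        hi = max(out.max(), 1.0)
        out = out / hi
    return ActivityMatrix(out, np.asarray(names, dtype=object), x.cell_ids, scaled=scale)


def assign_by_markers(x: ExpressionMatrix, marker_sets: Mapping[str, Sequence[str]] | Sequence,
                      scale: bool = True) -> StateAssignment:
    """Assign each cell to the marker set with the highest scaled mean expression.

    This is the marker-argmax route used for CD8+ T states when no external
    cluster labels are supplied.
    """
    if isinstance(marker_sets, Mapping):
        from .io import GeneSet

        sets = [GeneSet(name, tuple(genes)) for name, genes in marker_sets.items()]
    else:
        sets = list(marker_sets)
    act = mean_set_expression(x, sets, scale=scale)
    winner = act.values.argmax(axis=0)
    labels = pd.Series(
        [str(act.set_names[i]) for i in winner], index=pd.Index(x.cell_ids, name="cell_id")
    )
    return StateAssignment(labels=labels, k=len(sets))


# ---------------------------------------------------------------------------
# differential signatures
# ---------------------------------------------------------------------------

def differential_signature(x: ExpressionMatrix, assign: StateAssignment,
                           logfc_min: float = 0.25, fdr_max: float = 0.05) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum signature screen per state.

    logFC = ln((mean_in + 1) / (mean_out + 1)) on the stored layer; p-values
    are tie-corrected two-sided rank-sum (Mann-Whitney asymptotic), BH-adjusted
    across genes within each state. The ``significant`` column marks the
    signature: logFC > logfc_min and FDR < fdr_max.
    """
    states = assign.states
    if len(states) < 2:
        raise ValueError("differential_signature needs >= 2 states")
    cell_pos = {c: i for i, c in enumerate(x.cell_ids)}
    rows = []
    const = x.values.ptp(axis=1) == 0 if hasattr(x.values, "ptp") else np.ptp(x.values, axis=1) == 0
    for state in states:
        in_idx = np.array([cell_pos[c] for c in assign.cells_of(state)])
        if in_idx.size < 3:
            raise ValueError(f"state {state!r} has fewer than 3 cells")
        mask = np.zeros(x.n_cells, dtype=bool)
        mask[in_idx] = True
        xin, xout = x.values[:, mask], x.values[:, ~mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(xin, xout, axis=-1, alternative="two-sided",
                                     method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        p[const] = 1.0  # identical samples carry no evidence
        p = np.nan_to_num(p, nan=1.0)
        logfc = np.log((xin.mean(axis=1) + 1.0) / (xout.mean(axis=1) + 1.0))
        fdr = multipletests(p, method="fdr_bh")[1]
        rows.append(pd.DataFrame({
            "state": state, "gene": x.gene_names, "logfc": logfc, "p": p, "fdr": fdr,
            "significant": (logfc > logfc_min) & (fdr < fdr_max),
        }))
    return pd.concat(rows, ignore_index=True)


def signature_sets(table: pd.DataFrame) -> dict[str, list[str]]:
    """Extract state -> signature gene list from a differential table."""
    sig = table[table["significant"]]
    out: dict[str, list[str]] = {s: [] for s in table["state"].unique()}
    for state, sub in sig.groupby("state"):
        out[state] = list(sub["gene"])
    return out
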