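"""State-pair ligand-receptor interaction scoring with a permutation null.

Pairs from several annotation resources are integrated (kept when supported by
at least ``min_support`` resources). A ligand/receptor counts as expressed in a
state when strictly more than 20% of that state's cells have nonzero values;
unexpressed genes are zeroed. The interaction score of pair (L, R) from sender
state A to receiver state B is mean(L | A) * mean(R | B). Significance comes
from shuffling state labels within the tumor and CD8 compartments
independently and recomputing masks and scores each round.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .states import StateAssignment

DIRECTIONS = ("tumor->cd8", "cd8->tumor")


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    n_resources: int = 1

    def __post_init__(self):
        if self.n_resources < 1:
            raise ValueError("n_resources must be >= 1")


def integrate_pairs(tables: Sequence[Iterable], min_support: int = 2) -> list[LRPair]:
    """Merge per-resource pair lists, keeping pairs seen in >= min_support resources.

    Each table is an iterable of (ligand, receptor) tuples or a DataFrame with
    ``ligand``/``receptor`` columns. Duplicates within a resource collapse
    before counting; orientation matters, so (A, B) and (B, A) are distinct.
    """
    if not tables:
        raise ValueError("at least one resource table is required")
    support: dict[tuple[str, str], int] = {}
    first_seen: list[tuple[str, str]] = []
    for table in tables:
        if isinstance(table, pd.DataFrame):
            entries = list(zip(table["ligand"], table["receptor"]))
        else:
            entries = [(l, r) for l, r in table]
        for key in dict.fromkeys(entries):  # per-resource dedup
            if key not in support:
                first_seen.append(key)
            support[key] = support.get(key, 0) + 1
    return [
        LRPair(l, r, support[(l, r)])
        for (l, r) in first_seen
        if support[(l, r)] >= min_support
    ]


def pairs_frame(pairs: Sequence[LRPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.ligand, p.receptor, p.n_resources) for p in pairs],
        columns=["ligand", "receptor", "n_resources"],
    )


# ---------------------------------------------------------------------------
# expressed mask and scores
# ---------------------------------------------------------------------------

def expressed_mask(x: ExpressionMatrix, labels: pd.Series, genes: Sequence[str] | None = None,
                   min_frac: float = 0.20) -> pd.DataFrame:
    """gene x state table: True when > min_frac of the state's cells are positive.

    The comparison is strict ("more than 20% of cells"), so exactly 20% is not
    expressed. Genes absent from the matrix get an all-False row (warned once).
    """
    labels = labels.loc[list(x.cell_ids)]
    states = sorted(labels.unique())
    if genes is None:
        genes = list(x.gene_names)
    present = [g for g in genes if g in set(x.gene_names)]
    missing = [g for g in genes if g not in set(x.gene_names)]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) absent from matrix treated as unexpressed",
                      stacklevel=2)
    pos = x.subset_genes(present).values > 0
    out = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=states)
    lab_arr = labels.to_numpy()
    for s in states:
        cols = lab_arr == s
        out.loc[present, s] = pos[:, cols].mean(axis=1) > min_frac
    return out


def interaction_score(x: ExpressionMatrix, labels: pd.Series, pair: LRPair,
                      sender_state: str, receiver_state: str,
                      mask: pd.DataFrame) -> float:
    """mean(ligand | sender state) * mean(receptor | receiver state), masked to 0."""
    labels = labels.loc[list(x.cell_ids)]
    for s in (sender_state, receiver_state):
        if (labels == s).sum() == 0:
            raise ValueError(f"unknown or empty state {s!r}")
    known = set(x.gene_names)

    def masked_mean(gene: str, state: str) -> float:
        if gene not in known or not bool(mask.loc[gene, state]):
            return 0.0
        return float(x[gene][(labels == state).to_numpy()].mean())

    return masked_mean(pair.ligand, sender_state) * masked_mean(pair.receptor, receiver_state)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _state_stats(vals: np.ndarray, pos: np.ndarray, labels: np.ndarray,
                 states: list, min_frac: float) -> np.ndarray:
    """Masked per-state means for a genes x cells block: mean * (frac>0 > min_frac)."""
    out = np.empty((vals.shape[0], len(states)))
    for j, s in enumerate(states):
        cols = labels == s
        mean = vals[:, cols].mean(axis=1)
        frac = pos[:, cols].mean(axis=1)
        out[:, j] = mean * (frac > min_frac)
    return out


def permutation_test(x: ExpressionMatrix, assign: StateAssignment, pairs: Sequence[LRPair],
                     n_perm: int = 1000, seed: int = 0, min_frac: float = 0.20,
                     plus_one: bool = True) -> pd.DataFrame:
    """Score every pair x sender-state x receiver-state combination, both directions.

    Each permutation shuffles state labels within the tumor compartment and
    within the CD8 compartment independently (state sizes preserved), then
    recomputes the expressed masks and scores. With the default +1 correction,
    p = (1 + #{permuted score >= observed}) / (1 + n_perm) so p is never 0;
    ``plus_one=False`` gives the literal fraction of permuted scores > observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    meta = x.cell_meta
    if "compartment" not in meta.columns:
        raise ValueError("cell_meta must carry a 'compartment' column")
    labels = assign.labels.loc[list(x.cell_ids)].to_numpy()
    comp = meta["compartment"].to_numpy()
    comp_idx = {c: np.flatnonzero(comp == c) for c in ("tumor", "cd8")}
    states = {c: sorted(set(labels[idx])) for c, idx in comp_idx.items()}
    for c, idx in comp_idx.items():
        if idx.size == 0:
            raise ValueError(f"compartment {c!r} has no cells")

    genes = sorted({p.ligand for p in pairs} | {p.receptor for p in pairs})
    known = set(x.gene_names)
    present = [g for g in genes if g in known]
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} pair gene(s) absent from matrix; "
                      "their scores are 0", stacklevel=2)
    gpos = {g: i for i, g in enumerate(present)}
    sub = x.subset_genes(present)
    # direction -> (ligand row per pair, receptor row per pair), -1 = absent
    lig_row = np.array([gpos.get(p.ligand, -1) for p in pairs])
    rec_row = np.array([gpos.get(p.receptor, -1) for p in pairs])

    def all_scores(lab: np.ndarray) -> dict[str, np.ndarray]:
        """direction -> array [n_pairs, n_sender_states, n_receiver_states]."""
        stat = {}
        for c in ("tumor", "cd8"):
            idx = comp_idx[c]
            stat[c] = _state_stats(sub.values[:, idx], sub.values[:, idx] > 0,
                                   lab[idx], states[c], min_frac)
        out = {}
        for d, (cs, cr) in (("tumor->cd8", ("tumor", "cd8")), ("cd8->tumor", ("cd8", "tumor"))):
            lig = np.where(lig_row[:, None] >= 0, stat[cs][lig_row], 0.0)
            rec = np.where(rec_row[:, None] >= 0, stat[cr][rec_row], 0.0)
            out[d] = lig[:, :, None] * rec[:, None, :]
        return out

    observed = all_scores(labels)
    exceed = {d: np.zeros_like(observed[d]) for d in observed}
    rng = np.random.default_rng(seed)
    perm = labels.copy()
    for _ in range(n_perm):
        for c in ("tumor", "cd8"):
            idx = comp_idx[c]
            perm[idx] = rng.permutation(labels[idx])
        scores = all_scores(perm)
        for d in scores:
            if plus_one:
                exceed[d] += scores[d] >= observed[d]
            else:
                exceed[d] += scores[d] > observed[d]

    rows = []
    for d, (cs, cr) in (("tumor->cd8", ("tumor", "cd8")), ("cd8->tumor", ("cd8", "tumor"))):
        if plus_one:
            p = (1.0 + exceed[d]) / (1.0 + n_perm)
        else:
            p = exceed[d] / n_perm
        for i, pair in enumerate(pairs):
            for a, ss in enumerate(states[cs]):
                for b, rs in enumerate(states[cr]):
                    rows.append((pair.ligand, pair.receptor, pair.n_resources, d, ss, rs,
                                 observed[d][i, a, b], p[i, a, b], n_perm))
    return pd.DataFrame(rows, columns=["ligand", "receptor", "n_resources", "direction",
                                       "sender_state", "receiver_state", "score", "p",
                                       "n_perm"])


def summarize_network(results: pd.DataFrame, p_max: float = 0.05
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count significant pairs per directed state pair; also return the edge list."""
    if results.empty:
        raise ValueError("no interaction results to summarize")
    sig = results[results["p"] < p_max]
    counts = (
        results.groupby(["direction", "sender_state", "receiver_state"])
        .apply(lambda g: int((g["p"] < p_max).sum()), include_groups=False)
        .rename("n_significant")
        .reset_index()
    )
    edges = sig[["direction", "sender_state", "receiver_state", "ligand", "receptor",
                 "score", "p"]].reset_index(drop=True)
    return counts, edges
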