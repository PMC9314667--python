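"""Crosstalk propensity: state-related ligands on both sides of signaling and
the shared-ligand hypergeometric test.

For a signaling direction (tumor->cd8 or cd8->tumor), a ligand is related to a
*sender* state when its expression across sender-compartment cells correlates
(Pearson, BH FDR < 0.05, r > 0) with the per-cell mean expression of that
state's signature; it is related to a *receiver* state when its predicted
per-cell activity (correlation of a ligand-target regulatory-potential row
with the cell's binary expressed-gene indicator) correlates the same way with
the receiver state's signature score. A tumor state and a CD8 state "crosstalk"
when the ligands related to both sides overlap more than a hypergeometric draw
from the tested ligand universe explains (p < 0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .lrcomm import LRPair
from .states import ActivityMatrix, StateAssignment


@dataclass
class LigandTargetPrior:
    """Regulatory potential of each ligand on downstream target genes."""

    potential: pd.DataFrame  # ligands x target genes, non-negative

    def __post_init__(self):
        pot = self.potential.astype(float)
        if pot.index.has_duplicates or pot.columns.has_duplicates:
            raise ValueError("duplicate ligand or target-gene names in prior")
        if (pot.to_numpy() < 0).any():
            raise ValueError("regulatory potential must be non-negative")
        zero = pot.index[(pot.to_numpy() == 0).all(axis=1)]
        if len(zero):
            raise ValueError(f"all-zero ligand row(s): {list(zero[:5])}")
        self.potential = pot

    @property
    def ligands(self) -> list[str]:
        return list(self.potential.index)

    @property
    def targets(self) -> list[str]:
        return list(self.potential.columns)


@dataclass
class CrosstalkResult:
    """Shared-ligand over-occurrence between one tumor state and one CD8 state."""

    tumor_state: str
    cd8_state: str
    direction: str
    shared_ligands: tuple[str, ...]
    N: int
    K: int
    n: int
    k: int
    p_hyper: float
    significant: bool

    def __post_init__(self):
        if not (self.k <= min(self.K, self.n) <= self.N):
            raise ValueError("inconsistent hypergeometric counts")
        if len(self.shared_ligands) != self.k:
            raise ValueError("shared ligand set size must equal k")


# ---------------------------------------------------------------------------
# ligand activity (NicheNet-style, per receiver cell)
# ---------------------------------------------------------------------------

def ligand_activity(x_receivers: ExpressionMatrix, prior: LigandTargetPrior,
                    candidate_ligands: Sequence[str], binary: bool = True) -> pd.DataFrame:
    """Predicted ligand activity per receiver cell.

    activity(l, c) = Pearson correlation, over the target genes shared between
    the prior and the matrix, of ligand l's regulatory-potential row with the
    cell's response vector — by default the binary expressed indicator
    (x > 0); ``binary=False`` correlates against continuous expression. Cells
    with a constant response vector get activity 0 (warned).
    """
    missing = [l for l in candidate_ligands if l not in set(prior.ligands)]
    if missing:
        raise ValueError(f"candidate ligand(s) not in prior: {missing[:5]}")
    shared = [g for g in prior.targets if g in set(x_receivers.gene_names)]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} target genes shared between prior and matrix "
                         "(need >= 10)")
    P = prior.potential.loc[list(candidate_ligands), shared].to_numpy()
    resp = x_receivers.subset_genes(shared).values
    if binary:
        resp = (resp > 0).astype(float)

    def zscore(M, axis):  # standardize; zero-variance rows/cols -> 0
        mu = M.mean(axis=axis, keepdims=True)
        sd = M.std(axis=axis, keepdims=True)
        flat = sd == 0
        sd = np.where(flat, 1.0, sd)
        return (M - mu) / sd, flat

    Zp, flat_lig = zscore(P, axis=1)
    Zc, flat_cell = zscore(resp, axis=0)
    if flat_cell.any():
        warnings.warn(f"{int(flat_cell.sum())} receiver cell(s) with a constant response "
                      "indicator assigned activity 0", stacklevel=2)
    if flat_lig.any():
        warnings.warn("constant prior row(s) assigned activity 0", stacklevel=2)
    act = (Zp @ Zc) / len(shared)
    return pd.DataFrame(act, index=list(candidate_ligands), columns=x_receivers.cell_ids)


# ---------------------------------------------------------------------------
# state-related ligands
# ---------------------------------------------------------------------------

def _pearson_with_p(values: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of ``values`` [m x n] against ``target`` [n], with
    two-sided p from the t distribution. Constant rows get r = nan."""
    n = target.size
    tz = target - target.mean()
    t_sd = tz.std()
    vz = values - values.mean(axis=1, keepdims=True)
    v_sd = vz.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vz @ tz) / n / np.where(v_sd == 0, np.nan, v_sd) / (t_sd if t_sd else np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


def state_related_ligands(values: pd.DataFrame, signature_scores: pd.Series,
                          fdr_max: float = 0.05, require_positive: bool = True
                          ) -> pd.DataFrame:
    """Pearson screen of per-cell ligand quantities against a state's signature score.

    ``values`` is ligand x cell (expression for sender side, predicted activity
    for receiver side); ``signature_scores`` is the per-cell mean expression of
    the state signature over the same cells. BH adjustment runs across the
    ligands of this screen; ``related`` requires FDR < fdr_max and, by default,
    r > 0.
    """
    cells = list(values.columns)
    if len(cells) < 10:
        raise ValueError("state_related_ligands needs >= 10 cells")
    target = signature_scores.loc[cells].to_numpy(dtype=float)
    r, p = _pearson_with_p(values.to_numpy(dtype=float), target)
    const = np.isnan(r)
    if const.any():
        warnings.warn(f"{int(const.sum())} constant ligand vector(s) skipped", stacklevel=2)
    p_adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    related = ok & (p_adj < fdr_max)
    if require_positive:
        related &= r > 0
    return pd.DataFrame({
        "ligand": values.index, "r": r, "p": p, "fdr": p_adj, "related": related,
    }).reset_index(drop=True)


def shared_ligand_test(related_a: Sequence[str], related_b: Sequence[str],
                       universe: Sequence[str], alpha: float = 0.001,
                       tumor_state: str = "A", cd8_state: str = "B",
                       direction: str = "tumor->cd8") -> CrosstalkResult:
    """Hypergeometric over-occurrence of ligands related to both states.

    With N = |universe|, K = |related_a|, n = |related_b| and k the overlap,
    p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty ligand universe")
    a, b = set(related_a), set(related_b)
    if not a <= uni or not b <= uni:
        raise ValueError("related ligand sets must be subsets of the universe")
    N, K, n = len(uni), len(a), len(b)
    shared = tuple(sorted(a & b))
    k = len(shared)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
    return CrosstalkResult(tumor_state, cd8_state, direction, shared, N, K, n, k,
                           p, p < alpha)


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

def _signature_score(x: ExpressionMatrix, genes: Sequence[str]) -> pd.Series:
    present = [g for g in genes if g in set(x.gene_names)]
    if not present:
        raise ValueError("signature has no genes in the matrix")
    vals = x.subset_genes(present).values.mean(axis=0)
    return pd.Series(vals, index=x.cell_ids)


def _expressed_ligands(x_comp: ExpressionMatrix, ligands: Sequence[str],
                       min_frac: float) -> list[str]:
    known = set(x_comp.gene_names)
    out = []
    for l in ligands:
        if l in known and (x_comp[l] > 0).mean() > min_frac:
            out.append(l)
    return out


def _scan_direction(direction: str, x_send: ExpressionMatrix, x_recv: ExpressionMatrix,
                    send_corr: Mapping[str, pd.Series], recv_corr: Mapping[str, pd.Series],
                    prior: LigandTargetPrior, pairs: Sequence[LRPair], min_frac: float,
                    fdr_max: float, alpha: float, require_positive: bool,
                    binary: bool) -> tuple[list[CrosstalkResult], pd.DataFrame]:
    pair_ligands = list(dict.fromkeys(p.ligand for p in pairs))
    expressed = _expressed_ligands(x_send, pair_ligands, min_frac)
    universe = [l for l in expressed if l in set(prior.ligands)]
    dropped = len(expressed) - len(universe)
    if dropped:
        warnings.warn(f"{dropped} expressed ligand(s) absent from the prior excluded from "
                      f"the {direction} universe", stacklevel=3)
    assoc_rows = []
    results: list[CrosstalkResult] = []
    if not universe:
        warnings.warn(f"no testable ligands for direction {direction}", stacklevel=3)
    sender_related: dict[str, set[str]] = {}
    receiver_related: dict[str, set[str]] = {}
    if universe:
        send_vals = x_send.subset_genes(universe).to_frame()
        act = ligand_activity(x_recv, prior, universe, binary=binary)
        for state, score in send_corr.items():
            tab = state_related_ligands(send_vals, score, fdr_max, require_positive)
            tab.insert(0, "direction", direction)
            tab.insert(1, "side", "sender")
            tab.insert(2, "state", state)
            assoc_rows.append(tab)
            sender_related[state] = set(tab.loc[tab["related"], "ligand"])
        for state, score in recv_corr.items():
            tab = state_related_ligands(act, score, fdr_max, require_positive)
            tab.insert(0, "direction", direction)
            tab.insert(1, "side", "receiver")
            tab.insert(2, "state", state)
            assoc_rows.append(tab)
            receiver_related[state] = set(tab.loc[tab["related"], "ligand"])
    tumor_first = direction == "tumor->cd8"
    send_states = list(send_corr)
    recv_states = list(recv_corr)
    for ss in send_states:
        for rs in recv_states:
            ts, cs = (ss, rs) if tumor_first else (rs, ss)
            if universe:
                res = shared_ligand_test(
                    sorted(sender_related.get(ss, set())),
                    sorted(receiver_related.get(rs, set())),
                    universe, alpha, tumor_state=ts, cd8_state=cs, direction=direction,
                )
            else:
                res = CrosstalkResult(ts, cs, direction, (), 1, 0, 0, 0, 1.0, False)
            results.append(res)
    assoc = (pd.concat(assoc_rows, ignore_index=True) if assoc_rows
             else pd.DataFrame(columns=["direction", "side", "state", "ligand", "r", "p",
                                        "fdr", "related"]))
    return results, assoc


def crosstalk_frame(results: Sequence[CrosstalkResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "direction": r.direction, "tumor_state": r.tumor_state, "cd8_state": r.cd8_state,
        "N": r.N, "K": r.K, "n": r.n, "k": r.k, "p_hyper": r.p_hyper,
        "significant": r.significant, "shared_ligands": ",".join(r.shared_ligands),
    } for r in results])


def propensity_scan(signatures_tumor: Mapping[str, Sequence[str]],
                    signatures_cd8: Mapping[str, Sequence[str]],
                    x: ExpressionMatrix, assign: StateAssignment,
                    prior: LigandTargetPrior, pairs: Sequence[LRPair],
                    min_frac: float = 0.20, fdr_max: float = 0.05, alpha: float = 0.001,
                    require_positive: bool = True, binary: bool = True
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full crosstalk-propensity grid over tumor state x CD8 state x direction.

    Per direction, the ligand universe is the integrated pairs' ligands
    expressed (> min_frac of cells positive) in the sender compartment and
    present in the prior. States whose signature is empty contribute an empty
    related set (their grid cells get p = 1). Returns the grid and the full
    ligand-state association table.
    """
    x_tumor = x.compartment("tumor")
    x_cd8 = x.compartment("cd8")
    tumor_scores = {s: _signature_score(x_tumor, g) for s, g in signatures_tumor.items() if g}
    cd8_scores = {s: _signature_score(x_cd8, g) for s, g in signatures_cd8.items() if g}
    empty_t = [s for s, g in signatures_tumor.items() if not g]
    empty_c = [s for s, g in signatures_cd8.items() if not g]
    if empty_t or empty_c:
        warnings.warn(f"states with empty signatures treated as unrelated: "
                      f"{empty_t + empty_c}", stacklevel=2)
        for s in empty_t:
            tumor_scores[s] = None
        for s in empty_c:
            cd8_scores[s] = None

    def usable(d):
        return {s: v for s, v in d.items() if v is not None}

    res1, assoc1 = _scan_direction("tumor->cd8", x_tumor, x_cd8, usable(tumor_scores),
                                   usable(cd8_scores), prior, pairs, min_frac, fdr_max,
                                   alpha, require_positive, binary)
    res2, assoc2 = _scan_direction("cd8->tumor", x_cd8, x_tumor, usable(cd8_scores),
                                   usable(tumor_scores), prior, pairs, min_frac, fdr_max,
                                   alpha, require_positive, binary)
    # grid cells for empty-signature states (p = 1 by construction)
    extras = []
    for d, (senders, receivers, t_first) in {
        "tumor->cd8": (signatures_tumor, signatures_cd8, True),
        "cd8->tumor": (signatures_cd8, signatures_tumor, False),
    }.items():
        have = {(r.tumor_state, r.cd8_state) for r in (res1 if t_first else res2)}
        for ss in senders:
            for rs in receivers:
                ts, cs = (ss, rs) if t_first else (rs, ss)
                if (ts, cs) not in have:
                    extras.append(CrosstalkResult(ts, cs, d, (), 1, 0, 0, 0, 1.0, False))
    grid = crosstalk_frame(res1 + res2 + extras)
    assoc = pd.concat([assoc1, assoc2], ignore_index=True)
    return grid, assoc


def function_related_variant(function_sets_tumor: Mapping[str, Sequence[str]],
                             function_sets_cd8: Mapping[str, Sequence[str]],
                             x: ExpressionMatrix, assign: StateAssignment,
                             prior: LigandTargetPrior, pairs: Sequence[LRPair],
                             tumor_activity: ActivityMatrix | None = None,
                             **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Propensity grid keyed by function/TF sets instead of state signatures.

    The CD8-side correlate is the mean expression of the supplied function
    marker set. The tumor-side correlate is the mean regulon *activity* of the
    named sets when ``tumor_activity`` rows cover them, otherwise the mean
    expression of the genes — with expression correlates and sets equal to the
    state signatures this reproduces :func:`propensity_scan` exactly.
    """
    for name, genes in list(function_sets_tumor.items()) + list(function_sets_cd8.items()):
        if not genes:
            raise ValueError(f"empty function set {name!r}")
    sig_tumor = dict(function_sets_tumor)
    if tumor_activity is not None:
        rows = set(tumor_activity.set_names)
        act = tumor_activity.to_frame()
        x_tumor = x.compartment("tumor")
        overridden = {}
        for name, members in function_sets_tumor.items():
            if set(members) <= rows:
                overridden[name] = act.loc[list(members), list(x_tumor.cell_ids)].mean(axis=0)
        if overridden:
            return _scan_with_scores(sig_tumor, dict(function_sets_cd8), x, assign, prior,
                                     pairs, tumor_score_override=overridden, **kwargs)
    return propensity_scan(sig_tumor, dict(function_sets_cd8), x, assign, prior, pairs,
                           **kwargs)


def _scan_with_scores(signatures_tumor, signatures_cd8, x, assign, prior, pairs,
                      tumor_score_override: Mapping[str, pd.Series], min_frac: float = 0.20,
                      fdr_max: float = 0.05, alpha: float = 0.001,
                      require_positive: bool = True, binary: bool = True):
    x_tumor = x.compartment("tumor")
    x_cd8 = x.compartment("cd8")
    tumor_scores = {}
    for s, genes in signatures_tumor.items():
        if s in tumor_score_override:
            tumor_scores[s] = tumor_score_override[s].loc[list(x_tumor.cell_ids)]
        else:
            tumor_scores[s] = _signature_score(x_tumor, genes)
    cd8_scores = {s: _signature_score(x_cd8, g) for s, g in signatures_cd8.items()}
    res1, assoc1 = _scan_direction("tumor->cd8", x_tumor, x_cd8, tumor_scores, cd8_scores,
                                   prior, pairs, min_frac, fdr_max, alpha, require_positive,
                                   binary)
    res2, assoc2 = _scan_direction("cd8->tumor", x_cd8, x_tumor, cd8_scores, tumor_scores,
                                   prior, pairs, min_frac, fdr_max, alpha, require_positive,
                                   binary)
    return crosstalk_frame(res1 + res2), pd.concat([assoc1, assoc2], ignore_index=True)


# ---------------------------------------------------------------------------
# TF-ligand-receptor-TF chains
# ---------------------------------------------------------------------------

def assemble_chains(tf_ligand: pd.DataFrame, ligand_receptor_tf: pd.DataFrame) -> pd.DataFrame:
    """Join upstream TF->ligand links with ligand->receptor->downstream-TF links.

    Inner join on the shared ligand; duplicate chains collapse. Input columns:
    ``tf, ligand`` and ``ligand, receptor, tf``.
    """
    for df, cols, label in ((tf_ligand, {"tf", "ligand"}, "tf_ligand"),
                            (ligand_receptor_tf, {"ligand", "receptor", "tf"},
                             "ligand_receptor_tf")):
        if df.empty:
            raise ValueError(f"{label} table is empty")
        if not cols <= set(df.columns):
            raise ValueError(f"{label} table must have columns {sorted(cols)}")
    left = tf_ligand.rename(columns={"tf": "upstream_tf"})[["upstream_tf", "ligand"]]
    right = ligand_receptor_tf.rename(columns={"tf": "downstream_tf"})[
        ["ligand", "receptor", "downstream_tf"]]
    chains = left.merge(right, on="ligand").drop_duplicates(ignore_index=True)
    return chains[["upstream_tf", "ligand", "receptor", "downstream_tf"]]
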