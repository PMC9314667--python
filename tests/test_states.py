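import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from statecrosstalk.io import GeneSet
from statecrosstalk.states import (ActivityMatrix, StateAssignment, annotate_states,
                                   assign_by_markers, aucell_score, consensus_kmeans,
                                   differential_signature, maxdiff_scale, rank_genes,
                                   signature_sets)
from statecrosstalk.synth import simulate_sc
from statecrosstalk.validation import small_config

from conftest import make_matrix


def brute_force_aucell(expr, set_idx, top_frac):
    """Independent per-rank recovery-curve loop (the oracle)."""
    from math import ceil

    n = expr.size
    T = ceil(top_frac * n)
    order = np.argsort(-expr, kind="stable")  # distinct values assumed
    rank_of = np.empty(n, dtype=int)
    rank_of[order] = np.arange(1, n + 1)
    raw = 0
    for r in range(1, T + 1):
        raw += sum(1 for g in set_idx if rank_of[g] <= r)
    m = min(len(set_idx), T)
    max_auc = sum(min(r, m) for r in range(1, T + 1))
    return raw / max_auc


def descending_matrix(n=10):
    """One cell whose expression strictly decreases with gene index."""
    return make_matrix(np.arange(n, 0, -1, dtype=float).reshape(n, 1))


class TestAUCell:
    def test_top_ranks_give_one(self):
        x = descending_matrix()
        act = aucell_score(x, [GeneSet("s", ("g0", "g1", "g2"))], top_frac=0.3)
        assert act.values[0, 0] == pytest.approx(1.0)

    def test_outside_top_gives_zero(self):
        x = descending_matrix()
        act = aucell_score(x, [GeneSet("s", ("g7", "g8", "g9"))], top_frac=0.3)
        assert act.values[0, 0] == pytest.approx(0.0)

    def test_partial_recovery(self):
        # set genes at ranks {1, 3}: raw = 1+1+2 = 4, max = 1+2+2 = 5
        x = descending_matrix()
        act = aucell_score(x, [GeneSet("s", ("g0", "g2"))], top_frac=0.3)
        assert act.values[0, 0] == pytest.approx(0.8)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n_genes = int(rng.integers(10, 51))
            n_cells = int(rng.integers(1, 6))
            expr = rng.permutation(n_genes * n_cells).reshape(n_genes, n_cells).astype(float)
            x = make_matrix(expr)
            size = int(rng.integers(1, n_genes))
            idx = rng.choice(n_genes, size=size, replace=False)
            gs = GeneSet("s", tuple(f"g{i}" for i in idx))
            act = aucell_score(x, [gs], top_frac=0.2)
            for j in range(n_cells):
                assert act.values[0, j] == pytest.approx(
                    brute_force_aucell(expr[:, j], idx, 0.2))

    def test_monotone_transform_invariance(self, rng):
        expr = rng.permutation(40).reshape(20, 2).astype(float)
        gs = GeneSet("s", ("g1", "g5", "g9"))
        a = aucell_score(make_matrix(expr), [gs])
        b = aucell_score(make_matrix(np.exp(expr / 10)), [gs])
        assert np.allclose(a.values, b.values)

    def test_absent_set_errors(self):
        with pytest.raises(ValueError, match="no genes"):
            aucell_score(descending_matrix(), [GeneSet("s", ("missing",))])

    def test_tie_break_deterministic(self, rng):
        expr = rng.integers(0, 3, size=(30, 4)).astype(float)  # heavy ties
        x = make_matrix(expr)
        assert np.array_equal(rank_genes(x, seed=5), rank_genes(x, seed=5))


class TestMaxDiffScale:
    def test_linear_map(self):
        a = ActivityMatrix(np.array([[0.2, 0.4, 0.6]]), ["s"], ["c1", "c2", "c3"])
        out = maxdiff_scale(a)
        assert np.allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_constant_row_warns_to_zero(self):
        a = ActivityMatrix(np.array([[0.3, 0.3, 0.3]]), ["s"], ["c1", "c2", "c3"])
        with pytest.warns(UserWarning, match="constant"):
            out = maxdiff_scale(a)
        assert np.allclose(out.values, 0.0)

    def test_row_endpoints(self, rng):
        a = ActivityMatrix(rng.uniform(size=(5, 12)), [f"s{i}" for i in range(5)],
                           [f"c{j}" for j in range(12)])
        out = maxdiff_scale(a)
        assert np.allclose(out.values.min(axis=1), 0.0)
        assert np.allclose(out.values.max(axis=1), 1.0)


class TestConsensus:
    def test_identical_cells_co_cluster(self):
        vals = np.array([[0.9, 0.9, 0.1, 0.1], [0.1, 0.1, 0.9, 0.9]])
        a = ActivityMatrix(vals, ["s1", "s2"], list("abcd"), scaled=True)
        assign = consensus_kmeans(a, k=2, n_runs=1, seed=0)
        assert assign.labels["a"] == assign.labels["b"]
        assert assign.labels["a"] != assign.labels["c"]
        assert assign.consensus[0, 1] == pytest.approx(1.0)

    def test_consensus_symmetric_unit_diagonal(self, rng):
        a = ActivityMatrix(rng.uniform(size=(3, 10)), ["s1", "s2", "s3"],
                           [f"c{j}" for j in range(10)], scaled=True)
        assign = consensus_kmeans(a, k=2, n_runs=5, seed=1)
        c = assign.consensus
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)

    def test_reorder_invariance_up_to_relabel(self, rng):
        vals = np.clip(np.repeat(np.eye(3), 6, axis=1) * 0.8 + 0.1
                       + rng.normal(0, 0.02, (3, 18)), 0, 1)
        cells = [f"c{j}" for j in range(18)]
        a = ActivityMatrix(vals, ["s1", "s2", "s3"], cells, scaled=True)
        perm = rng.permutation(18)
        b = ActivityMatrix(vals[:, perm], ["s1", "s2", "s3"],
                           [cells[j] for j in perm], scaled=True)
        la = consensus_kmeans(a, k=3, n_runs=20, seed=0).labels
        lb = consensus_kmeans(b, k=3, n_runs=20, seed=0).labels.loc[la.index]
        assert adjusted_rand_score(la, lb) == pytest.approx(1.0)

    def test_k_exceeding_cells(self):
        a = ActivityMatrix(np.zeros((1, 3)), ["s"], list("abc"), scaled=True)
        with pytest.raises(ValueError, match="exceeds"):
            consensus_kmeans(a, k=4, n_runs=1)


class TestAnnotate:
    def _assignment(self):
        labels = pd.Series(["C1", "C1", "C2", "C2"],
                           index=pd.Index(list("abcd"), name="cell_id"))
        return StateAssignment(labels=labels, k=2)

    def test_argmax_annotation(self):
        act = ActivityMatrix(np.array([[0.9, 0.9, 0.1, 0.1], [0.1, 0.1, 0.8, 0.8]]),
                             ["mE", "mF"], list("abcd"), scaled=True)
        out, scores = annotate_states(self._assignment(), act,
                                      {"E": ["mE"], "F": ["mF"]})
        assert out.labels.tolist() == ["E", "E", "F", "F"]
        assert scores.loc["E", "C1"] == pytest.approx(0.9)

    def test_non_injective_warns(self):
        act = ActivityMatrix(np.array([[0.9, 0.9, 0.8, 0.8], [0.1, 0.1, 0.2, 0.2]]),
                             ["mE", "mF"], list("abcd"), scaled=True)
        with pytest.warns(UserWarning, match="non-injective"):
            out, _ = annotate_states(self._assignment(), act, {"E": ["mE"], "F": ["mF"]})
        assert set(out.labels) == {"E"}

    def test_cluster_order_invariance(self):
        act = ActivityMatrix(np.array([[0.9, 0.9, 0.1, 0.1], [0.1, 0.1, 0.8, 0.8]]),
                             ["mE", "mF"], list("abcd"), scaled=True)
        swapped = StateAssignment(labels=self._assignment().labels.map(
            {"C1": "C2", "C2": "C1"}), k=2)
        out1, _ = annotate_states(self._assignment(), act, {"E": ["mE"], "F": ["mF"]})
        out2, _ = annotate_states(swapped, act, {"E": ["mE"], "F": ["mF"]})
        assert out1.labels.equals(out2.labels)

    def test_marker_argmax_assignment(self):
        x = make_matrix([[5, 5, 0, 0], [0, 0, 5, 5]], genes=["m1", "m2"])
        assign = assign_by_markers(x, {"A": ["m1"], "B": ["m2"]})
        assert assign.labels.tolist() == ["A", "A", "B", "B"]


def bh_step_up(p):
    """Independent Benjamini-Hochberg oracle."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        r = n - rank_from_top
        running = min(running, p[i] * n / r)
        adj[i] = running
    return adj


class TestDifferentialSignature:
    def _two_state(self, expr):
        n = expr.shape[1]
        labels = pd.Series(["A"] * (n // 2) + ["B"] * (n - n // 2),
                           index=pd.Index([f"c{j}" for j in range(n)], name="cell_id"))
        return make_matrix(expr), StateAssignment(labels=labels, k=2)

    def test_constant_gene_excluded(self, rng):
        expr = np.vstack([np.full(12, 3.0), rng.uniform(1, 5, 12)])
        x, assign = self._two_state(expr)
        tab = differential_signature(x, assign)
        const = tab[tab["gene"] == "g0"]
        assert (const["p"] == 1.0).all()
        assert not const["significant"].any()

    def test_logfc_definition(self):
        expr = np.zeros((1, 12))
        expr[0, :6] = np.e - 1  # mean_in = e-1, mean_out = 0 -> logFC = 1
        x, assign = self._two_state(expr)
        tab = differential_signature(x, assign)
        row = tab[(tab["state"] == "A") & (tab["gene"] == "g0")].iloc[0]
        assert row["logfc"] == pytest.approx(1.0)

    def test_bh_adjustment_matches_step_up_oracle(self, rng):
        expr = rng.lognormal(size=(20, 16))
        x, assign = self._two_state(expr)
        tab = differential_signature(x, assign)
        for _, sub in tab.groupby("state"):
            assert np.allclose(sub["fdr"], bh_step_up(sub["p"].to_numpy()))
            assert (sub["fdr"] >= sub["p"] - 1e-12).all()

    def test_small_state_rejected(self, rng):
        x = make_matrix(rng.uniform(1, 2, (4, 5)))
        labels = pd.Series(["A", "A", "B", "B", "B"],
                           index=pd.Index([f"c{j}" for j in range(5)], name="cell_id"))
        with pytest.raises(ValueError, match="fewer than 3"):
            differential_signature(x, StateAssignment(labels=labels, k=2))

    def test_planted_signature_recovery(self):
        """Genes planted at 2-fold over-expression per state are recovered with
        precision >= 0.9 and recall >= 0.8 (50 cells/state)."""
        cfg = small_config(seed=11, cells_per_state=50)
        x, truth, _, _ = simulate_sc(cfg)
        from statecrosstalk.io import cpm_normalize, filter_low_genes

        xt = filter_low_genes(cpm_normalize(x).compartment("tumor"))
        assign = StateAssignment(truth.cell_states.loc[list(xt.cell_ids)], k=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig = signature_sets(differential_signature(xt, assign))
        precisions, recalls = [], []
        for state, genes in sig.items():
            planted = set(truth.de_genes[state]) & set(xt.gene_names)
            found = set(genes)
            if found:
                precisions.append(len(found & planted) / len(found))
            recalls.append(len(found & planted) / len(planted))
        assert min(precisions) >= 0.9
        assert min(recalls) >= 0.8
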