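import math

import numpy as np
import pandas as pd
import pytest

from statecrosstalk.io import cpm_normalize, filter_low_genes
from statecrosstalk.propensity import (CrosstalkResult, LigandTargetPrior,
                                       assemble_chains, function_related_variant,
                                       ligand_activity, propensity_scan,
                                       shared_ligand_test, state_related_ligands)
from statecrosstalk.states import StateAssignment, signature_sets, differential_signature
from statecrosstalk.validation import small_config
from statecrosstalk.synth import simulate_prior, simulate_sc, true_pairs

from conftest import make_matrix
from test_states import bh_step_up


def toy_prior(n_ligands=3, n_targets=20, seed=0):
    rng = np.random.default_rng(seed)
    pot = np.abs(rng.normal(0, 0.1, (n_ligands, n_targets)))
    for i in range(n_ligands):
        pot[i, i * 5:(i + 1) * 5] = 1.0  # each ligand owns a 5-gene block
    return LigandTargetPrior(pd.DataFrame(
        pot, index=[f"L{i}" for i in range(n_ligands)],
        columns=[f"g{j}" for j in range(n_targets)]))


class TestLigandActivity:
    def test_matching_cell_maximizes_planted_ligand(self):
        prior = toy_prior()
        vals = np.zeros((20, 2))
        vals[5:10, 0] = 1.0   # cell 0 expresses exactly L1's block
        vals[0:3, 1] = 1.0
        vals[12:16, 1] = 1.0
        x = make_matrix(vals)
        act = ligand_activity(x, prior, ["L0", "L1", "L2"])
        assert act["c0"].idxmax() == "L1"
        # direct correlation cross-check for one entry
        expected = np.corrcoef(prior.potential.loc["L1"], vals[:, 0] > 0)[0, 1]
        assert act.loc["L1", "c0"] == pytest.approx(expected)

    def test_constant_indicator_zero_with_warning(self):
        prior = toy_prior()
        x = make_matrix(np.ones((20, 1)))
        with pytest.warns(UserWarning, match="constant response"):
            act = ligand_activity(x, prior, ["L0"])
        assert act.iloc[0, 0] == 0.0

    def test_gene_order_permutation_invariance(self, rng):
        prior = toy_prior()
        vals = (rng.uniform(size=(20, 3)) > 0.5).astype(float)
        x = make_matrix(vals)
        perm = rng.permutation(20)
        x_perm = make_matrix(vals[perm], genes=[f"g{j}" for j in perm])
        a = ligand_activity(x, prior, ["L0", "L1"])
        b = ligand_activity(x_perm, prior, ["L0", "L1"])
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_too_few_shared_targets(self):
        prior = toy_prior(n_targets=20)
        x = make_matrix(np.ones((5, 2)), genes=[f"g{j}" for j in range(5)])
        with pytest.raises(ValueError, match="target genes shared"):
            ligand_activity(x, prior, ["L0"])


class TestStateRelatedLigands:
    def test_perfect_correlation_related(self, rng):
        score = pd.Series(rng.uniform(size=12), index=[f"c{j}" for j in range(12)])
        values = pd.DataFrame([score.to_numpy()], index=["L0"], columns=score.index)
        tab = state_related_ligands(values, score)
        assert tab.loc[0, "r"] == pytest.approx(1.0)
        assert bool(tab.loc[0, "related"])

    def test_negative_correlation_not_related_by_default(self, rng):
        score = pd.Series(rng.uniform(size=12), index=[f"c{j}" for j in range(12)])
        values = pd.DataFrame([-score.to_numpy() + 2], index=["L0"], columns=score.index)
        tab = state_related_ligands(values, score)
        assert not bool(tab.loc[0, "related"])
        tab2 = state_related_ligands(values, score, require_positive=False)
        assert bool(tab2.loc[0, "related"])

    def test_constant_ligand_skipped(self, rng):
        score = pd.Series(rng.uniform(size=12), index=[f"c{j}" for j in range(12)])
        values = pd.DataFrame(np.vstack([np.ones(12), score.to_numpy()]),
                              index=["flat", "L0"], columns=score.index)
        with pytest.warns(UserWarning, match="constant ligand"):
            tab = state_related_ligands(values, score)
        assert np.isnan(tab.loc[0, "r"])
        assert not bool(tab.loc[0, "related"])

    def test_fdr_matches_bh_oracle(self, rng):
        score = pd.Series(rng.normal(size=30), index=[f"c{j}" for j in range(30)])
        values = pd.DataFrame(rng.normal(size=(15, 30)),
                              index=[f"L{i}" for i in range(15)], columns=score.index)
        tab = state_related_ligands(values, score)
        assert np.allclose(tab["fdr"], bh_step_up(tab["p"].to_numpy()))


def enumerate_hypergeom_tail(N, K, n, k):
    """P(X >= k) by the exact combinatorial sum."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


class TestSharedLigandTest:
    def test_exact_value(self):
        uni = [f"L{i}" for i in range(10)]
        res = shared_ligand_test(uni[:5], uni[1:5], uni)
        # N=10, K=5, n=4, k=4 -> C(5,4)*C(5,0)/C(10,4) = 5/210
        assert res.p_hyper == pytest.approx(5 / 210)
        assert res.k == 4 and res.N == 10

    def test_zero_overlap_p_one(self):
        uni = ["a", "b", "c", "d"]
        res = shared_ligand_test(["a"], ["b", "c"], uni)
        assert res.k == 0
        assert res.p_hyper == pytest.approx(1.0)

    def test_degenerate_full_overlap(self):
        uni = ["a", "b", "c"]
        res = shared_ligand_test(uni, uni, uni)
        assert res.k == 3
        assert res.p_hyper == pytest.approx(1.0)  # P(X >= N) with K = n = N

    def test_matches_enumeration(self, rng):
        for _ in range(50):
            N = int(rng.integers(1, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            uni = [f"L{i}" for i in range(N)]
            a = uni[:K]
            b = uni[:k] + uni[K:K + n - k]
            res = shared_ligand_test(a, b, uni)
            assert res.p_hyper == pytest.approx(enumerate_hypergeom_tail(N, K, n, k))

    def test_empty_universe(self):
        with pytest.raises(ValueError, match="empty"):
            shared_ligand_test([], [], [])

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            CrosstalkResult("t", "c", "tumor->cd8", ("L1",), N=2, K=1, n=1, k=2,
                            p_hyper=0.5, significant=False)


@pytest.fixture(scope="module")
def scan_world():
    cfg = small_config(seed=21)
    x, truth, regulons, markers = simulate_sc(cfg)
    cpm = cpm_normalize(x)
    xt = filter_low_genes(cpm.compartment("tumor"))
    xc = filter_low_genes(cpm.compartment("cd8"))
    kept = [g for g in cpm.gene_names if g in set(xt.gene_names) | set(xc.gene_names)]
    x_all = cpm.subset_genes(kept)
    assign = StateAssignment(truth.cell_states.loc[list(x_all.cell_ids)], k=7)
    ta = StateAssignment(truth.cell_states.loc[list(xt.cell_ids)], k=4)
    ca = StateAssignment(truth.cell_states.loc[list(xc.cell_ids)], k=3)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sig_t = signature_sets(differential_signature(xt, ta))
        sig_c = signature_sets(differential_signature(xc, ca))
    return dict(cfg=cfg, truth=truth, x_all=x_all, assign=assign, sig_t=sig_t,
                sig_c=sig_c, prior=simulate_prior(cfg), pairs=true_pairs(cfg))


class TestPropensityScan:
    def test_grid_shape(self, scan_world):
        w = scan_world
        grid, _ = propensity_scan(w["sig_t"], w["sig_c"], w["x_all"], w["assign"],
                                  w["prior"], w["pairs"])
        assert len(grid) == 4 * 3 * 2
        assert set(grid["direction"]) == {"tumor->cd8", "cd8->tumor"}

    def test_planted_cell_is_grid_minimum(self, scan_world):
        w = scan_world
        grid, _ = propensity_scan(w["sig_t"], w["sig_c"], w["x_all"], w["assign"],
                                  w["prior"], w["pairs"])
        best = grid.loc[grid["p_hyper"].idxmin()]
        assert best["tumor_state"] == w["truth"].circuit_sender
        assert best["cd8_state"] == w["truth"].circuit_receiver
        assert best["direction"] == w["truth"].circuit_direction
        assert best["p_hyper"] < 0.001

    def test_empty_signatures_give_p_one(self, scan_world):
        w = scan_world
        empty_t = {s: [] for s in w["sig_t"]}
        empty_c = {s: [] for s in w["sig_c"]}
        with pytest.warns(UserWarning, match="empty signatures"):
            grid, _ = propensity_scan(empty_t, empty_c, w["x_all"], w["assign"],
                                      w["prior"], w["pairs"])
        assert (grid["p_hyper"] == 1.0).all()
        assert len(grid) == 4 * 3 * 2

    def test_function_variant_substitution_identity(self, scan_world):
        w = scan_world
        grid1, _ = propensity_scan(w["sig_t"], w["sig_c"], w["x_all"], w["assign"],
                                   w["prior"], w["pairs"])
        sig_t = {s: g for s, g in w["sig_t"].items() if g}
        sig_c = {s: g for s, g in w["sig_c"].items() if g}
        grid2, _ = function_related_variant(sig_t, sig_c, w["x_all"], w["assign"],
                                            w["prior"], w["pairs"])
        merged = grid1.merge(grid2, on=["direction", "tumor_state", "cd8_state"],
                             suffixes=("_a", "_b"))
        assert np.allclose(merged["p_hyper_a"], merged["p_hyper_b"])

    def test_function_variant_empty_set_rejected(self, scan_world):
        w = scan_world
        with pytest.raises(ValueError, match="empty function set"):
            function_related_variant({"f": []}, {"g": ["G0001"]}, w["x_all"],
                                     w["assign"], w["prior"], w["pairs"])


class TestAssembleChains:
    def test_join_on_ligand(self):
        tf_l = pd.DataFrame({"tf": ["P"], "ligand": ["L1"]})
        lrt = pd.DataFrame({"ligand": ["L1"], "receptor": ["R1"], "tf": ["F"]})
        chains = assemble_chains(tf_l, lrt)
        assert chains.iloc[0].tolist() == ["P", "L1", "R1", "F"]

    def test_no_shared_ligand_empty(self):
        tf_l = pd.DataFrame({"tf": ["P"], "ligand": ["L1"]})
        lrt = pd.DataFrame({"ligand": ["L2"], "receptor": ["R1"], "tf": ["F"]})
        assert assemble_chains(tf_l, lrt).empty

    def test_duplicates_collapse(self):
        tf_l = pd.DataFrame({"tf": ["P", "P"], "ligand": ["L1", "L1"]})
        lrt = pd.DataFrame({"ligand": ["L1"], "receptor": ["R1"], "tf": ["F"]})
        assert len(assemble_chains(tf_l, lrt)) == 1

    def test_missing_columns(self):
        with pytest.raises(ValueError, match="columns"):
            assemble_chains(pd.DataFrame({"tf": ["P"]}),
                            pd.DataFrame({"ligand": ["L"], "receptor": ["R"],
                                          "tf": ["F"]}))
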