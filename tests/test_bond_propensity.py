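"""Energy graph construction and bond-to-bond propensity machinery."""

import numpy as np
import pandas as pd
import pytest

from conftest import dense_propensity_oracle, random_energy_graph
from ensmut.bond_propensity import (
    ENERGY_GRAPH_PARAMS,
    EnergyGraph,
    build_energy_graph,
    edge_propensity,
    quantile_score,
    snapshot_average,
)
from ensmut.ensemble_io import ConformationalEnsemble
from ensmut.synthetic_data import gen_gaussian_ensemble


def _graph_from_edges(n_nodes, edges, weights, coords=None):
    rng = np.random.default_rng(0)
    if coords is None:
        coords = rng.normal(size=(n_nodes, 3)) * 10
    nodes = pd.DataFrame(
        {
            "atom_name": ["CA"] * n_nodes,
            "element": ["C"] * n_nodes,
            "residue_index": np.arange(n_nodes) + 1,
            "residue_name": ["ALA"] * n_nodes,
            "chain_id": ["A"] * n_nodes,
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        }
    )
    edf = pd.DataFrame(
        {
            "i": [a for a, _ in edges],
            "j": [b for _, b in edges],
            "weight": weights,
            "kind": ["covalent"] * len(edges),
        }
    )
    return EnergyGraph(nodes, edf)


class TestGraphConstruction:
    def test_distant_uncharged_atoms_no_edge(self):
        atoms = pd.DataFrame(
            {
                "atom_name": ["CA", "CA"], "element": ["C", "C"],
                "residue_index": [1, 2], "residue_name": ["ALA", "ALA"],
                "chain_id": ["A", "A"],
            }
        )
        coords = np.array([[[0, 0, 0], [10.0, 0, 0]]])
        with pytest.warns(UserWarning):
            g = build_energy_graph(ConformationalEnsemble(atoms, coords))
        assert g.n_edges == 0

    def test_ideal_hbond_matches_12_10_potential(self):
        # C=O ... N with d(O,N)=2.9 A and angle N-O-C = 120 deg
        d0 = ENERGY_GRAPH_PARAMS["hbond_d0"]
        eps = ENERGY_GRAPH_PARAMS["hbond_eps"]
        c = np.array([0.0, 0.0, 0.0])
        o = np.array([1.23, 0.0, 0.0])
        ang = np.radians(180.0 - 120.0)
        n = o + d0 * np.array([np.cos(ang), np.sin(ang), 0.0])
        atoms = pd.DataFrame(
            {
                "atom_name": ["C", "O", "N"],
                "element": ["C", "O", "N"],
                "residue_index": [1, 1, 5],
                "residue_name": ["GLY", "GLY", "GLY"],
                "chain_id": ["A", "A", "A"],
            }
        )
        ens = ConformationalEnsemble(atoms, np.array([[c, o, n]]))
        with pytest.warns(UserWarning):  # lone-atom residues use heuristics
            g = build_energy_graph(ens)
        hb = g.edges[g.edges["kind"] == "hbond"]
        assert len(hb) == 1
        # independent 12-10 evaluation at d = d0: -eps * (5 - 6) = -(-eps)
        r = d0 / d0
        expected = -eps * (5 * r**12 - 6 * r**10)
        assert hb["weight"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_polyala_covalent_count(self, helix10):
        g = build_energy_graph(helix10)
        cov = g.edges[g.edges["kind"] == "covalent"]
        # ALA heavy-atom template: N-CA, CA-C, C-O, CA-CB = 4 per residue,
        # plus 9 peptide bonds
        assert len(cov) == 4 * 10 + 9

    def test_weights_positive_no_duplicates(self, dimer):
        g = build_energy_graph(dimer)
        assert (g.edges["weight"] > 0).all()
        pairs = set(zip(g.edges["i"], g.edges["j"]))
        assert len(pairs) == g.n_edges


class TestEdgePropensity:
    def test_star_graph_symmetry(self):
        # hub 0, leaves 1..5, equal weights; source = edge (0,1).  In a tree
        # the injected flow runs through the source edge alone, so all other
        # peripheral edges receive equal (zero) propensity.
        edges = [(0, k) for k in range(1, 6)]
        g = _graph_from_edges(6, edges, np.ones(5))
        res = edge_propensity(g, np.array([0]))
        others = res.raw[1:]
        assert np.allclose(others, others[0])
        assert np.allclose(others, 0.0, atol=1e-12)

    def test_cycle_graph_symmetry_and_normalization(self):
        # 6-cycle, equal weights: edges equidistant from the source edge
        # must receive equal propensity, and the total must be 1
        edges = [(k, (k + 1) % 6) for k in range(6)]
        edges = [(min(a, b), max(a, b)) for a, b in edges]
        g = _graph_from_edges(6, edges, np.ones(6))
        res = edge_propensity(g, np.array([0]))  # edge (0,1)
        p = res.propensity
        assert p.sum() == pytest.approx(1.0)
        # edges (1,2) and (0,5) are mirror images, as are (2,3) and (4,5)
        by_pair = {
            (int(g.edges["i"][e]), int(g.edges["j"][e])): p[e]
            for e in range(6)
        }
        assert by_pair[(1, 2)] == pytest.approx(by_pair[(0, 5)], abs=1e-12)
        assert by_pair[(2, 3)] == pytest.approx(by_pair[(4, 5)], abs=1e-12)

    def test_path_graph_matches_dense_oracle(self):
        # tree case: compare raw transfer magnitudes (the normalized vector
        # is degenerate because only the source edge carries flow)
        edges = [(0, 1), (1, 2), (2, 3), (3, 4)]
        g = _graph_from_edges(5, edges, [1.0, 2.0, 3.0, 4.0])
        res = edge_propensity(g, np.array([0]))
        m, n = g.n_edges, g.n_nodes
        b = np.zeros((m, n))
        b[np.arange(m), g.edges["i"]] = 1.0
        b[np.arange(m), g.edges["j"]] = -1.0
        w_d = np.diag(g.edges["weight"].to_numpy())
        transfer = w_d @ b @ np.linalg.pinv(
            b.T @ w_d @ b, hermitian=True
        ) @ b.T @ w_d
        assert np.abs(res.raw - np.abs(transfer[:, 0])).max() < 1e-10

    def test_random_graphs_match_dense_oracle(self):
        rng = np.random.default_rng(100)
        for _ in range(20):
            g = random_energy_graph(
                int(rng.integers(10, 40)), int(rng.integers(40, 80)), rng
            )
            src = rng.choice(g.n_edges, 3, replace=False)
            res = edge_propensity(g, src)
            oracle = dense_propensity_oracle(g, src)
            assert np.abs(res.propensity - oracle).max() < 1e-8
            assert res.propensity.sum() == pytest.approx(1.0)

    def test_orientation_flip_invariance(self):
        rng = np.random.default_rng(7)
        g = random_energy_graph(15, 30, rng)
        flipped = g.edges.copy()
        flip = rng.random(len(flipped)) < 0.5
        flipped.loc[flip, ["i", "j"]] = flipped.loc[flip, ["j", "i"]].to_numpy()
        g2 = EnergyGraph(g.nodes, flipped)
        a = edge_propensity(g, np.array([2])).propensity
        b = edge_propensity(g2, np.array([2])).propensity
        assert np.abs(a - b).max() < 1e-12

    def test_node_relabel_invariance(self):
        rng = np.random.default_rng(9)
        g = random_energy_graph(12, 25, rng)
        perm = rng.permutation(12)
        nodes2 = g.nodes.iloc[np.argsort(perm)].reset_index(drop=True)
        edges2 = g.edges.copy()
        edges2["i"] = perm[g.edges["i"].to_numpy()]
        edges2["j"] = perm[g.edges["j"].to_numpy()]
        g2 = EnergyGraph(nodes2, edges2)
        a = edge_propensity(g, np.array([4])).propensity
        b = edge_propensity(g2, np.array([4])).propensity
        assert np.abs(a - b).max() < 1e-12

    def test_empty_source_rejected(self):
        g = _graph_from_edges(3, [(0, 1), (1, 2)], [1.0, 1.0])
        with pytest.raises(ValueError, match="non-empty"):
            edge_propensity(g, np.array([], dtype=int))


class TestQuantileScore:
    def test_scores_bounded_on_random_graphs(self):
        rng = np.random.default_rng(200)
        for _ in range(10):
            g = random_energy_graph(40, 100, rng)
            res = quantile_score(edge_propensity(g, np.array([0, 1])))
            assert res.edge_score.min() >= 0.0
            assert res.edge_score.max() <= 1.0
            assert res.residue_score["score"].between(0, 1).all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(201)
        g = random_energy_graph(40, 100, rng)
        res = quantile_score(edge_propensity(g, np.array([0, 1])))
        g2 = EnergyGraph(g.nodes, g.edges.assign(weight=g.edges["weight"] * 2))
        res2 = quantile_score(edge_propensity(g2, np.array([0, 1])))
        assert np.array_equal(res.edge_score, res2.edge_score)

    def test_stratum_maximum_scores_high(self):
        rng = np.random.default_rng(44)
        g = random_energy_graph(60, 150, rng)
        res = quantile_score(edge_propensity(g, np.array([0, 1, 2])))
        mask = (~res.is_source) & (res.propensity > 0)
        d = res.distance[mask]
        lp = np.log10(res.propensity[mask])
        sc = res.edge_score[mask]
        # global empirical maximum (largest propensity overall)
        assert sc[np.argmax(lp)] >= 0.95
        # per-quartile-stratum maxima rank near the top of their stratum
        qs = np.quantile(d, [0, 0.25, 0.5, 0.75, 1.0])
        for b in range(4):
            sel = (d >= qs[b]) & (d <= qs[b + 1])
            if sel.sum() >= 10:
                assert sc[sel][np.argmax(lp[sel])] >= 0.9


class TestSnapshotAverage:
    def test_identical_frames_equal_single_frame(self, dimer):
        ens = ConformationalEnsemble(
            dimer.atoms, np.repeat(dimer.coords, 3, axis=0)
        )
        avg = snapshot_average(ens, [1], n_snapshots=3, seed=0)
        single = snapshot_average(dimer, [1], n_snapshots=1, seed=0)
        merged = avg.merge(single, on="residue_index", suffixes=("_a", "_s"))
        assert np.allclose(merged["score_a"], merged["score_s"])

    def test_seed_determinism(self, helix10):
        ens, _ = gen_gaussian_ensemble(helix10, 0.15, 12, seed=3)
        a = snapshot_average(ens, [1], n_snapshots=4, seed=11)
        b = snapshot_average(ens, [1], n_snapshots=4, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_all_frames_when_requested(self, helix10):
        ens, _ = gen_gaussian_ensemble(helix10, 0.15, 3, seed=4)
        avg = snapshot_average(ens, [1], n_snapshots=3, seed=0)
        assert len(avg) > 0
        with pytest.raises(ValueError):
            snapshot_average(ens, [1], n_snapshots=5)
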