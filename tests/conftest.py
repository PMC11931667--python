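"""Shared fixtures: toy structures, random energy graphs, dense oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ensmut.bond_propensity import EnergyGraph
from ensmut.synthetic_data import ToyComplexSpec, build_toy_complex


@pytest.fixture(scope="session")
def helix10():
    """Single 10-residue ideal poly-Ala helix (1 frame)."""
    return build_toy_complex(ToyComplexSpec(chains=[("A", 10)]))


@pytest.fixture(scope="session")
def dimer():
    """Two 10-residue helices, 8 A axis separation: a contacting dimer."""
    return build_toy_complex(
        ToyComplexSpec(chains=[("A", 10), ("B", 10)], separation=8.0)
    )


def random_energy_graph(
    n_nodes: int, n_edges: int, rng: np.random.Generator
) -> EnergyGraph:
    """Connected random graph with uniform(0.5, 5) weights as an EnergyGraph.

    Nodes get random coordinates so distance-based scoring is exercised;
    each node is its own residue.
    """
    n_edges = min(n_edges, n_nodes * (n_nodes - 1) // 2)
    edges = set()
    for v in range(1, n_nodes):
        edges.add((int(rng.integers(0, v)), v))
    while len(edges) < n_edges:
        u, v = rng.integers(0, n_nodes, 2)
        if u != v:
            edges.add((min(int(u), int(v)), max(int(u), int(v))))
    e = sorted(edges)
    nodes = pd.DataFrame(
        {
            "atom_name": ["CA"] * n_nodes,
            "element": ["C"] * n_nodes,
            "residue_index": np.arange(n_nodes) + 1,
            "residue_name": ["ALA"] * n_nodes,
            "chain_id": ["A"] * n_nodes,
            "x": rng.normal(size=n_nodes) * 10,
            "y": rng.normal(size=n_nodes) * 10,
            "z": rng.normal(size=n_nodes) * 10,
        }
    )
    edf = pd.DataFrame(
        {
            "i": [a for a, _ in e],
            "j": [b for _, b in e],
            "weight": rng.uniform(0.5, 5, len(e)),
            "kind": ["covalent"] * len(e),
        }
    )
    return EnergyGraph(nodes, edf)


def dense_propensity_oracle(graph: EnergyGraph, source_edges) -> np.ndarray:
    """Normalized propensities via an explicit dense pseudoinverse."""
    m, n = graph.n_edges, graph.n_nodes
    ii = graph.edges["i"].to_numpy()
    jj = graph.edges["j"].to_numpy()
    w = graph.edges["weight"].to_numpy()
    b = np.zeros((m, n))
    b[np.arange(m), ii] = 1.0
    b[np.arange(m), jj] = -1.0
    w_d = np.diag(w)
    lap = b.T @ w_d @ b
    transfer = w_d @ b @ np.linalg.pinv(lap, hermitian=True) @ b.T @ w_d
    src_raw = np.abs(transfer[:, source_edges]).sum(axis=1)[
        np.asarray(source_edges)
    ].sum()
    raw = np.abs(transfer[:, source_edges]).sum(axis=1)
    raw[np.asarray(source_edges)] = 0.0
    if raw.sum() <= 1e-10 * src_raw:  # bridge-only source: exact zeros
        return np.zeros_like(raw)
    return raw / raw.sum()


def torsion_oracle(p0, p1, p2, p3) -> float:
    """Independent four-atom torsion: signed angle via plane normals.

    Uses the arccos-of-normals construction with an explicit sign from the
    scalar triple product (a different formulation from the library's
    projection-based arctan2 computation).
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    n1 = np.cross(p1 - p0, p2 - p1)
    n2 = np.cross(p2 - p1, p3 - p2)
    cosang = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), p2 - p1) < 0:
        ang = -ang
    return ((ang + 180.0) % 360.0) - 180.0
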