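"""Suboptimal-path analysis on a correlation-weighted residue network.

Allosteric communication routes between a source residue and a sink (e.g.
an active-site residue) are modelled as shortest paths on a graph whose
nodes are residues, whose edges require both a physical contact (minimum
heavy-atom distance below a cutoff) and a feature correlation above a
threshold, and whose edge weight is ``-log |C_ij|`` so that strongly
correlated contacts are cheap to traverse.  The k shortest loopless paths
and their node/edge degeneracies summarize the communication corridor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import islice

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial import cKDTree

from .ensemble_io import ConformationalEnsemble, DihedralSeries

__all__ = [
    "CorrelationNetwork",
    "PathEnsemble",
    "feature_correlation",
    "reduce_to_residue",
    "contact_matrix",
    "build_network",
    "k_shortest_paths",
    "path_summary",
]

DEFAULT_CONTACT_CUTOFF = 6.0   # A, minimum heavy-atom distance
DEFAULT_CORR_CUTOFF = 0.25     # |C_ij| threshold for an edge
DEFAULT_K = 500


def feature_correlation(
    series: list[DihedralSeries],
) -> tuple[np.ndarray, list[int]]:
    """Pearson correlation between structural features.

    Features are the sin and cos of every dihedral series (two per series),
    which linearizes the circular variables.  Returns ``(corr, residues)``
    where ``residues[f]`` is the residue index owning feature ``f``.
    Zero-variance features get correlation 0 with a warning.
    """
    if len(series) < 2:
        raise ValueError("need at least two dihedral series")
    n_frames = len(series[0].values)
    feats, owners = [], []
    for s in series:
        if len(s.values) != n_frames:
            raise ValueError("all series must have equal frame counts")
        rad = np.radians(s.values)
        feats.extend([np.sin(rad), np.cos(rad)])
        owners.extend([int(s.residue_index)] * 2)
    mat = np.array(feats)
    sd = mat.std(axis=1)
    dead = sd < 1e-12
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance features; correlation 0")
    corr = np.zeros((len(feats), len(feats)))
    alive = ~dead
    if alive.sum() >= 2:
        sub = np.corrcoef(mat[alive])
        corr[np.ix_(alive, alive)] = sub
    np.fill_diagonal(corr, 1.0)
    return corr, owners


def reduce_to_residue(
    feature_corr: np.ndarray,
    feature_residues: list[int],
) -> tuple[np.ndarray, list[int]]:
    """Residue-level correlation: max |r| over cross-feature pairs, diag 1.

    Returns ``(C, residues)`` with residues sorted ascending.  A residue
    with no features keeps zero off-diagonal correlation (flagged).
    """
    residues = sorted(set(int(r) for r in feature_residues))
    pos = {r: i for i, r in enumerate(residues)}
    n = len(residues)
    c_mat = np.zeros((n, n))
    owners = np.array([pos[int(r)] for r in feature_residues])
    abs_corr = np.abs(np.asarray(feature_corr))
    for a in range(n):
        fa = np.where(owners == a)[0]
        for b in range(a + 1, n):
            fb = np.where(owners == b)[0]
            if len(fa) and len(fb):
                v = float(abs_corr[np.ix_(fa, fb)].max())
                c_mat[a, b] = c_mat[b, a] = v
    np.fill_diagonal(c_mat, 1.0)
    return c_mat, residues


def contact_matrix(
    ens: ConformationalEnsemble,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    mode: str = "mean",
    min_fraction: float = 0.5,
) -> tuple[np.ndarray, list[int]]:
    """Boolean residue-residue contact matrix.

    Two residues are in contact when their minimum heavy-atom distance is
    at or below ``cutoff``.  ``mode='mean'`` (default) evaluates the
    ensemble-average structure; ``mode='fraction'`` requires the contact in
    at least ``min_fraction`` of frames.  Self-contacts are excluded.
    """
    keys = ens.residue_keys()
    residues = [rid for _, rid in keys]
    n = len(keys)
    heavy = (ens.atoms["element"] != "H").to_numpy()
    masks = [ens.atom_mask(c, r) & heavy for c, r in keys]

    def frame_contacts(xyz: np.ndarray) -> np.ndarray:
        out = np.zeros((n, n), dtype=bool)
        trees = [cKDTree(xyz[m]) for m in masks]
        for a in range(n):
            for b in range(a + 1, n):
                d = trees[a].query(xyz[masks[b]], k=1)[0].min()
                if d <= cutoff:
                    out[a, b] = out[b, a] = True
        return out

    if mode == "mean":
        contacts = frame_contacts(ens.coords.mean(axis=0))
    elif mode == "fraction":
        counts = np.zeros((n, n))
        for f in range(ens.n_frames):
            counts += frame_contacts(ens.coords[f])
        contacts = counts / ens.n_frames >= min_fraction
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return contacts, residues


@dataclass
class CorrelationNetwork:
    """Residue graph: edge iff contact AND |C_ij| >= cutoff; weight -log|C|."""

    residues: list[int]
    correlation: np.ndarray = field(repr=False)
    contacts: np.ndarray = field(repr=False)
    corr_cutoff: float = DEFAULT_CORR_CUTOFF

    def __post_init__(self) -> None:
        n = len(self.residues)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.contacts = np.asarray(self.contacts, dtype=bool)
        if self.correlation.shape != (n, n) or self.contacts.shape != (n, n):
            raise ValueError("matrix shapes must match the residue list")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation diagonal must be 1")
        if np.abs(self.correlation).max() > 1 + 1e-9:
            raise ValueError("|C_ij| must not exceed 1")


def build_network(net: CorrelationNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.residues)
    n = len(net.residues)
    absc = np.abs(net.correlation)
    for a in range(n):
        for b in range(a + 1, n):
            if net.contacts[a, b] and absc[a, b] >= net.corr_cutoff:
                # -log|C| >= 0 since |C| <= 1; clip exact 1 to weight 0
                w = float(-np.log(min(absc[a, b], 1.0)))
                g.add_edge(net.residues[a], net.residues[b], weight=w)
    return g


@dataclass
class PathEnsemble:
    """Ranked loopless paths from source to sink with degeneracy counts."""

    source: int
    sink: int
    paths: list[list[int]]
    weights: list[float]
    k_requested: int
    status: str = "ok"  # ok | isolated | no-path

    def node_degeneracy(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for p in self.paths:
            for node in p:
                counts[node] = counts.get(node, 0) + 1
        return counts

    def edge_degeneracy(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for p in self.paths:
            for a, b in zip(p[:-1], p[1:]):
                key = (min(a, b), max(a, b))
                counts[key] = counts.get(key, 0) + 1
        return counts


def _path_weight(g: nx.Graph, path: list[int]) -> float:
    return float(
        sum(g[a][b]["weight"] for a, b in zip(path[:-1], path[1:]))
    )


def k_shortest_paths(
    net: CorrelationNetwork | nx.Graph,
    source: int,
    sink: int,
    k: int = DEFAULT_K,
) -> PathEnsemble:
    """The k shortest loopless paths in non-decreasing total weight.

    Ties in total weight are broken by lexicographic node sequence so the
    output is deterministic.  Fewer than k paths are returned when the
    graph admits fewer; an isolated source or sink yields an empty
    ensemble with an explicit status.
    """
    g = build_network(net) if isinstance(net, CorrelationNetwork) else net
    if source not in g or sink not in g:
        raise ValueError("source and sink must be nodes of the network")
    if source == sink:
        return PathEnsemble(source, sink, [[source]], [0.0], k)
    if g.degree(source) == 0 or g.degree(sink) == 0:
        return PathEnsemble(source, sink, [], [], k, status="isolated")
    try:
        gen = nx.shortest_simple_paths(g, source, sink, weight="weight")
        raw = list(islice(gen, k))
        if len(raw) == k:
            # absorb further paths tied with the k-th weight so the final
            # lexicographic tie-break cannot depend on generator order
            kth = _path_weight(g, raw[-1])
            for extra in gen:
                if _path_weight(g, extra) > kth + 1e-12:
                    break
                raw.append(extra)
    except nx.NetworkXNoPath:
        return PathEnsemble(source, sink, [], [], k, status="no-path")
    scored = sorted(
        ((p, _path_weight(g, p)) for p in raw),
        key=lambda t: (t[1], t[0]),
    )[:k]
    return PathEnsemble(
        source, sink,
        [p for p, _ in scored],
        [w for _, w in scored],
        k,
    )


def path_summary(pe: PathEnsemble) -> tuple[pd.DataFrame, int]:
    """Node-degeneracy table and the minimal path length in residues."""
    if not pe.paths:
        raise ValueError("empty path ensemble")
    table = pd.DataFrame(
        sorted(pe.node_degeneracy().items()), columns=["residue_index", "count"]
    )
    return table, min(len(p) for p in pe.paths)
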