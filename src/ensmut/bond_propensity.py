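"""Bond-to-bond propensity on an energy-weighted atomistic graph.

A protein frame is converted into a graph whose nodes are heavy atoms and
whose edges are weighted interactions (covalent bonds, hydrogen bonds,
screened electrostatics, hydrophobic contacts).  A perturbation injected
at a set of source edges (e.g. all bonds of the active-site residues)
redistributes over every other edge according to an edge formulation of
random walks: with incidence matrix ``B``, weight diagonal ``W`` and
weighted Laplacian ``L = B^T W B``, the edge-to-edge transfer matrix is
``M = W B L^+ B^T W`` and the propensity of edge ``b`` is
``sum over source edges b' of |M[b, b']|``, normalized to sum 1 over
non-source edges.  Because raw propensities decay with distance from the
source, each edge is ranked against peers at its distance by quantile
regression, yielding a quantile score in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .aminoacids import APOLAR_CARBONS, CHARGED_ATOMS
from .ensemble_io import ConformationalEnsemble, to_atom_array_stack

__all__ = [
    "EnergyGraph",
    "PropensityResult",
    "ENERGY_GRAPH_PARAMS",
    "build_energy_graph",
    "edge_propensity",
    "quantile_score",
    "snapshot_average",
]

# All interaction-potential constants in one place.  Functional forms follow
# the atomistic energy-graph literature: harmonic-strength covalent bonds by
# element pair, a 12-10 hydrogen-bond potential with an angular factor at the
# acceptor, screened Coulomb (distance-dependent dielectric eps(r) = 4r) for
# charged groups, and a constant-depth hydrophobic well for apolar carbons.
ENERGY_GRAPH_PARAMS = {
    "covalent_energy": {  # kcal/mol per bond, by element pair
        ("C", "C"): 83.0, ("C", "N"): 70.0, ("C", "O"): 84.0,
        ("C", "S"): 62.0, ("N", "O"): 48.0, ("S", "S"): 54.0,
        ("N", "N"): 38.0, ("O", "O"): 35.0,
    },
    "covalent_default": 60.0,
    "hbond_cutoff": 3.5,        # A donor-acceptor
    "hbond_d0": 2.9,            # A equilibrium donor-acceptor distance
    "hbond_eps": 5.0,           # kcal/mol well depth
    "hbond_angle0": 120.0,      # deg, ideal donor-acceptor-antecedent angle
    "elec_cutoff": 6.0,         # A between charged atoms
    "coulomb_k": 332.06,        # kcal*A/(mol*e^2)
    "hydrophobic_cutoff": 5.0,  # A between apolar carbons
    "hydrophobic_eps": 0.1,     # kcal/mol per contact
}

_DONOR_ATOMS = {
    "backbone": {"N"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
_ACCEPTOR_ATOMS = {
    "backbone": {"O", "OXT"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}


@dataclass
class EnergyGraph:
    """Heavy-atom interaction graph of one structure frame.

    ``nodes`` has one row per atom (atom_name, element, residue_index,
    chain_id, x, y, z); ``edges`` columns are ``i, j, weight, kind`` with
    ``i < j``, strictly positive weights and no duplicates.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.edges):
            if (self.edges["weight"] <= 0).any():
                raise ValueError("edge weights must be strictly positive")
            if (self.edges["i"] == self.edges["j"]).any():
                raise ValueError("self-edges are not allowed")
            pairs = list(zip(self.edges["i"], self.edges["j"]))
            if len(pairs) != len(set(pairs)):
                raise ValueError("duplicate edges")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def coords(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy()

    def edges_of_residues(self, residues) -> np.ndarray:
        """Indices of edges incident to any atom of the given residues."""
        residues = set(int(r) for r in residues)
        atom_in = self.nodes["residue_index"].isin(residues).to_numpy()
        return np.where(
            atom_in[self.edges["i"].to_numpy()]
            | atom_in[self.edges["j"].to_numpy()]
        )[0]


def _hbond_energy(d: float, p: dict) -> float:
    r = p["hbond_d0"] / d
    return p["hbond_eps"] * (5.0 * r**12 - 6.0 * r**10)


def build_energy_graph(
    frame: ConformationalEnsemble,
    params: dict | None = None,
) -> EnergyGraph:
    """Energy-weighted atomistic graph of a single frame.

    Covalent edges come from standard residue connectivity templates (with
    an element-distance fallback for unknown residues); hydrogen-bond,
    electrostatic and hydrophobic edges from the geometric criteria in
    ``ENERGY_GRAPH_PARAMS``.  All weights are positive interaction
    magnitudes in kcal/mol.
    """
    p = dict(ENERGY_GRAPH_PARAMS)
    if params:
        p.update(params)
    atoms = frame.atoms
    heavy = (atoms["element"] != "H").to_numpy()
    idx_map = np.where(heavy)[0]
    back = {orig: new for new, orig in enumerate(idx_map)}
    xyz = frame.coords[0][heavy]
    sub = atoms.iloc[idx_map].reset_index(drop=True)
    nodes = pd.DataFrame(
        {
            "atom_name": sub["atom_name"],
            "element": sub["element"],
            "residue_index": sub["residue_index"].astype(int),
            "residue_name": sub["residue_name"],
            "chain_id": sub["chain_id"],
            "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        }
    )
    edge_dict: dict[tuple[int, int], tuple[float, str]] = {}

    def add_edge(i: int, j: int, w: float, kind: str, replace: bool = False) -> None:
        if i == j or w <= 0:
            return
        key = (min(i, j), max(i, j))
        if replace or key not in edge_dict:
            edge_dict[key] = (w, kind)

    # covalent edges from residue templates
    stack = to_atom_array_stack(frame)
    arr = stack[0]
    try:
        bonds = struc.connect_via_residue_names(arr)
        bond_pairs = bonds.as_array()[:, :2]
    except Exception:
        bond_pairs = np.empty((0, 2), dtype=int)
    known = set(map(tuple, bond_pairs.tolist()))
    for a, b in known:
        if heavy[a] and heavy[b]:
            ea, eb = sorted([atoms["element"].iloc[a], atoms["element"].iloc[b]])
            w = p["covalent_energy"].get((ea, eb), p["covalent_default"])
            add_edge(back[a], back[b], w, "covalent", replace=True)
    # element-distance fallback for residues the templates do not cover
    covered = {r for pair in known for r in (
        int(atoms["residue_index"].iloc[pair[0]]),
        int(atoms["residue_index"].iloc[pair[1]]),
    )}
    uncovered_res = set(nodes["residue_index"]) - covered
    if uncovered_res:
        warnings.warn(
            f"residues {sorted(uncovered_res)} lack connectivity templates; "
            "using element-distance heuristic"
        )
        mask = nodes["residue_index"].isin(uncovered_res).to_numpy()
        tree = cKDTree(xyz)
        for i, j in tree.query_pairs(1.8):
            if mask[i] or mask[j]:
                ea, eb = sorted([nodes["element"].iloc[i], nodes["element"].iloc[j]])
                add_edge(i, j, p["covalent_energy"].get((ea, eb), p["covalent_default"]),
                         "covalent")
    # also connect consecutive backbone C-N (peptide bonds across residues)
    name_arr = nodes["atom_name"].to_numpy()
    res_arr = nodes["residue_index"].to_numpy()
    chain_arr = nodes["chain_id"].to_numpy()
    c_idx = {(c, r): i for i, (c, r, n) in enumerate(zip(chain_arr, res_arr, name_arr)) if n == "C"}
    n_idx = {(c, r): i for i, (c, r, n) in enumerate(zip(chain_arr, res_arr, name_arr)) if n == "N"}
    for (c, r), ci in c_idx.items():
        ni = n_idx.get((c, r + 1))
        if ni is not None and np.linalg.norm(xyz[ci] - xyz[ni]) < 2.0:
            add_edge(ci, ni, p["covalent_energy"][("C", "N")], "covalent")

    # hydrogen bonds (donor-acceptor heavy-atom geometry, 12-10 potential,
    # cos^2 angular factor at the acceptor)
    donors, acceptors = [], []
    for i in range(len(nodes)):
        rn, an = nodes["residue_name"].iloc[i], name_arr[i]
        if an in _DONOR_ATOMS["backbone"] or an in _DONOR_ATOMS.get(rn, ()):
            donors.append(i)
        if an in _ACCEPTOR_ATOMS["backbone"] or an in _ACCEPTOR_ATOMS.get(rn, ()):
            acceptors.append(i)
    # acceptor antecedent: nearest covalently plausible heavy atom
    tree = cKDTree(xyz)
    covalent_adj: dict[int, list[int]] = {}
    for (i, j), (w, kind) in edge_dict.items():
        if kind == "covalent":
            covalent_adj.setdefault(i, []).append(j)
            covalent_adj.setdefault(j, []).append(i)
    acc_tree = cKDTree(xyz[acceptors]) if acceptors else None
    for d_i in donors:
        if acc_tree is None:
            break
        for a_pos in acc_tree.query_ball_point(xyz[d_i], p["hbond_cutoff"]):
            a_i = acceptors[a_pos]
            if a_i == d_i or res_arr[a_i] == res_arr[d_i] and chain_arr[a_i] == chain_arr[d_i]:
                continue
            dist = float(np.linalg.norm(xyz[d_i] - xyz[a_i]))
            if dist < 2.0:
                continue
            e = _hbond_energy(dist, p)
            if e >= 0:
                continue
            ante = covalent_adj.get(a_i, [])
            if ante:
                v1 = xyz[d_i] - xyz[a_i]
                v2 = xyz[ante[0]] - xyz[a_i]
                cosang = float(
                    v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                dev = np.radians(ang - p["hbond_angle0"])
                f = np.cos(dev) ** 2 if abs(dev) < np.pi / 2 else 0.0
            else:
                f = 1.0
            if f > 0:
                add_edge(d_i, a_i, -e * f, "hbond")

    # screened electrostatics between charged side-chain atoms
    charged = []
    for i in range(len(nodes)):
        q = CHARGED_ATOMS.get(nodes["residue_name"].iloc[i], {}).get(name_arr[i])
        if q:
            charged.append((i, q))
    for a in range(len(charged)):
        for b in range(a + 1, len(charged)):
            i, qi = charged[a]
            j, qj = charged[b]
            if res_arr[i] == res_arr[j] and chain_arr[i] == chain_arr[j]:
                continue
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if 0 < d <= p["elec_cutoff"]:
                w = p["coulomb_k"] * abs(qi * qj) / (4.0 * d * d)
                add_edge(i, j, w, "electrostatic")

    # hydrophobic contacts between apolar carbons
    apolar = [
        i for i in range(len(nodes))
        if name_arr[i] in APOLAR_CARBONS.get(nodes["residue_name"].iloc[i], ())
    ]
    if apolar:
        ap_xyz = xyz[apolar]
        ap_tree = cKDTree(ap_xyz)
        for a, b in ap_tree.query_pairs(p["hydrophobic_cutoff"]):
            i, j = apolar[a], apolar[b]
            if res_arr[i] == res_arr[j] and chain_arr[i] == chain_arr[j]:
                continue
            add_edge(i, j, p["hydrophobic_eps"], "hydrophobic")

    if edge_dict:
        keys = sorted(edge_dict)
        edges = pd.DataFrame(
            {
                "i": [k[0] for k in keys],
                "j": [k[1] for k in keys],
                "weight": [edge_dict[k][0] for k in keys],
                "kind": [edge_dict[k][1] for k in keys],
            }
        )
    else:
        edges = pd.DataFrame(columns=["i", "j", "weight", "kind"])
    return EnergyGraph(nodes, edges)


@dataclass
class PropensityResult:
    """Per-edge propensities and distance-corrected quantile scores."""

    graph: EnergyGraph
    propensity: np.ndarray = field(repr=False)   # normalized, 0 on source edges
    raw: np.ndarray = field(repr=False)
    is_source: np.ndarray = field(repr=False)
    distance: np.ndarray = field(repr=False)     # A to nearest source atom
    edge_score: np.ndarray | None = field(default=None, repr=False)
    residue_score: pd.DataFrame | None = None

    def per_residue_propensity(self) -> pd.DataFrame:
        """Summed propensity of each residue's incident non-source edges."""
        res_i = self.graph.nodes["residue_index"].to_numpy()
        acc: dict[int, float] = {}
        ii = self.graph.edges["i"].to_numpy()
        jj = self.graph.edges["j"].to_numpy()
        for e in range(self.graph.n_edges):
            if self.is_source[e]:
                continue
            for r in {int(res_i[ii[e]]), int(res_i[jj[e]])}:
                acc[r] = acc.get(r, 0.0) + float(self.propensity[e])
        return pd.DataFrame(
            sorted(acc.items()), columns=["residue_index", "propensity"]
        )


def edge_propensity(
    graph: EnergyGraph,
    source_edges: np.ndarray,
) -> PropensityResult:
    """Propensity of every edge for perturbations at ``source_edges``.

    Solves ``L x = B^T W e_src`` per source edge with a grounded sparse LU
    factorization (shared across sources); results equal a dense
    pseudoinverse computation.  Edges outside the source's connected
    component receive propensity 0 with a warning.
    """
    source_edges = np.asarray(source_edges, dtype=int)
    if source_edges.size == 0:
        raise ValueError("source edge set must be non-empty")
    n, m = graph.n_nodes, graph.n_edges
    ii = graph.edges["i"].to_numpy()
    jj = graph.edges["j"].to_numpy()
    w = graph.edges["weight"].to_numpy(dtype=float)
    rows = np.concatenate([np.arange(m), np.arange(m)])
    cols = np.concatenate([ii, jj])
    data = np.concatenate([np.ones(m), -np.ones(m)])
    b_mat = sparse.csr_matrix((data, (rows, cols)), shape=(m, n))
    lap = (b_mat.T @ sparse.diags(w) @ b_mat).tocsr()

    n_comp, labels = csgraph.connected_components(
        sparse.csr_matrix(
            (np.ones(m), (ii, jj)), shape=(n, n)
        ) + sparse.csr_matrix((np.ones(m), (jj, ii)), shape=(n, n))
    )
    src_comp = set(labels[ii[source_edges]]) | set(labels[jj[source_edges]])
    if len(src_comp) > 1:
        raise ValueError("source edges span multiple connected components")
    comp = src_comp.pop()
    comp_nodes = np.where(labels == comp)[0]
    if n_comp > 1:
        warnings.warn(
            "graph is disconnected; edges outside the source component "
            "receive propensity 0"
        )
    # grounded Laplacian on the source component (drop the first node)
    local = {node: k for k, node in enumerate(comp_nodes)}
    grounded = comp_nodes[1:]
    lap_g = lap[np.ix_(grounded, grounded)].tocsc()
    solver = splu(lap_g)

    raw = np.zeros(m)
    edge_in_comp = np.isin(labels[ii], [comp]) & np.isin(labels[jj], [comp])
    for e_src in source_edges:
        y = np.zeros(n)
        y[ii[e_src]] += w[e_src]
        y[jj[e_src]] -= w[e_src]
        x = np.zeros(n)
        x[grounded] = solver.solve(y[grounded])
        # m_col[e] = w_e * (x[i_e] - x[j_e]); constants cancel in differences
        raw += np.abs(w * (x[ii] - x[jj])) * edge_in_comp

    # edges that carry no flow (e.g. dangling subtrees) come out as ~1e-17
    # roundoff; clip them to exact zero so downstream masks are stable
    if raw.max() > 0:
        raw[raw < 1e-12 * raw.max()] = 0.0
    is_source = np.zeros(m, dtype=bool)
    is_source[source_edges] = True
    prop = raw.copy()
    prop[is_source] = 0.0
    total = prop.sum()
    # bridge-only sources drive no flow through other edges: the exact
    # non-source propensities are all zero and must not be normalized
    # against numerical noise
    if total > 1e-10 * raw[is_source].sum():
        prop = prop / total
    else:
        if total > 0:
            warnings.warn(
                "source edges are bridges: all non-source propensities are 0"
            )
        prop[:] = 0.0

    xyz = graph.coords()
    src_atoms = np.unique(
        np.concatenate([ii[source_edges], jj[source_edges]])
    )
    tree = cKDTree(xyz[src_atoms])
    mid = 0.5 * (xyz[ii] + xyz[jj])
    distance, _ = tree.query(mid)
    return PropensityResult(graph, prop, raw, is_source, distance)


def quantile_score(
    result: PropensityResult,
    quantile_grid: np.ndarray | None = None,
) -> PropensityResult:
    """Distance-corrected quantile scores for edges and residues.

    Fits linear conditional quantiles of log10 propensity against distance
    to the source (grid 0.01..0.99, step 0.01); an edge's score is the
    largest quantile level whose fitted line at the edge's distance lies at
    or below the edge's log propensity.  The per-residue score is the score
    of that residue's maximum-propensity edge.  Scores are attached to
    ``result`` (``edge_score``, ``residue_score``) and the result returned.
    """
    import statsmodels.api as sm

    if quantile_grid is None:
        quantile_grid = np.arange(0.01, 1.0, 0.01)
    mask = (~result.is_source) & (result.propensity > 0)
    if mask.sum() < 20:
        raise ValueError("need at least 20 non-source edges with propensity")
    # rounding removes ~1e-16 float jitter (e.g. from uniform weight
    # rescaling) so the quantile fits are exactly reproducible
    y = np.round(np.log10(result.propensity[mask]), 9)
    x = result.distance[mask]
    scores = np.zeros(result.graph.n_edges)
    if np.ptp(y) < 1e-12:
        warnings.warn("degenerate all-equal propensities; scores set to 0.5")
        scores[mask] = 0.5
    else:
        exog = sm.add_constant(x)
        model = sm.QuantReg(y, exog)
        fitted = np.empty((len(quantile_grid), int(mask.sum())))
        with warnings.catch_warnings():
            # IRLS hitting the iteration cap at extreme quantiles is benign
            warnings.simplefilter("ignore")
            for qi, q in enumerate(quantile_grid):
                res = model.fit(q=q, max_iter=500)
                fitted[qi] = res.params[0] + res.params[1] * x
        at_or_below = fitted <= y[None, :] + 1e-12
        # largest quantile level whose curve lies at or below the edge
        any_below = at_or_below.any(axis=0)
        last = np.zeros(int(mask.sum()))
        idx = np.where(any_below)[0]
        last[idx] = quantile_grid[
            at_or_below.shape[0] - 1 - np.argmax(at_or_below[::-1][:, idx], axis=0)
        ]
        scores[mask] = last
    result.edge_score = scores

    res_i = result.graph.nodes["residue_index"].to_numpy()
    ii = result.graph.edges["i"].to_numpy()
    jj = result.graph.edges["j"].to_numpy()
    best: dict[int, tuple[float, float]] = {}  # residue -> (max prop, score)
    for e in range(result.graph.n_edges):
        if result.is_source[e]:
            continue
        for r in {int(res_i[ii[e]]), int(res_i[jj[e]])}:
            cur = best.get(r)
            if cur is None or result.propensity[e] > cur[0]:
                best[r] = (float(result.propensity[e]), float(scores[e]))
    result.residue_score = pd.DataFrame(
        [(r, s) for r, (_, s) in sorted(best.items())],
        columns=["residue_index", "score"],
    )
    return result


def snapshot_average(
    ens: ConformationalEnsemble,
    source_residues,
    n_snapshots: int = 9,
    seed: int | None = None,
    params: dict | None = None,
) -> pd.DataFrame:
    """Mean per-residue quantile score over randomly selected snapshots.

    Source edges are all edges incident to atoms of ``source_residues``
    (typically the active-site set).  Returns columns ``residue_index,
    score`` (mean over snapshots).
    """
    if n_snapshots > ens.n_frames:
        raise ValueError("more snapshots requested than frames available")
    rng = np.random.default_rng(seed)
    if n_snapshots == ens.n_frames:
        frames = np.arange(ens.n_frames)
    else:
        frames = np.sort(
            rng.choice(ens.n_frames, size=n_snapshots, replace=False)
        )
    acc: dict[int, list[float]] = {}
    for f in frames:
        graph = build_energy_graph(ens.frame(int(f)), params)
        src = graph.edges_of_residues(source_residues)
        res = quantile_score(edge_propensity(graph, src))
        for _, row in res.residue_score.iterrows():
            acc.setdefault(int(row["residue_index"]), []).append(
                float(row["score"])
            )
    return pd.DataFrame(
        [(r, float(np.mean(v))) for r, v in sorted(acc.items())],
        columns=["residue_index", "score"],
    )
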