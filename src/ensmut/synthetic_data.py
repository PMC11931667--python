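"""Synthetic inputs with analytically known ground truth.

Every generator here exists so that a pipeline stage can be tested against
a closed-form answer instead of a downloaded trajectory:

* :func:`gen_coupled_dihedrals` draws circular time series from a latent
  Gaussian copula, for which the pairwise mutual information is exactly
  ``-0.5 * ln(1 - rho**2)`` nats.
* :func:`gen_gaussian_ensemble` perturbs a base structure with correlated
  Gaussian displacements whose per-residue RMSF is known in closed form.
* :func:`build_toy_complex` builds small multi-chain ideal-helix complexes
  with a controlled interface geometry.
* :func:`gen_mutation_table` emits schema-valid mutation catalogs.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble_io import ConformationalEnsemble, DihedralSeries

__all__ = [
    "CouplingSpec",
    "ToyComplexSpec",
    "gen_coupled_dihedrals",
    "gen_gaussian_ensemble",
    "build_toy_complex",
    "gen_mutation_table",
    "IDEAL_HELIX_PHI",
    "IDEAL_HELIX_PSI",
]

IDEAL_HELIX_PHI = -57.0
IDEAL_HELIX_PSI = -47.0


@dataclass
class CouplingSpec:
    """Latent-correlation specification for coupled circular series."""

    n_series: int
    correlation: np.ndarray  # (n_series, n_series) latent correlation matrix
    n_frames: int
    seed: int
    concentration: float | None = None  # optional wrapped-normal noise 1/var

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (self.n_series, self.n_series):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation diagonal must be 1")


@dataclass
class ToyComplexSpec:
    """Chains of ideal poly-Ala helices placed side by side.

    ``chains`` lists ``(chain_id, n_residues)``.  ``separation`` is the
    distance in Angstrom between consecutive helix axes; ``rotations``
    optionally spins each helix about its own axis so that engineered
    side chains can face a partner chain.  ``substitutions`` replaces
    single positions with charged residues (ASP or LYS, minimal side
    chains) for interface fixtures.
    """

    chains: list[tuple[str, int]]
    separation: float = 10.0
    rotations: list[float] | None = None
    substitutions: list[tuple[str, int, str]] = field(default_factory=list)
    seed: int = 0


def correlation_pair(rho: float) -> np.ndarray:
    return np.array([[1.0, rho], [rho, 1.0]])


def latent_gaussian_mi(rho: float) -> float:
    """Exact MI in nats of a bivariate Gaussian pair with correlation rho."""
    return -0.5 * np.log(1.0 - rho**2)


def gen_coupled_dihedrals(
    spec: CouplingSpec,
) -> tuple[list[DihedralSeries], np.ndarray]:
    """Draw circular series from a Gaussian copula; return ground-truth MI.

    Latent normals with the requested correlation are mapped through the
    normal CDF to uniforms on [0, 1), then scaled to degrees on [-180, 180).
    Because MI is invariant under monotone per-variable transforms, the MI
    of every pair equals the latent-Gaussian value ``-0.5 ln(1 - rho^2)``
    exactly.  If ``concentration`` is set, independent wrapped-normal noise
    with variance ``1/concentration`` (radians^2) is added, which can only
    lower the realized MI.

    Returns ``(series, mi_truth)`` where ``mi_truth[i, j]`` is in nats.
    """
    try:
        chol = np.linalg.cholesky(spec.correlation)
    except np.linalg.LinAlgError as err:
        raise ValueError("correlation matrix is not positive definite") from err
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, spec.n_series)) @ chol.T
    u = stats.norm.cdf(z)
    angles = 360.0 * u - 180.0
    if spec.concentration is not None:
        noise = rng.normal(
            0.0, np.sqrt(1.0 / spec.concentration), size=angles.shape
        )
        angles = ((angles + np.degrees(noise) + 180.0) % 360.0) - 180.0
    series = [
        DihedralSeries(i + 1, "A", "chi1", angles[:, i])
        for i in range(spec.n_series)
    ]
    with np.errstate(divide="ignore"):
        mi_truth = -0.5 * np.log(1.0 - spec.correlation**2)
    np.fill_diagonal(mi_truth, np.inf)
    return series, mi_truth


def gen_gaussian_ensemble(
    base: ConformationalEnsemble,
    sigma,
    n_frames: int,
    seed: int,
) -> tuple[ConformationalEnsemble, pd.DataFrame]:
    """Base coordinates plus Gaussian displacements; known per-residue RMSF.

    ``sigma`` is either a scalar (isotropic per-coordinate SD in Angstrom),
    a per-atom array of SDs, or a full ``(3n, 3n)`` covariance matrix.
    Ground-truth RMSF of residue i is ``sqrt(sum of its atoms' coordinate
    variances / n_atoms_i)``; for isotropic sigma this is ``sigma*sqrt(3)``.

    Returns ``(ensemble, truth)`` with ``truth`` columns
    ``residue_index, chain, rmsf``.
    """
    n_atoms = base.n_atoms
    rng = np.random.default_rng(seed)
    base_xyz = base.coords[0]
    if np.isscalar(sigma):
        sig = np.full(n_atoms, float(sigma))
        disp = rng.normal(0.0, 1.0, size=(n_frames, n_atoms, 3)) * sig[None, :, None]
        var_atom = 3.0 * sig**2
    else:
        sigma = np.asarray(sigma, dtype=float)
        if sigma.ndim == 1:
            if sigma.shape[0] != n_atoms:
                raise ValueError("per-atom sigma length mismatch")
            disp = (
                rng.normal(0.0, 1.0, size=(n_frames, n_atoms, 3))
                * sigma[None, :, None]
            )
            var_atom = 3.0 * sigma**2
        elif sigma.shape == (3 * n_atoms, 3 * n_atoms):
            try:
                chol = np.linalg.cholesky(
                    sigma + 1e-12 * np.eye(3 * n_atoms)
                )
            except np.linalg.LinAlgError as err:
                raise ValueError("covariance not positive semidefinite") from err
            flat = rng.standard_normal((n_frames, 3 * n_atoms)) @ chol.T
            disp = flat.reshape(n_frames, n_atoms, 3)
            var_atom = np.diag(sigma).reshape(n_atoms, 3).sum(axis=1)
        else:
            raise ValueError(
                f"sigma shape {sigma.shape} does not match {n_atoms} atoms"
            )
    coords = base_xyz[None] + disp
    ens = ConformationalEnsemble(base.atoms, coords)
    rows = []
    for chain, rid in base.residue_keys():
        m = base.atom_mask(chain, rid)
        rows.append((rid, chain, float(np.sqrt(var_atom[m].mean()))))
    truth = pd.DataFrame(rows, columns=["residue_index", "chain", "rmsf"])
    return ens, truth


# -- ideal-helix builder ----------------------------------------------------

_BB_GEOMETRY = {
    # bond lengths (A) and angles (deg) of the standard peptide backbone
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231, "ca_cb": 1.521,
    "ang_c_n_ca": 121.7, "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2,
    "ang_ca_c_o": 120.8, "ang_n_ca_cb": 110.4,
}

_SIDE_CHAINS = {
    # minimal heavy-atom side chains used for charged-interface fixtures
    # (atom, parent triplet ending at bonded atom, bond, angle, dihedral)
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.0, 180.0),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.0, 0.0),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.0, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.49, 111.0, 180.0),
    ],
}

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C",
            "CD": "C", "CE": "C", "OD1": "O", "OD2": "O", "NZ": "N"}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to A-B-C."""
    ang = np.radians(angle)
    dih = np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + np.column_stack([bc, m, n]) @ d_local


def _build_helix_chain(
    chain_id: str,
    n_residues: int,
    phi: float,
    psi: float,
    substitutions: dict[int, str],
) -> tuple[list[dict], np.ndarray]:
    g = _BB_GEOMETRY
    atoms: list[dict] = []
    coords: list[np.ndarray] = []

    def add(name: str, rid: int, resname: str, xyz: np.ndarray) -> None:
        atoms.append(
            {
                "atom_name": name,
                "element": _ELEMENT[name],
                "residue_index": rid,
                "residue_name": resname,
                "chain_id": chain_id,
            }
        )
        coords.append(xyz)

    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for i in range(n_residues):
        rid = i + 1
        resname = substitutions.get(rid, "ALA")
        if i == 0:
            n = np.zeros(3)
            ca = np.array([g["n_ca"], 0.0, 0.0])
            ang = np.radians(g["ang_n_ca_c"])
            c = ca + g["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n_prev, ca_prev, c_prev = backbone[-1]
            n = _nerf(n_prev, ca_prev, c_prev, g["c_n"], g["ang_ca_c_n"], psi)
            ca = _nerf(ca_prev, c_prev, n, g["n_ca"], g["ang_c_n_ca"], 180.0)
            c = _nerf(c_prev, n, ca, g["ca_c"], g["ang_n_ca_c"], phi)
        backbone.append((n, ca, c))
        add("N", rid, resname, n)
        add("CA", rid, resname, ca)
        add("C", rid, resname, c)
        # carbonyl O anti to the next N (dihedral psi+180 about CA-C)
        add("O", rid, resname, _nerf(n, ca, c, g["c_o"], g["ang_ca_c_o"], psi + 180.0))
        if resname != "GLY":
            cb = _nerf(c, n, ca, g["ca_cb"], g["ang_n_ca_cb"], 123.0)
            add("CB", rid, resname, cb)
            placed = {"N": n, "CA": ca, "CB": cb}
            for name, (pa, pb, pc), bond, angle, dih in _SIDE_CHAINS.get(
                resname, []
            ):
                xyz = _nerf(placed[pa], placed[pb], placed[pc], bond, angle, dih)
                placed[name] = xyz
                add(name, rid, resname, xyz)
    return atoms, np.array(coords)


def _align_to_z(coords: np.ndarray, ca_mask: np.ndarray) -> np.ndarray:
    """Rotate so the helix axis (principal CA direction) lies along +z."""
    ca = coords[ca_mask]
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(axis @ z)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    out = (coords - ca.mean(axis=0)) @ rot.T
    return out


def build_toy_complex(spec: ToyComplexSpec) -> ConformationalEnsemble:
    """Deterministic multi-chain ideal-helix complex as a 1-frame ensemble.

    Chains are poly-Ala alpha helices (phi=-57, psi=-47) with axes parallel
    to z, chain k translated by ``k * separation`` along x.  Raises if any
    interatomic distance falls below 1.0 A (overlapping chains).
    """
    subs_by_chain: dict[str, dict[int, str]] = {}
    for chain_id, rid, resname in spec.substitutions:
        if resname not in _SIDE_CHAINS and resname not in ("ALA", "GLY"):
            raise ValueError(f"unsupported substitution residue {resname}")
        subs_by_chain.setdefault(chain_id, {})[rid] = resname
    all_atoms: list[dict] = []
    all_coords: list[np.ndarray] = []
    rotations = spec.rotations or [0.0] * len(spec.chains)
    if len(rotations) != len(spec.chains):
        raise ValueError("one rotation per chain required")
    for k, ((chain_id, n_res), rot_deg) in enumerate(zip(spec.chains, rotations)):
        atoms, coords = _build_helix_chain(
            chain_id, n_res, IDEAL_HELIX_PHI, IDEAL_HELIX_PSI,
            subs_by_chain.get(chain_id, {}),
        )
        ca_mask = np.array([a["atom_name"] == "CA" for a in atoms])
        coords = _align_to_z(coords, ca_mask)
        th = np.radians(rot_deg)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        coords = coords @ rot.T
        coords[:, 0] += k * spec.separation
        all_atoms.extend(atoms)
        all_coords.append(coords)
    coords = np.vstack(all_coords)
    if len(spec.chains) > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(coords)
        pairs = tree.query_pairs(1.0)
        if pairs:
            raise ValueError(
                f"{len(pairs)} interatomic distances below 1.0 A: "
                "chains overlap"
            )
    return ConformationalEnsemble(pd.DataFrame(all_atoms), coords[None])


# -- mutation catalogs ------------------------------------------------------

_AA1 = "ACDEFGHIKLMNPQRSTVWY"
_SS_LABELS = ["Loop", "alpha-helix", "beta-sheet", "beta-turn"]


def gen_mutation_table(
    n_folding: int,
    n_activity: int,
    n_unclassified: int,
    seed: int,
    n_positions: int = 1000,
) -> pd.DataFrame:
    """Random mutation catalog in the packaged-table schema.

    Columns: ``mutation, chain, group, relative_activity, distance_to_zn,
    secondary_structure, contact_chains``.  Unclassified rows get activity
    ``N.D.``; bytes are identical for identical seeds.
    """
    rng = np.random.default_rng(seed)
    rows = []
    used: set[int] = set()
    for group, count in [
        ("folding", n_folding),
        ("activity", n_activity),
        ("unclassified", n_unclassified),
    ]:
        for _ in range(count):
            while True:
                pos = int(rng.integers(50, 50 + n_positions))
                if pos not in used:
                    used.add(pos)
                    break
            wt, mut = rng.choice(list(_AA1), size=2, replace=False)
            n_contacts = int(rng.integers(0, 3))
            contacts = sorted(
                rng.choice(list("ABCDE"), size=n_contacts, replace=False)
            )
            rows.append(
                {
                    "mutation": f"{wt}{pos}{mut}",
                    "chain": str(rng.choice(list("ABCDE"))),
                    "group": group,
                    "relative_activity": (
                        "N.D." if group == "unclassified"
                        else str(int(rng.integers(1, 54)))
                    ),
                    "distance_to_zn": f"{rng.uniform(5.0, 45.0):.1f}",
                    "secondary_structure": str(rng.choice(_SS_LABELS)),
                    "contact_chains": ";".join(contacts) if contacts else "-",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mutation", "chain", "group", "relative_activity",
            "distance_to_zn", "secondary_structure", "contact_chains",
        ],
    )
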