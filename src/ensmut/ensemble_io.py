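"""Conformational-ensemble I/O and per-residue geometry descriptors.

An ensemble is a stack of structure snapshots (typically printed from a
molecular-dynamics trajectory) sharing one atom table.  This module reads
and writes multi-model PDB files, extracts dihedral-angle time series
(phi, psi, chi1..chi5), computes per-residue RMSF profiles, and subsamples
frames for downstream descriptor calculations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ConformationalEnsemble",
    "DihedralSeries",
    "read_ensemble",
    "write_ensemble",
    "extract_dihedrals",
    "compute_rmsf",
    "subsample_frames",
]

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Side-chain dihedral definitions: atom-name quadruples per residue type.
# chi angles beyond those listed do not exist for that residue.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ"),
            ("CD", "NE", "CZ", "NH1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


@dataclass
class ConformationalEnsemble:
    """Frames x atoms x 3 coordinate stack with a shared atom table.

    ``atoms`` holds one row per atom with columns ``atom_name``, ``element``,
    ``residue_index`` (1-based, preserved exactly as authored in the input
    file), ``residue_name`` (3-letter code) and ``chain_id``.  ``coords`` is
    an ``(n_frames, n_atoms, 3)`` float array in Angstrom.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate array has {self.coords.shape[1]} atoms but the "
                f"atom table has {len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> "ConformationalEnsemble":
        """Single-frame view (atom table shared)."""
        return ConformationalEnsemble(self.atoms, self.coords[i][None].copy())

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_index) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.atoms["chain_id"], self.atoms["residue_index"]):
            seen.setdefault((c, int(r)), None)
        return list(seen)

    def atom_mask(self, chain_id: str, residue_index: int) -> np.ndarray:
        return (
            (self.atoms["chain_id"] == chain_id)
            & (self.atoms["residue_index"] == residue_index)
        ).to_numpy()


@dataclass
class DihedralSeries:
    """One dihedral angle traced over every frame, in degrees in [-180, 180)."""

    residue_index: int
    chain_id: str
    angle_name: str  # phi, psi, chi1..chi5
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _wrap_degrees(a: np.ndarray) -> np.ndarray:
    """Map angles to the canonical [-180, 180) domain (+180 -> -180)."""
    return ((np.asarray(a, dtype=float) + 180.0) % 360.0) - 180.0


def read_ensemble(path) -> ConformationalEnsemble:
    """Read a multi-model PDB file into a :class:`ConformationalEnsemble`.

    Frames keep file order; residue numbering is preserved as written.
    Models with inconsistent atom counts raise a ``ValueError`` naming the
    offending model; non-standard residue names are retained with a warning.
    Water and monoatomic ions are dropped.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models < 1:
        raise ValueError(f"no models found in {path}")
    first = pdb.get_structure(model=1)
    n_atoms = first.array_length()
    frames = [first.coord]
    for m in range(2, n_models + 1):
        arr = pdb.get_structure(model=m)
        if arr.array_length() != n_atoms:
            raise ValueError(
                f"model {m} has {arr.array_length()} atoms, "
                f"model 1 has {n_atoms}: inconsistent ensemble"
            )
        frames.append(arr.coord)
    keep = ~np.isin(first.res_name, ["HOH", "WAT", "NA", "CL", "K", "MG"])
    first = first[keep]
    coords = np.stack(frames)[:, keep]
    unknown = set(first.res_name) - STANDARD_RESIDUES
    if unknown:
        warnings.warn(
            f"non-standard residue names retained: {sorted(unknown)}"
        )
    atoms = pd.DataFrame(
        {
            "atom_name": first.atom_name,
            "element": first.element,
            "residue_index": first.res_id.astype(int),
            "residue_name": first.res_name,
            "chain_id": first.chain_id,
        }
    )
    return ConformationalEnsemble(atoms, coords)


def to_atom_array_stack(ens: ConformationalEnsemble) -> struc.AtomArrayStack:
    stack = struc.AtomArrayStack(ens.n_frames, ens.n_atoms)
    stack.coord = ens.coords.copy()
    stack.atom_name = ens.atoms["atom_name"].to_numpy(dtype="U6")
    stack.element = ens.atoms["element"].to_numpy(dtype="U2")
    stack.res_id = ens.atoms["residue_index"].to_numpy(dtype=int)
    stack.res_name = ens.atoms["residue_name"].to_numpy(dtype="U5")
    stack.chain_id = ens.atoms["chain_id"].to_numpy(dtype="U4")
    return stack


def write_ensemble(ens: ConformationalEnsemble, path) -> None:
    """Write the ensemble as a multi-model PDB (MODEL/ENDMDL records)."""
    pdb = PDBFile()
    pdb.set_structure(to_atom_array_stack(ens))
    pdb.write(str(path))


def _dihedral_values(coords: np.ndarray, idx: tuple[int, int, int, int]) -> np.ndarray:
    # float64 torsion: signed angle between the two bond planes about b2
    p0, p1, p2, p3 = (coords[:, i].astype(float) for i in idx)
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = p3 - p2
    v = b0 - (b0 * b1).sum(axis=-1, keepdims=True) * b1
    w = b2 - (b2 * b1).sum(axis=-1, keepdims=True) * b1
    x = (v * w).sum(axis=-1)
    y = (np.cross(b1, v) * w).sum(axis=-1)
    return _wrap_degrees(np.degrees(np.arctan2(y, x)))


def extract_dihedrals(ens: ConformationalEnsemble) -> list[DihedralSeries]:
    """Extract phi, psi and chi1..chi5 series for every residue.

    Terminal residues lack phi (first) or psi (last); Gly and Ala carry no
    chi angle.  A dihedral whose atoms are missing is omitted silently apart
    from a warning, so partially resolved residues degrade gracefully.
    """
    atoms = ens.atoms
    # residue -> {atom_name: atom index}; keyed by (chain, res_id)
    index: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    for i, (c, r, name) in enumerate(
        zip(atoms["chain_id"], atoms["residue_index"], atoms["atom_name"])
    ):
        key = (c, int(r))
        if key not in index:
            index[key] = {}
            order.append(key)
        index[key].setdefault(name, i)
    resname = {
        (c, int(r)): n
        for c, r, n in zip(
            atoms["chain_id"], atoms["residue_index"], atoms["residue_name"]
        )
    }

    out: list[DihedralSeries] = []
    missing: list[str] = []
    for pos, key in enumerate(order):
        chain, rid = key
        res_atoms = index[key]
        prev_key = order[pos - 1] if pos > 0 else None
        next_key = order[pos + 1] if pos + 1 < len(order) else None
        if prev_key is not None and prev_key[0] != chain:
            prev_key = None
        if next_key is not None and next_key[0] != chain:
            next_key = None

        def emit(name: str, quad: list[int | None]) -> None:
            if any(q is None for q in quad):
                missing.append(f"{chain}{rid}:{name}")
                return
            out.append(
                DihedralSeries(
                    rid, chain, name, _dihedral_values(ens.coords, tuple(quad))
                )
            )

        if prev_key is not None:
            emit(
                "phi",
                [
                    index[prev_key].get("C"),
                    res_atoms.get("N"),
                    res_atoms.get("CA"),
                    res_atoms.get("C"),
                ],
            )
        if next_key is not None:
            emit(
                "psi",
                [
                    res_atoms.get("N"),
                    res_atoms.get("CA"),
                    res_atoms.get("C"),
                    index[next_key].get("N"),
                ],
            )
        for n_chi, quad_names in enumerate(CHI_ATOMS.get(resname[key], []), 1):
            emit(f"chi{n_chi}", [res_atoms.get(a) for a in quad_names])
    if missing:
        warnings.warn(f"{len(missing)} dihedrals omitted for missing atoms")
    return out


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile onto ref."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return rot, rc - mc @ rot


def superpose(ens: ConformationalEnsemble, mask: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Least-squares superpose all frames on ``mask`` atoms; returns coords.

    Frames are first fitted on frame 0, then refitted on the resulting mean
    structure (``n_iter`` rounds), the standard iterative-mean alignment.
    """
    coords = ens.coords.copy()
    ref = coords[0][mask]
    for _ in range(n_iter):
        for f in range(coords.shape[0]):
            rot, t = _kabsch(coords[f][mask], ref)
            coords[f] = coords[f] @ rot + t
        ref = coords[:, mask].mean(axis=0)
    return coords


def _selection_mask(ens: ConformationalEnsemble, selection: str) -> np.ndarray:
    if selection == "ca":
        return (ens.atoms["atom_name"] == "CA").to_numpy()
    if selection == "heavy":
        return (ens.atoms["element"] != "H").to_numpy()
    raise ValueError(f"unknown selection {selection!r} (use 'ca' or 'heavy')")


def compute_rmsf(
    ens: ConformationalEnsemble,
    selection: str = "heavy",
    align: bool = True,
    align_selection: str = "ca",
) -> pd.DataFrame:
    """Per-residue RMSF in Angstrom.

    RMSF of an atom is the root-mean-square displacement from its ensemble
    mean position; per residue the selected atoms' RMSF values are averaged.
    With ``align=True`` (default) frames are least-squares superposed on the
    ``align_selection`` atoms first, so only internal fluctuations remain.

    Returns a DataFrame with columns ``residue_index``, ``chain``, ``rmsf``.
    """
    sel = _selection_mask(ens, selection)
    if not sel.any():
        raise ValueError("empty atom selection for RMSF")
    if ens.n_frames == 1:
        warnings.warn("single-frame ensemble: RMSF is zero everywhere")
    if align and ens.n_frames > 1:
        amask = _selection_mask(ens, align_selection)
        coords = superpose(ens, amask if amask.any() else sel)
    else:
        coords = ens.coords
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    rows = []
    for chain, rid in ens.residue_keys():
        m = ens.atom_mask(chain, rid) & sel
        if m.any():
            rows.append((rid, chain, float(per_atom[m].mean())))
    return pd.DataFrame(rows, columns=["residue_index", "chain", "rmsf"])


def subsample_frames(
    ens: ConformationalEnsemble,
    n: int = 60,
    strategy: str = "even",
    seed: int | None = None,
) -> ConformationalEnsemble:
    """Pick ``n`` frames, evenly spaced (first and last included) or random."""
    if not 1 <= n <= ens.n_frames:
        raise ValueError(f"cannot take {n} frames from {ens.n_frames}")
    if strategy == "even":
        idx = np.unique(np.round(np.linspace(0, ens.n_frames - 1, n)).astype(int))
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(ens.n_frames, size=n, replace=False))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return ConformationalEnsemble(ens.atoms, ens.coords[idx].copy())
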