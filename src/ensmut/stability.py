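"""Per-mutation stability-change (ddG) distributions over an ensemble.

The scientific object here is the *distribution* of the stability change
ddG(X->Y) across conformational snapshots: its mean quantifies the impact
on the fold, its standard deviation serves as a local-dynamics descriptor,
and multimodality signals distinct conformational states of the local
environment.  The scorer itself is pluggable: the built-in empirical
surrogate combines a residue-level contact potential, a burial-weighted
hydrophobicity transfer term, a volume-clash penalty, and a Pro/Gly
backbone-strain term; per-frame tables produced by external force-field
tools can be imported through the same summary path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from scipy import stats

from .aminoacids import AA3_TO_1, FORMAL_CHARGE, HYDROPATHY, VOLUME
from .ensemble_io import ConformationalEnsemble, subsample_frames

__all__ = [
    "StabilityScorer",
    "EnsembleDdgResult",
    "ddg_ensemble",
    "builtin_empirical_scorer",
    "import_external_ddg",
    "detect_modes",
]


class StabilityScorer(Protocol):
    """Contract: kcal/mol stability change of one substitution in one frame.

    Implementations must return exactly 0.0 for identity substitutions."""

    def __call__(
        self,
        frame: ConformationalEnsemble,
        position: int,
        wt_aa: str,
        mut_aa: str,
    ) -> float: ...


@dataclass
class EnsembleDdgResult:
    """ddG distribution of one mutation over the subsampled frames."""

    mutation: str
    values: np.ndarray = field(repr=False)
    frames_used: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frames_used = np.asarray(self.frames_used, dtype=int)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        """Population SD (divide by n)."""
        return float(self.values.std(ddof=0))

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def n_modes(self, bandwidth=None) -> int:
        return detect_modes(self, bandwidth)


def _parse_mutation_key(mutation) -> tuple[str, int, str]:
    if hasattr(mutation, "wt_aa"):
        return mutation.wt_aa, mutation.position, mutation.mut_aa
    token = str(mutation)
    return token[0], int(token[1:-1]), token[-1]


def ddg_ensemble(
    ens: ConformationalEnsemble,
    mutation,
    scorer: StabilityScorer,
    n_frames: int = 60,
    strategy: str = "even",
    seed: int | None = None,
) -> EnsembleDdgResult:
    """Score one substitution on ``n_frames`` subsampled snapshots.

    ``mutation`` is a ``MutationRecord`` or a token like ``"A95P"``.  The
    wild-type residue at the position must match the structure, otherwise
    the catalog and the ensemble are out of sync and a ``ValueError`` is
    raised.  Default subsampling is 60 evenly spaced frames.
    """
    wt, pos, mut = _parse_mutation_key(mutation)
    res_rows = ens.atoms[ens.atoms["residue_index"] == pos]
    if res_rows.empty:
        raise ValueError(f"position {pos} absent from structure")
    found = AA3_TO_1.get(res_rows["residue_name"].iloc[0], "X")
    if found != wt:
        raise ValueError(
            f"wild-type mismatch at {pos}: catalog says {wt}, "
            f"structure has {found}"
        )
    n_frames = min(n_frames, ens.n_frames)
    sub = subsample_frames(ens, n_frames, strategy=strategy, seed=seed)
    values = np.array(
        [scorer(sub.frame(f), pos, wt, mut) for f in range(sub.n_frames)]
    )
    return EnsembleDdgResult(f"{wt}{pos}{mut}", values, np.arange(sub.n_frames))


# -- built-in empirical scorer ---------------------------------------------

DEFAULT_SCORER_PARAMS = {
    "contact_cutoff": 8.0,       # A, between side-chain centroids (CB, CA for Gly)
    "k_contact": 0.03,           # contact-potential scale, kcal/mol
    "k_charge": 0.25,            # charge-pair contact term, kcal/mol
    "k_hydro": 0.35,             # hydrophobic-transfer scale, kcal/mol
    "hydro_baseline": 0.25,      # exposure-independent share of the transfer
    "burial_saturation": 12,     # neighbor count treated as fully buried
    "k_volume": 0.04,            # clash penalty per 10 A^3 overfill when buried
    "proline_strain": 2.5,       # kcal/mol, mutating into Pro in ordered phi/psi
    "glycine_loss": 1.5,         # kcal/mol, removing Gly at positive-phi backbone
}


def _contact_energy(aa_i: str, aa_j: str, p: dict) -> float:
    """Residue-level contact potential: hydrophobic attraction + charge term."""
    e = -p["k_contact"] * HYDROPATHY[aa_i] * HYDROPATHY[aa_j]
    e += p["k_charge"] * FORMAL_CHARGE[aa_i] * FORMAL_CHARGE[aa_j]
    return e


def builtin_empirical_scorer(
    params: dict | None = None,
) -> Callable[[ConformationalEnsemble, int, str, str], float]:
    """Simplified residue-level empirical stability scorer.

    ddG = (change in contact-potential energy with neighbors within the
    cutoff) + burial-weighted hydrophobicity transfer + volume-clash
    penalty + Pro/Gly backbone-strain term.  Deterministic per frame;
    identity substitutions score exactly 0.  All constants live in
    ``DEFAULT_SCORER_PARAMS``.
    """
    p = dict(DEFAULT_SCORER_PARAMS)
    if params:
        p.update(params)

    def scorer(
        frame: ConformationalEnsemble, position: int, wt_aa: str, mut_aa: str
    ) -> float:
        if wt_aa == mut_aa:
            return 0.0
        atoms = frame.atoms
        xyz = frame.coords[0]
        # side-chain reference point per residue: CB, else CA
        keys, centers, res_aa = [], [], []
        for chain, rid in frame.residue_keys():
            m = frame.atom_mask(chain, rid)
            names = atoms.loc[m, "atom_name"]
            sel = m & (atoms["atom_name"] == "CB").to_numpy()
            if not sel.any():
                sel = m & (atoms["atom_name"] == "CA").to_numpy()
            if not sel.any():
                continue
            keys.append((chain, rid))
            centers.append(xyz[sel][0])
            res_aa.append(AA3_TO_1.get(atoms.loc[m, "residue_name"].iloc[0], "A"))
        centers = np.asarray(centers)
        try:
            site = next(i for i, (_, r) in enumerate(keys) if r == position)
        except StopIteration:
            raise ValueError(f"position {position} absent from frame")
        dist = np.linalg.norm(centers - centers[site], axis=1)
        neigh = np.where((dist <= p["contact_cutoff"]) & (dist > 1e-9))[0]
        if len(neigh) == 0:
            warnings.warn(f"residue {position} has no neighbors; contact term 0")
        contact = sum(
            _contact_energy(mut_aa, res_aa[j], p)
            - _contact_energy(wt_aa, res_aa[j], p)
            for j in neigh
        )
        burial = min(len(neigh) / p["burial_saturation"], 1.0)
        hydro = (
            p["k_hydro"]
            * (p["hydro_baseline"] + burial)
            * (HYDROPATHY[wt_aa] - HYDROPATHY[mut_aa])
        )
        clash = p["k_volume"] * burial * max(
            0.0, VOLUME[mut_aa] - VOLUME[wt_aa]
        ) / 10.0
        strain = _backbone_strain(frame, position, wt_aa, mut_aa, p)
        return float(contact + hydro + clash + strain)

    return scorer


def _backbone_phi(frame: ConformationalEnsemble, position: int) -> float | None:
    from .ensemble_io import _dihedral_values

    atoms = frame.atoms
    idx = {
        (r, n): i
        for i, (r, n) in enumerate(
            zip(atoms["residue_index"], atoms["atom_name"])
        )
    }
    quad = (
        idx.get((position - 1, "C")),
        idx.get((position, "N")),
        idx.get((position, "CA")),
        idx.get((position, "C")),
    )
    if any(q is None for q in quad):
        return None
    return float(_dihedral_values(frame.coords, quad)[0])


def _backbone_strain(
    frame: ConformationalEnsemble,
    position: int,
    wt_aa: str,
    mut_aa: str,
    p: dict,
) -> float:
    strain = 0.0
    phi = _backbone_phi(frame, position)
    if mut_aa == "P":
        # proline tolerates only phi near -60; elsewhere the ring strains
        # the local backbone (helix/sheet phi included)
        if phi is None or not -90.0 <= phi <= -40.0:
            strain += p["proline_strain"]
        else:
            strain += 0.5 * p["proline_strain"]
    if wt_aa == "G":
        # positive-phi backbone conformations are glycine-only
        if phi is not None and phi > 0.0:
            strain += p["glycine_loss"]
        else:
            strain += 0.5 * p["glycine_loss"]
    if wt_aa == "P" and mut_aa != "P":
        strain += 0.3 * p["proline_strain"]
    return strain


def import_external_ddg(path) -> list[EnsembleDdgResult]:
    """Adapter for per-frame ddG tables from external force-field tools.

    Expects a long-format CSV with columns ``mutation, frame, value_kcal_mol``
    (``value`` accepted as an alias).  Missing frames are tolerated; the
    realized frame count is recorded in the result.
    """
    df = pd.read_csv(path, comment="#")
    value_col = "value_kcal_mol" if "value_kcal_mol" in df.columns else "value"
    if not {"mutation", "frame", value_col} <= set(df.columns):
        raise ValueError(
            "expected columns mutation, frame, value_kcal_mol (or value)"
        )
    results = []
    for mutation, grp in df.groupby("mutation", sort=False):
        grp = grp.sort_values("frame")
        results.append(
            EnsembleDdgResult(
                str(mutation),
                grp[value_col].to_numpy(dtype=float),
                grp["frame"].to_numpy(dtype=int),
            )
        )
    return results


def detect_modes(result, bandwidth=None) -> int:
    """Count the modes (local maxima of a Gaussian-kernel density estimate).

    ``bandwidth`` follows ``scipy.stats.gaussian_kde`` conventions; the
    default is Silverman's rule.  Needs at least 10 values; an all-equal
    sample counts as a single mode.
    """
    values = result.values if isinstance(result, EnsembleDdgResult) else (
        np.asarray(result, dtype=float)
    )
    if len(values) < 10:
        raise ValueError("mode detection needs at least 10 values")
    if np.ptp(values) == 0.0:
        return 1
    kde = stats.gaussian_kde(
        values, bw_method="silverman" if bandwidth is None else bandwidth
    )
    span = np.ptp(values)
    grid = np.linspace(values.min() - 0.1 * span, values.max() + 0.1 * span, 512)
    dens = kde(grid)
    # discount sampling-noise bumps: a mode must rise to at least 2% of the
    # global density peak
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(dens, prominence=0.02 * dens.max())
    return max(len(peaks), 1)
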