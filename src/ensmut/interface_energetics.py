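"""Chain-chain binding energies over an ensemble, decomposed per residue.

A deliberately simple implicit-solvent interaction model: for every
interchain heavy-atom pair within a cutoff, a Lennard-Jones term plus a
Coulomb term with distance-dependent dielectric ``eps(r) = 4r``, and a
desolvation proxy proportional to the number of close interface contacts.
The model's purpose is the machinery around it — per-frame distributions
and an exact per-residue decomposition whose contributions always sum to
the chain-pair total — not force-field accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .aminoacids import CHARGED_ATOMS
from .ensemble_io import ConformationalEnsemble

__all__ = [
    "InteractionEnergyResult",
    "INTERFACE_PARAMS",
    "chain_pair_energy",
    "rank_interface_residues",
]

INTERFACE_PARAMS = {
    "pair_cutoff": 12.0,       # A, interchain heavy-atom pair inclusion
    "coulomb_k": 332.06,       # kcal*A/(mol*e^2)
    "dielectric_slope": 4.0,   # eps(r) = slope * r
    "lj_radius": {"C": 1.95, "N": 1.75, "O": 1.65, "S": 2.0},  # A
    "lj_radius_default": 1.8,
    "lj_eps": 0.12,            # kcal/mol well depth (geometric-mean free)
    "desolv_cutoff": 4.5,      # A, close-contact count for the proxy
    "desolv_k": -0.05,         # kcal/mol per close contact (burial favorable)
}


@dataclass
class InteractionEnergyResult:
    """Binding energy of one chain pair with per-residue decomposition.

    ``per_frame`` holds the total per frame; ``residues`` lists
    ``(chain_id, residue_index)`` and ``contributions`` is
    ``(n_frames, n_residues)`` with rows summing to the frame total.
    """

    chain_pair: tuple[str, str]
    per_frame: np.ndarray = field(repr=False)
    residues: list[tuple[str, int]] = field(repr=False, default_factory=list)
    contributions: np.ndarray = field(repr=False, default=None)

    @property
    def mean(self) -> float:
        return float(self.per_frame.mean())

    @property
    def sd(self) -> float:
        return float(self.per_frame.std(ddof=0))

    def per_residue(self) -> pd.DataFrame:
        """Mean contribution per residue over frames (kcal/mol)."""
        return pd.DataFrame(
            {
                "chain": [c for c, _ in self.residues],
                "residue_index": [r for _, r in self.residues],
                "energy": self.contributions.mean(axis=0),
            }
        )


def chain_pair_energy(
    ens: ConformationalEnsemble,
    chain_x: str,
    chain_y: str,
    params: dict | None = None,
    charges: dict | None = None,
) -> InteractionEnergyResult:
    """Interaction energy between two disjoint chains, per frame.

    ``charges`` optionally overrides the per-atom partial charges as a
    ``{(residue_name, atom_name): q}`` mapping (defaults to the formal
    side-chain charge table).  Pair terms are split half/half between the
    two residues involved so the decomposition is exactly conservative.
    """
    p = dict(INTERFACE_PARAMS)
    if params:
        p.update(params)
    atoms = ens.atoms
    heavy = (atoms["element"] != "H").to_numpy()
    mask_x = (atoms["chain_id"] == chain_x).to_numpy() & heavy
    mask_y = (atoms["chain_id"] == chain_y).to_numpy() & heavy
    if not mask_x.any() or not mask_y.any():
        raise ValueError(f"chain {chain_x} or {chain_y} absent or empty")
    if chain_x == chain_y:
        raise ValueError("chains must be distinct")

    def atom_charge(i: int) -> float:
        rn = atoms["residue_name"].iloc[i]
        an = atoms["atom_name"].iloc[i]
        if charges is not None:
            return float(charges.get((rn, an), 0.0))
        return float(CHARGED_ATOMS.get(rn, {}).get(an, 0.0))

    idx_x = np.where(mask_x)[0]
    idx_y = np.where(mask_y)[0]
    q_x = np.array([atom_charge(i) for i in idx_x])
    q_y = np.array([atom_charge(i) for i in idx_y])
    r_tab = p["lj_radius"]
    rad_x = np.array(
        [r_tab.get(atoms["element"].iloc[i], p["lj_radius_default"]) for i in idx_x]
    )
    rad_y = np.array(
        [r_tab.get(atoms["element"].iloc[i], p["lj_radius_default"]) for i in idx_y]
    )

    res_keys = ens.residue_keys()
    res_pos = {key: n for n, key in enumerate(res_keys)}
    atom_res = np.array(
        [
            res_pos[(c, int(r))]
            for c, r in zip(atoms["chain_id"], atoms["residue_index"])
        ]
    )
    n_res = len(res_keys)
    n_frames = ens.n_frames
    totals = np.zeros(n_frames)
    contrib = np.zeros((n_frames, n_res))

    for f in range(n_frames):
        xyz = ens.coords[f]
        tree_y = cKDTree(xyz[idx_y])
        pairs = tree_y.query_ball_point(xyz[idx_x], p["pair_cutoff"])
        for a, ys in enumerate(pairs):
            if not ys:
                continue
            ia = idx_x[a]
            d = np.linalg.norm(xyz[idx_y[ys]] - xyz[ia], axis=1)
            d = np.maximum(d, 1e-6)
            r0 = rad_x[a] + rad_y[ys]
            s = (r0 / d) ** 6
            e_lj = p["lj_eps"] * (s**2 - 2.0 * s)
            e_c = (
                p["coulomb_k"] * q_x[a] * q_y[ys]
                / (p["dielectric_slope"] * d * d)
            )
            e_pair = e_lj + e_c
            e_desolv = np.where(d <= p["desolv_cutoff"], p["desolv_k"], 0.0)
            e_all = e_pair + e_desolv
            totals[f] += float(e_all.sum())
            contrib[f, atom_res[ia]] += 0.5 * float(e_all.sum())
            np.add.at(contrib[f], atom_res[idx_y[ys]], 0.5 * e_all)

    # keep only residues of the two chains (others are zero by construction)
    keep = [
        n for n, (c, _) in enumerate(res_keys) if c in (chain_x, chain_y)
    ]
    return InteractionEnergyResult(
        (chain_x, chain_y),
        totals,
        [res_keys[n] for n in keep],
        contrib[:, keep],
    )


def rank_interface_residues(
    result: InteractionEnergyResult, top_n: int | None = None
) -> pd.DataFrame:
    """Residues ordered by most favorable (lowest) mean contribution.

    Ties are broken by residue index; ``top_n=None`` returns all.
    """
    df = result.per_residue()
    df = df.sort_values(
        ["energy", "residue_index"], kind="stable"
    ).reset_index(drop=True)
    return df if top_n is None else df.head(top_n)
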