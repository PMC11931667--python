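"""Dihedral-dihedral mutual information and active-site coupling totals.

Mutual information between two circular time series is estimated from
equal-width histograms on [-180, 180) as ``MI = H(x) + H(y) - H(x, y)``
(plug-in entropies, nats).  Each value is also normalized by the smaller
marginal entropy so that 0 means no coupling and 1 maximum coupling.
Residue-level coupling is the SUM of normalized MI over all dihedral pairs
of the two residues ("total pairwise MI"); totals may therefore exceed 1
and are only rescaled during report integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble_io import DihedralSeries

__all__ = [
    "DEFAULT_ACTIVE_SITE",
    "MiMatrix",
    "pair_mi",
    "residue_pair_mi",
    "compute_mi_matrix",
    "active_site_total_mi",
    "matrix_stats",
]

# Ten residues at or near the catalytic site of hLAMAN (precursor numbering):
# H72, D74, W77, D196, R220, D319, H446, D447, Y660, R823.
DEFAULT_ACTIVE_SITE: tuple[int, ...] = (72, 74, 77, 196, 220, 319, 446, 447, 660, 823)

DEFAULT_N_BINS = 50


def _entropy_nats(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    c = counts[counts > 0].astype(float)
    return float(np.log(n) - (c * np.log(c)).sum() / n)


def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    # equal-width circular bins over [-180, 180); +180 wraps to -180
    wrapped = ((np.asarray(values, dtype=float) + 180.0) % 360.0) - 180.0
    idx = np.floor((wrapped + 180.0) / 360.0 * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, DihedralSeries) else np.asarray(x, float)


def pair_mi(
    x,
    y,
    n_bins: int = DEFAULT_N_BINS,
    jackknife: bool = False,
) -> tuple[float, float]:
    """MI of two dihedral series: ``(mi_nats, mi_normalized)``.

    ``mi_normalized = MI / min(H(x), H(y))`` in [0, 1]; defined as 0 when
    either marginal entropy vanishes.  ``jackknife=True`` applies the
    leave-one-out jackknife bias correction to the raw MI before
    normalization (the plug-in estimator is biased upward at finite n).
    """
    xv, yv = _values(x), _values(y)
    if xv.shape != yv.shape:
        raise ValueError(
            f"frame-count mismatch: {xv.shape[0]} vs {yv.shape[0]}"
        )
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    xi = _bin_indices(xv, n_bins)
    yi = _bin_indices(yv, n_bins)
    joint = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(joint, (xi, yi), 1)
    cx = joint.sum(axis=1)
    cy = joint.sum(axis=0)
    hx, hy, hxy = _entropy_nats(cx), _entropy_nats(cy), _entropy_nats(joint.ravel())
    mi = max(hx + hy - hxy, 0.0)
    if jackknife:
        mi = _jackknife_mi(joint, cx, cy, mi)
    hmin = min(hx, hy)
    mi_norm = 0.0 if hmin <= 0.0 else min(mi / hmin, 1.0)
    return mi, mi_norm


def _jackknife_mi(joint: np.ndarray, cx: np.ndarray, cy: np.ndarray,
                  mi: float) -> float:
    """Leave-one-out jackknife: n*MI - (n-1)*mean(MI_loo)."""
    n = int(joint.sum())
    if n < 2:
        return mi

    def _plogp(c: np.ndarray | float) -> np.ndarray | float:
        return np.where(np.asarray(c) > 0, c * np.log(np.maximum(c, 1)), 0.0)

    sx = float(_plogp(cx.astype(float)).sum())
    sy = float(_plogp(cy.astype(float)).sum())
    sxy = float(_plogp(joint.astype(float).ravel()).sum())
    xs, ys = np.nonzero(joint)
    weights = joint[xs, ys].astype(float)
    mean_loo = 0.0
    log_nm1 = np.log(n - 1)
    for a, b, w in zip(xs, ys, weights):
        sx_ = sx - float(_plogp(float(cx[a]))) + float(_plogp(float(cx[a] - 1)))
        sy_ = sy - float(_plogp(float(cy[b]))) + float(_plogp(float(cy[b] - 1)))
        sxy_ = sxy - float(_plogp(float(joint[a, b]))) + float(
            _plogp(float(joint[a, b] - 1))
        )
        hx_ = log_nm1 - sx_ / (n - 1)
        hy_ = log_nm1 - sy_ / (n - 1)
        hxy_ = log_nm1 - sxy_ / (n - 1)
        mean_loo += w * max(hx_ + hy_ - hxy_, 0.0)
    mean_loo /= n
    return max(n * mi - (n - 1) * mean_loo, 0.0)


def _series_by_residue(
    series: list[DihedralSeries],
) -> dict[int, list[DihedralSeries]]:
    by_res: dict[int, list[DihedralSeries]] = {}
    for s in series:
        by_res.setdefault(int(s.residue_index), []).append(s)
    return by_res


def residue_pair_mi(
    residue_i: int,
    residue_j: int,
    series: list[DihedralSeries],
    n_bins: int = DEFAULT_N_BINS,
) -> float:
    """Total coupling of two residues: sum of normalized MI over all
    (dihedral of i) x (dihedral of j) pairs.  Residues without any series
    contribute 0 (flagged with a warning)."""
    by_res = _series_by_residue(series)
    si = by_res.get(int(residue_i), [])
    sj = by_res.get(int(residue_j), [])
    if not si or not sj:
        warnings.warn(
            f"residue {residue_i if not si else residue_j} has no dihedral "
            "series; coupling set to 0"
        )
        return 0.0
    return float(
        sum(pair_mi(a, b, n_bins)[1] for a in si for b in sj)
    )


@dataclass
class MiMatrix:
    """Symmetric residue-pair total-MI matrix.

    ``values[i, j]`` is the summed normalized MI between residues
    ``residues[i]`` and ``residues[j]``; the diagonal (auto-coupling) is set
    to 0 and excluded from all summary statistics.
    """

    residues: list[int]
    values: np.ndarray = field(repr=False)
    n_bins: int = DEFAULT_N_BINS
    normalization: str = "min-marginal-entropy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residues)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match residue list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("MI matrix must be symmetric")

    def index_of(self, residue: int) -> int:
        try:
            return self.residues.index(int(residue))
        except ValueError as err:
            raise KeyError(f"residue {residue} not in MI matrix") from err


def compute_mi_matrix(
    series: list[DihedralSeries],
    n_bins: int = DEFAULT_N_BINS,
) -> MiMatrix:
    """Residue x residue total-MI matrix over every residue with series."""
    by_res = _series_by_residue(series)
    residues = sorted(by_res)
    n = len(residues)
    values = np.zeros((n, n))
    # cache binned pair MI per series pair
    for a in range(n):
        for b in range(a + 1, n):
            total = sum(
                pair_mi(x, y, n_bins)[1]
                for x in by_res[residues[a]]
                for y in by_res[residues[b]]
            )
            values[a, b] = values[b, a] = total
    return MiMatrix(residues, values, n_bins)


def active_site_total_mi(
    mi: MiMatrix,
    site: tuple[int, ...] = DEFAULT_ACTIVE_SITE,
) -> pd.DataFrame:
    """Per-residue total MI with the active-site set.

    ``total_i = sum over site residues s != i of the residue-pair MI``.
    Site members are flagged ``in_site`` (reported as 0 by convention in
    the descriptor table and excluded from group statistics).
    """
    if not site:
        raise ValueError("active-site set must be non-empty")
    site_idx = [mi.index_of(s) for s in site]
    site_set = set(int(s) for s in site)
    rows = []
    for i, res in enumerate(mi.residues):
        total = float(
            sum(mi.values[i, j] for j in site_idx if j != i)
        )
        rows.append((res, total, res in site_set))
    return pd.DataFrame(rows, columns=["residue_index", "total_mi", "in_site"])


def matrix_stats(
    mi: MiMatrix,
    site: tuple[int, ...] = DEFAULT_ACTIVE_SITE,
) -> tuple[float, float]:
    """(mean off-diagonal pairwise MI, mean per-residue total with the site)."""
    if not site:
        raise ValueError("active-site set must be non-empty")
    n = len(mi.residues)
    if n < 2:
        raise ValueError("need at least two residues")
    off = ~np.eye(n, dtype=bool)
    mean_pairwise = float(mi.values[off].mean())
    totals = active_site_total_mi(mi, site)["total_mi"]
    return mean_pairwise, float(totals.mean())
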