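"""Descriptor normalization, radar/quadrant profiles and group statistics.

The four per-mutation descriptors — total dihedral MI with the active
site, ensemble mean stability change, its SD, and the bond-to-bond
propensity quantile score — are normalized to [0, 1] (stability values
against a fixed cap in kcal/mol, the others by their series maximum),
assembled into per-mutation profiles, summarized by group medians,
compared by rank-sum tests, and used to classify unassigned variants by
nearest group median.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .mutation_catalog import DescriptorRow, MutationRecord

__all__ = [
    "DescriptorProfile",
    "GroupSummary",
    "DEFAULT_DDG_CAP",
    "DESCRIPTORS",
    "normalize_series",
    "build_profiles",
    "profiles_from_descriptor_rows",
    "group_medians",
    "rank_sum_test",
    "classify_unknown",
    "quadrant_projection",
    "radar_export",
]

# Stability changes above this value (kcal/mol) are truncated to the cap,
# which then acts as the normalizing value.
DEFAULT_DDG_CAP = 20.35

DESCRIPTORS = ("total_dihedral_mi", "ddg_norm", "ddg_sd_norm", "b2b_propensity")


@dataclass
class DescriptorProfile:
    """Normalized 4-descriptor vector of one mutation."""

    mutation: str
    chain: str
    group: str
    values: dict[str, float | None]
    raw: dict[str, float | None] = field(default_factory=dict)
    capped: set[str] = field(default_factory=set)
    active_site: bool = False
    missing: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if v is not None and not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(
                    f"{self.mutation}: normalized {name}={v} outside [0, 1]"
                )

    def vector(self) -> np.ndarray:
        return np.array(
            [np.nan if self.values.get(d) is None else self.values[d]
             for d in DESCRIPTORS]
        )


@dataclass
class GroupSummary:
    """Component-wise descriptor medians of one mutation group."""

    group: str
    n: int
    medians: dict[str, float]


def normalize_series(
    values, cap: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a descriptor series to [0, 1].

    Without a cap, divide by the series maximum (the maximum maps to
    exactly 1).  With a cap, truncate at the cap and divide by it, flagging
    truncated entries; order among uncapped entries is preserved.
    Returns ``(normalized, capped_flags)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("need at least one finite value")
    if cap is None:
        vmax = v.max()
        if vmax <= 0:
            if np.allclose(v, 0):
                warnings.warn("all-zero series normalizes to zeros")
                return np.zeros_like(v), np.zeros(v.shape, dtype=bool)
            raise ValueError("series maximum must be positive without a cap")
        return v / vmax, np.zeros(v.shape, dtype=bool)
    flags = v > cap
    return np.minimum(v, cap) / cap, flags


def build_profiles(
    ddg_results,
    mi_totals,
    b2b_scores,
    catalog: list[MutationRecord],
    cap: float = DEFAULT_DDG_CAP,
    active_site_residues=(),
) -> list[DescriptorProfile]:
    """Assemble normalized profiles from the four descriptor computations.

    ``ddg_results`` is a list of ``EnsembleDdgResult``; ``mi_totals`` and
    ``b2b_scores`` map residue index to the raw total MI / mean quantile
    score (DataFrames with ``residue_index`` plus ``total_mi`` / ``score``
    columns are accepted).  Stability mean and SD are normalized against
    ``cap``; MI and propensity by their series maxima.  Catalog positions
    in ``active_site_residues`` get MI and propensity 0 with a flag;
    positions absent from a descriptor set are flagged missing.
    """
    def as_map(obj, col):
        if hasattr(obj, "columns"):
            return dict(zip(obj["residue_index"].astype(int), obj[col]))
        return {int(k): float(v) for k, v in dict(obj).items()}

    mi_map = as_map(mi_totals, "total_mi")
    b2b_map = as_map(b2b_scores, "score")
    ddg_map = {r.mutation: (r.mean, r.sd) for r in ddg_results}
    site = set(int(r) for r in active_site_residues)

    mi_max = max((v for k, v in mi_map.items() if k not in site), default=0.0)
    b2b_max = max((v for k, v in b2b_map.items() if k not in site), default=0.0)

    profiles = []
    for rec in catalog:
        values: dict[str, float | None] = {}
        raw: dict[str, float | None] = {}
        capped: set[str] = set()
        missing: set[str] = set()
        in_site = rec.position in site
        for name, vmap, vmax in [
            ("total_dihedral_mi", mi_map, mi_max),
            ("b2b_propensity", b2b_map, b2b_max),
        ]:
            if in_site:
                values[name], raw[name] = 0.0, vmap.get(rec.position)
            elif rec.position in vmap and vmax > 0:
                raw[name] = vmap[rec.position]
                values[name] = min(raw[name] / vmax, 1.0)
            else:
                values[name], raw[name] = None, None
                missing.add(name)
        if rec.mutation in ddg_map:
            mean, sd = ddg_map[rec.mutation]
            raw["ddg_norm"], raw["ddg_sd_norm"] = mean, sd
            for name, v in [("ddg_norm", mean), ("ddg_sd_norm", sd)]:
                clipped = max(v, 0.0)
                values[name] = min(clipped, cap) / cap
                if clipped > cap:
                    capped.add(name)
        else:
            values["ddg_norm"] = values["ddg_sd_norm"] = None
            raw["ddg_norm"] = raw["ddg_sd_norm"] = None
            missing.update({"ddg_norm", "ddg_sd_norm"})
        profiles.append(
            DescriptorProfile(
                rec.mutation, rec.chain, rec.group, values, raw,
                capped, in_site, missing,
            )
        )
    return profiles


def profiles_from_descriptor_rows(
    rows: list[DescriptorRow],
) -> list[DescriptorProfile]:
    """Wrap an already-normalized descriptor table into profiles."""
    out = []
    for r in rows:
        capped = set()
        if r.ddg_capped:
            capped.add("ddg_norm")
        if r.ddg_sd_capped:
            capped.add("ddg_sd_norm")
        out.append(
            DescriptorProfile(
                r.mutation, r.chain, r.group,
                {
                    "total_dihedral_mi": r.total_dihedral_mi,
                    "ddg_norm": r.ddg_norm,
                    "ddg_sd_norm": r.ddg_sd_norm,
                    "b2b_propensity": r.b2b_propensity,
                },
                capped=capped,
                active_site=r.active_site,
            )
        )
    return out


def group_medians(
    profiles: list[DescriptorProfile],
    groups: tuple[str, ...] | None = None,
) -> list[GroupSummary]:
    """Component-wise medians per group.

    Active-site-flagged profiles are excluded from the MI and propensity
    medians (their zeros are a reporting convention, not a measurement)
    but contribute to the stability medians.  Empty groups are omitted
    with a warning.
    """
    if groups is None:
        groups = tuple(dict.fromkeys(p.group for p in profiles))
    out = []
    for g in groups:
        members = [p for p in profiles if p.group == g]
        if not members:
            warnings.warn(f"group {g!r} has no members; omitted")
            continue
        medians = {}
        for d in DESCRIPTORS:
            vals = [
                p.values[d] for p in members
                if p.values.get(d) is not None
                and not (p.active_site and d in ("total_dihedral_mi", "b2b_propensity"))
            ]
            if vals:
                medians[d] = float(np.median(vals))
        out.append(GroupSummary(g, len(members), medians))
    return out


def rank_sum_test(
    group_a, group_b
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test: ``(U of group_a, p)``.

    Exact p by enumeration of all rank assignments when
    ``n_a + n_b <= 12`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Identical values
    throughout give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2.0), 1.0
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    no_ties = len(np.unique(pooled)) == pooled.size
    if a.size + b.size <= 12 and no_ties:
        n = pooled.size
        order = stats.rankdata(pooled)  # 1..n, no ties
        u_values = []
        for combo in combinations(range(n), a.size):
            r = order[list(combo)].sum()
            u_values.append(r - a.size * (a.size + 1) / 2.0)
        u_values = np.asarray(u_values)
        total = comb(n, a.size)
        p_le = float((u_values <= u_a + 1e-9).sum()) / total
        p_ge = float((u_values >= u_a - 1e-9).sum()) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_a, p
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def classify_unknown(
    profile: DescriptorProfile,
    summaries: list[GroupSummary],
    metric: str = "euclidean",
) -> tuple[str | None, dict[str, float]]:
    """Nearest-group-median assignment of an unassigned variant.

    Returns ``(group, distances)``; missing descriptors are excluded from
    the distance (noted via the profile's ``missing`` set) and exact ties
    are reported as ``None`` rather than silently resolved.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two group summaries")
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is implemented")
    distances = {}
    for s in summaries:
        terms = [
            (profile.values[d] - s.medians[d]) ** 2
            for d in DESCRIPTORS
            if profile.values.get(d) is not None and d in s.medians
        ]
        if not terms:
            raise ValueError("no shared descriptors between profile and group")
        distances[s.group] = float(np.sqrt(sum(terms)))
    best = min(distances.values())
    winners = [g for g, d in distances.items() if abs(d - best) < 1e-12]
    return (winners[0] if len(winners) == 1 else None), distances


def quadrant_projection(
    profiles: list[DescriptorProfile], midpoint: float = 0.5
) -> dict[str, str]:
    """Quadrant label per mutation on the (MI, propensity) plane.

    Values at or above the midpoint of the normalized scale count as
    "high" (boundary assigned to high by the >= convention).
    """
    labels = {}
    for p in profiles:
        mi = p.values.get("total_dihedral_mi")
        b2b = p.values.get("b2b_propensity")
        if mi is None or b2b is None:
            labels[p.mutation] = "undefined"
            continue
        labels[p.mutation] = (
            f"{'high' if mi >= midpoint else 'low'}-MI/"
            f"{'high' if b2b >= midpoint else 'low'}-b2b"
        )
    return labels


def radar_export(
    profiles: list[DescriptorProfile],
    summaries: list[GroupSummary],
    path,
) -> dict:
    """Radar-chart data as JSON: one 4-vertex polygon per mutation plus the
    group-median polygons.  Values outside [0, 1] are refused."""
    payload = {
        "axes": list(DESCRIPTORS),
        "mutations": [],
        "group_medians": [],
    }
    for p in profiles:
        vec = [p.values.get(d) for d in DESCRIPTORS]
        for v in vec:
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{p.mutation}: value {v} outside [0, 1]")
        payload["mutations"].append(
            {
                "mutation": p.mutation,
                "group": p.group,
                "values": vec,
                "capped": sorted(p.capped),
                "active_site": p.active_site,
            }
        )
    for s in summaries:
        payload["group_medians"].append(
            {
                "group": s.group,
                "n": s.n,
                "values": [s.medians.get(d) for d in DESCRIPTORS],
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload
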