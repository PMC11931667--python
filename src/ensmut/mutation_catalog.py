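"""Mutation catalog and normalized-descriptor table handling.

The package ships three CSV tables for human lysosomal alpha-mannosidase
(hLAMAN): the 43 reported deleterious missense variants with their group
assignment (folding / activity / unclassified), the 9 benign variants, and
the normalized four-descriptor table (total dihedral MI, normalized
stability change and its SD, bond-to-bond propensity quantile score) for
every deleterious variant.  This module parses, validates, and summarizes
catalogs in that schema.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "MutationRecord",
    "DescriptorRow",
    "load_catalog",
    "count_by_group",
    "load_descriptor_table",
    "write_catalog",
    "packaged_path",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")
VALID_GROUPS = {"folding", "activity", "unclassified", "benign"}
_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

CATALOG_COLUMNS = [
    "mutation", "chain", "group", "relative_activity", "distance_to_zn",
    "secondary_structure", "contact_chains",
]


@dataclass(frozen=True)
class MutationRecord:
    """One reported missense variant with its structural annotations."""

    wt_aa: str
    position: int
    mut_aa: str
    chain: str
    group: str
    relative_activity: float | None  # % of wild type; None where not reported
    distance_to_zn: float | None     # A to the catalytic Zn(2+)
    secondary_structure: str
    contact_chains: tuple[str, ...]

    @property
    def mutation(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class DescriptorRow:
    """Normalized descriptor 4-vector of one variant, all values in [0, 1]."""

    mutation: str
    chain: str
    group: str
    total_dihedral_mi: float
    ddg_norm: float
    ddg_sd_norm: float
    b2b_propensity: float
    ddg_capped: bool = False
    ddg_sd_capped: bool = False
    active_site: bool = False

    def vector(self) -> tuple[float, float, float, float]:
        return (
            self.total_dihedral_mi, self.ddg_norm,
            self.ddg_sd_norm, self.b2b_propensity,
        )


def packaged_path(name: str) -> Path:
    """Path of a packaged data table.

    ``name`` is one of ``deleterious``, ``benign``, ``descriptors``.
    """
    fname = {
        "deleterious": "mutations_deleterious.csv",
        "benign": "mutations_benign.csv",
        "descriptors": "descriptors_normalized.csv",
    }[name]
    return Path(str(resources.files("ensmut").joinpath("data", fname)))


def _parse_mutation(token: str, row: int) -> tuple[str, int, str]:
    m = _MUTATION_RE.match(token.strip())
    if not m:
        raise ValueError(f"row {row}: malformed mutation token {token!r}")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    if wt not in VALID_AA or mut not in VALID_AA:
        raise ValueError(f"row {row}: invalid amino-acid code in {token!r}")
    if wt == mut:
        raise ValueError(f"row {row}: wild-type equals mutant in {token!r}")
    if pos < 1:
        raise ValueError(f"row {row}: position must be >= 1 in {token!r}")
    return wt, pos, mut


def load_catalog(path) -> list[MutationRecord]:
    """Parse a mutation catalog CSV into validated records.

    ``N.D.`` and non-numeric activity entries become missing values;
    duplicate (mutation, group) pairs and malformed rows raise ``ValueError``
    with the offending row number.
    """
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    records: list[MutationRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based + header
        wt, pos, mut = _parse_mutation(row["mutation"], rowno)
        group = row["group"].strip()
        if group not in VALID_GROUPS:
            raise ValueError(f"row {rowno}: unknown group {group!r}")
        key = (f"{wt}{pos}{mut}", group)
        if key in seen:
            raise ValueError(f"row {rowno}: duplicate entry {key}")
        seen.add(key)
        try:
            activity = float(row["relative_activity"])
        except ValueError:
            activity = None
        if activity is not None and not 0.0 <= activity <= 200.0:
            raise ValueError(
                f"row {rowno}: relative activity {activity} outside [0, 200]"
            )
        try:
            dist = float(row["distance_to_zn"])
        except ValueError:
            dist = None
        contacts = tuple(
            c for c in row["contact_chains"].split(";") if c and c != "-"
        )
        records.append(
            MutationRecord(
                wt, pos, mut, row["chain"].strip(), group, activity, dist,
                row["secondary_structure"].strip(), contacts,
            )
        )
    return records


def count_by_group(records: list[MutationRecord]) -> dict[str, int]:
    """Exhaustive partition counts; groups absent from the input count 0."""
    counts = {g: 0 for g in ("folding", "activity", "unclassified", "benign")}
    for rec in records:
        counts[rec.group] += 1
    return counts


def load_descriptor_table(path) -> list[DescriptorRow]:
    """Parse the normalized descriptor table; every value must lie in [0, 1]."""
    df = pd.read_csv(path, comment="#")
    value_cols = ["total_dihedral_mi", "ddg_norm", "ddg_sd_norm", "b2b_propensity"]
    missing = set(value_cols + ["mutation"]) - set(df.columns)
    if missing:
        raise ValueError(f"descriptor table missing columns: {sorted(missing)}")
    rows: list[DescriptorRow] = []
    for i, row in df.iterrows():
        for col in value_cols:
            v = float(row[col])
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"row {int(i) + 2}: {col}={v} outside [0, 1]"
                )
        rows.append(
            DescriptorRow(
                mutation=str(row["mutation"]),
                chain=str(row.get("chain", "")),
                group=str(row.get("group", "")),
                total_dihedral_mi=float(row["total_dihedral_mi"]),
                ddg_norm=float(row["ddg_norm"]),
                ddg_sd_norm=float(row["ddg_sd_norm"]),
                b2b_propensity=float(row["b2b_propensity"]),
                ddg_capped=bool(int(row.get("ddg_capped", 0))),
                ddg_sd_capped=bool(int(row.get("ddg_sd_capped", 0))),
                active_site=bool(int(row.get("active_site", 0))),
            )
        )
    return rows


def write_catalog(records: list[MutationRecord], path) -> None:
    """Write records back in the catalog CSV schema (no comment header)."""
    rows = []
    for r in records:
        rows.append(
            {
                "mutation": r.mutation,
                "chain": r.chain,
                "group": r.group,
                "relative_activity": (
                    "N.D." if r.relative_activity is None
                    else f"{r.relative_activity:g}"
                ),
                "distance_to_zn": (
                    "" if r.distance_to_zn is None else f"{r.distance_to_zn:g}"
                ),
                "secondary_structure": r.secondary_structure,
                "contact_chains": ";".join(r.contact_chains) or "-",
            }
        )
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, index=False)
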