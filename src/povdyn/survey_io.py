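"""Reading, validating and writing the flat household survey tables.

One panel dataset is a directory of five comma-separated UTF-8 tables
("." decimal, long format keyed by household_id and round):

* ``households.csv`` — one row per household x round: site, land
  cultivated (ha), off-farm income, education, and the wide welfare
  block (``hfias_q1..q9``, ``hdds_flush_*`` / ``hdds_lean_*`` food-group
  flags, ``ppi_*`` answer indices, ``months_food_shortage``).
* ``roster.csv`` — one row per household member (age, sex).
* ``livestock.csv`` — head counts per species.
* ``crops.csv`` / ``livestock_products.csv`` — per-product produced /
  consumed / sold kg and reported sale income.

Missing numeric cells are read as 0 for quantities but as *missing* for
welfare items: welfare scores require complete responses, quantities
default to "none reported".  Rows violating record invariants (e.g.
consumed + sold exceeding production by more than the 5% recall
tolerance) are excluded and reported, never silently dropped.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .conversions import ConversionTable
from .records import (HouseholdRecord, Member, ProduceRow, RecordError,
                      WelfareResponses)

__all__ = [
    "SCHEMA_VERSION",
    "read_household_table",
    "read_panel",
    "write_panel",
    "validate_dataset",
    "retention_percent",
]


def retention_percent(n_resurveyed: int, n_first_round: int) -> int:
    """Panel retention as a whole percentage.

    Ties at half a percent round down: a site is credited a percentage
    point of retention only once it is fully earned (147 of 200 -> 73).
    """
    if n_first_round <= 0:
        raise ValueError("first-round count must be > 0")
    if not 0 <= n_resurveyed <= n_first_round:
        raise ValueError("resurveyed count must be within [0, n_first_round]")
    pct = 100.0 * n_resurveyed / n_first_round
    return math.ceil(pct - 0.5)

SCHEMA_VERSION = "1"

HOUSEHOLD_COLUMNS = ["household_id", "site", "round", "land_cultivated_ha",
                     "off_farm_income", "education", "months_food_shortage"]
ROSTER_COLUMNS = ["household_id", "round", "age", "sex"]
LIVESTOCK_COLUMNS = ["household_id", "round", "species", "count"]
PRODUCE_COLUMNS = ["household_id", "round", "product", "produced_kg",
                   "consumed_kg", "sold_kg", "sale_income"]

_FILES = {
    "households": ("households.csv", HOUSEHOLD_COLUMNS),
    "roster": ("roster.csv", ROSTER_COLUMNS),
    "livestock": ("livestock.csv", LIVESTOCK_COLUMNS),
    "crops": ("crops.csv", PRODUCE_COLUMNS),
    "livestock_products": ("livestock_products.csv", PRODUCE_COLUMNS),
}


def _read_csv(path: Path, mandatory: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"household_id": str})
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory columns {missing}")
    return df


def _num(value, default: float = 0.0) -> float:
    """Quantity cell: blank reads as 0 (none reported)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    return float(value)


def _opt_int(value) -> Optional[int]:
    """Welfare cell: blank stays missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(value)


def _welfare_from_row(row: pd.Series) -> WelfareResponses:
    hfias = {f"q{i}": _opt_int(row.get(f"hfias_q{i}")) for i in range(1, 10)}
    if all(v is None for v in hfias.values()):
        hfias = None
    elif any(v is None for v in hfias.values()):
        hfias = {k: v for k, v in hfias.items() if v is not None}

    def _flags(prefix: str) -> Optional[dict[str, bool]]:
        flags = {}
        for col in row.index:
            if col.startswith(prefix):
                v = _opt_int(row[col])
                if v is not None:
                    flags[col[len(prefix):]] = bool(v)
        return flags or None

    ppi = {}
    for col in row.index:
        if col.startswith("ppi_"):
            v = _opt_int(row[col])
            if v is not None:
                ppi[col[len("ppi_"):]] = v
    return WelfareResponses(
        hfias=hfias,
        hdds_flush=_flags("hdds_flush_"),
        hdds_lean=_flags("hdds_lean_"),
        ppi_answers=ppi or None,
        months_food_shortage=_opt_int(row.get("months_food_shortage")),
    )


def read_household_table(path: Union[str, Path],
                         schema_version: str = SCHEMA_VERSION,
                         ) -> tuple[list[HouseholdRecord], list[RecordError]]:
    """Read a panel directory into validated household records.

    Returns ``(records, errors)``: rows violating record invariants are
    excluded from ``records`` and reported in ``errors`` with their
    household id.  A missing mandatory column is a hard failure naming
    the column.  Row order of ``households.csv`` is preserved.
    """
    if schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {schema_version!r}")
    root = Path(path)
    tables = {key: _read_csv(root / fname, cols)
              for key, (fname, cols) in _FILES.items()}

    def _by_household(df: pd.DataFrame) -> dict[tuple[str, int], pd.DataFrame]:
        if df.empty:
            return {}
        return {key: grp for key, grp in
                df.groupby(["household_id", "round"], sort=False)}

    roster_g = _by_household(tables["roster"])
    livestock_g = _by_household(tables["livestock"])
    crops_g = _by_household(tables["crops"])
    products_g = _by_household(tables["livestock_products"])

    def _rows(group: Optional[pd.DataFrame]) -> list[ProduceRow]:
        if group is None:
            return []
        return [
            ProduceRow(
                product=str(r["product"]),
                produced=_num(r["produced_kg"]),
                consumed=_num(r["consumed_kg"]),
                sold=_num(r["sold_kg"]),
                sale_income=(None if pd.isna(r["sale_income"])
                             else float(r["sale_income"])),
            )
            for _, r in group.iterrows()
        ]

    records: list[HouseholdRecord] = []
    errors: list[RecordError] = []
    for _, row in tables["households"].iterrows():
        hid = str(row["household_id"])
        rnd = int(row["round"])
        key = (hid, rnd)
        roster_df = roster_g.get(key)
        roster = ([Member(age=float(r["age"]), sex=str(r["sex"]))
                   for _, r in roster_df.iterrows()]
                  if roster_df is not None else [])
        livestock_df = livestock_g.get(key)
        livestock = ({str(r["species"]): _num(r["count"])
                      for _, r in livestock_df.iterrows()}
                     if livestock_df is not None else {})
        education = row.get("education")
        record = HouseholdRecord(
            household_id=hid,
            site=str(row["site"]),
            round=rnd,
            roster=roster,
            land_cultivated=_num(row["land_cultivated_ha"]),
            livestock_counts=livestock,
            crop_rows=_rows(crops_g.get(key)),
            livestock_product_rows=_rows(products_g.get(key)),
            off_farm_income=_num(row["off_farm_income"]),
            education=None if pd.isna(education) else str(education),
            welfare=_welfare_from_row(row),
        )
        problems = record.check()
        if problems:
            errors.extend(RecordError(hid, rnd, msg) for msg in problems)
        else:
            records.append(record)
    return records, errors


#: Alias matching the directory-level reading entry point.
read_panel = read_household_table


def _welfare_to_cells(w: WelfareResponses) -> dict:
    cells: dict = {}
    if w.hfias:
        for q, v in w.hfias.items():
            cells[f"hfias_{q}"] = v
    if w.hdds_flush:
        for g, v in w.hdds_flush.items():
            cells[f"hdds_flush_{g}"] = int(v)
    if w.hdds_lean:
        for g, v in w.hdds_lean.items():
            cells[f"hdds_lean_{g}"] = int(v)
    if w.ppi_answers:
        for q, v in w.ppi_answers.items():
            cells[f"ppi_{q}"] = v
    if w.months_food_shortage is not None:
        cells["months_food_shortage"] = w.months_food_shortage
    return cells


def write_panel(records: Iterable[HouseholdRecord],
                path: Union[str, Path],
                conversion_table: Optional[ConversionTable] = None) -> Path:
    """Write records (any mix of rounds) to a panel directory.

    Emits the same CSV dialect :func:`read_household_table` reads, plus
    ``conversions.yaml`` when a conversion table is given.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    households, roster, livestock, crops, products = [], [], [], [], []
    for rec in records:
        base = {
            "household_id": rec.household_id, "site": rec.site,
            "round": rec.round, "land_cultivated_ha": rec.land_cultivated,
            "off_farm_income": rec.off_farm_income,
            "education": rec.education,
        }
        base.update(_welfare_to_cells(rec.welfare))
        households.append(base)
        for m in rec.roster:
            roster.append({"household_id": rec.household_id,
                           "round": rec.round, "age": m.age, "sex": m.sex})
        for species, count in rec.livestock_counts.items():
            livestock.append({"household_id": rec.household_id,
                              "round": rec.round, "species": species,
                              "count": count})
        for rows, bucket in ((rec.crop_rows, crops),
                             (rec.livestock_product_rows, products)):
            for r in rows:
                bucket.append({
                    "household_id": rec.household_id, "round": rec.round,
                    "product": r.product, "produced_kg": r.produced,
                    "consumed_kg": r.consumed, "sold_kg": r.sold,
                    "sale_income": (np.nan if r.sale_income is None
                                    else r.sale_income),
                })

    frames = {
        "households": pd.DataFrame(households),
        "roster": pd.DataFrame(roster),
        "livestock": pd.DataFrame(livestock),
        "crops": pd.DataFrame(crops),
        "livestock_products": pd.DataFrame(products),
    }
    for key, (fname, cols) in _FILES.items():
        df = frames[key]
        for c in cols:
            if c not in df.columns:
                df[c] = np.nan
        ordered = [c for c in cols if c in df.columns] + \
            sorted(c for c in df.columns if c not in cols)
        df[ordered].to_csv(root / fname, index=False)
    if conversion_table is not None:
        conversion_table.to_yaml(root / "conversions.yaml")
    return root


def validate_dataset(records: Iterable[HouseholdRecord],
                     conversion_table: ConversionTable) -> list[dict]:
    """Report-only cross checks of a dataset against its conversion table.

    Findings (list of dicts with ``kind``, ``household_id`` and detail):
    unpriced products, livestock species without a TLU weight, and
    households present in round 2 but not round 1.  Inputs are never
    modified.
    """
    findings: list[dict] = []
    records = list(records)
    round1_ids = {r.household_id for r in records if r.round == 1}
    for rec in records:
        for row in list(rec.crop_rows) + list(rec.livestock_product_rows):
            if (rec.site, rec.round, row.product) not in conversion_table.prices:
                findings.append({
                    "kind": "unpriced_product", "household_id": rec.household_id,
                    "round": rec.round, "site": rec.site,
                    "product": row.product,
                })
        for species in rec.livestock_counts:
            if species not in conversion_table.tlu_weights:
                findings.append({
                    "kind": "unknown_species",
                    "household_id": rec.household_id,
                    "round": rec.round, "species": species,
                })
        if rec.round == 2 and rec.household_id not in round1_ids:
            findings.append({
                "kind": "unmatched_panel_id",
                "household_id": rec.household_id, "round": 2,
            })
    return findings
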