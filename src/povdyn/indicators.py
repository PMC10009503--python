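"""Per-household derived indicators.

From one household record and a conversion table this module derives:

* **MAE** — male adult equivalents, the sum of age/sex calorie-demand
  factors over the roster; the denominator for per-person quantities.
* **TLU** — tropical livestock units, the weighted livestock inventory.
* **Component values** — the $PPP/yr value of crops consumed, crops
  sold, livestock products consumed, livestock products sold, and
  off-farm income.  Sold produce is valued at reported sale income when
  the survey captured it, falling back to quantity x local price.
* **TVA** — total value of activities, the sum of the five components.
* **FA** — food availability in kcal/MAE/day: calories of consumed farm
  produce plus all cash income (sales + off-farm) converted to calorie
  equivalents at the local staple (maize) price.
* **Intensity metrics** — crop value per hectare, livestock value per
  TLU, off-farm income per MAE.

Intensities with a zero denominator are 0 when the numerator is also 0
(no activity at all) and NaN (missing, excluded from group summaries)
when value was produced with no recorded denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Optional

import pandas as pd

from .conversions import ConversionTable
from .records import HouseholdRecord, Member, ProduceRow

__all__ = [
    "IndicatorSet",
    "compute_mae",
    "compute_tlu",
    "value_production",
    "compute_fa",
    "compute_intensities",
    "compute_indicators",
    "indicator_table",
]

DAYS_PER_YEAR = 365.0


@dataclass
class IndicatorSet:
    """Derived values for one household in one round.

    Monetary components are $PPP per year; ``fa`` is kcal per MAE per
    day; intensities are $PPP per ha, per TLU, and per MAE per year.
    """

    household_id: str
    site: str
    round: int
    n_members: int
    mae: float
    tlu: float
    land_cultivated: float
    value_consumed_crops: float
    value_sold_crops: float
    value_consumed_livestock: float
    value_sold_livestock: float
    off_farm_income: float
    tva: float
    tva_per_mae_day: float
    fa: float
    crop_value: float
    livestock_value: float
    crop_intensity: float
    livestock_intensity: float
    offfarm_intensity: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_mae(roster: Iterable[Member], table: ConversionTable) -> float:
    """Male-adult-equivalent household size: sum of roster factors.

    Raises ``ValueError`` on an empty roster or a negative age.
    """
    roster = list(roster)
    if not roster:
        raise ValueError("empty roster: MAE undefined")
    return sum(table.mae_factor(m.age, m.sex) for m in roster)


def compute_tlu(livestock_counts: dict[str, float],
                tlu_weights: dict[str, float]) -> float:
    """Tropical livestock units: sum of head counts x species weights.

    Every species present must have a weight; unknown species raise
    ``KeyError`` naming the species.
    """
    total = 0.0
    for species, count in livestock_counts.items():
        if species not in tlu_weights:
            raise KeyError(f"no TLU weight for species {species!r}")
        if count < 0:
            raise ValueError(f"negative count for species {species!r}")
        total += count * tlu_weights[species]
    return total


def _row_values(rows: Iterable[ProduceRow], site: str, round: int,
                table: ConversionTable) -> tuple[float, float]:
    """(consumed value, sold value) in local currency for a set of rows."""
    consumed = 0.0
    sold = 0.0
    for row in rows:
        price = table.price(site, round, row.product)
        consumed += row.consumed * price
        if row.sale_income is not None:
            sold += row.sale_income
        else:
            sold += row.sold * price
    return consumed, sold


def value_production(record: HouseholdRecord,
                     table: ConversionTable) -> dict[str, float]:
    """Component values in $PPP/yr for one household.

    Consumed produce is valued at the local price; sold produce at the
    reported sale income when present, else sold kg x price.  All values
    are divided by the site/round PPP factor.
    """
    ppp = table.get_ppp(record.site, record.round)
    cc, cs = _row_values(record.crop_rows, record.site, record.round, table)
    lc, ls = _row_values(record.livestock_product_rows, record.site,
                         record.round, table)
    return {
        "value_consumed_crops": cc / ppp,
        "value_sold_crops": cs / ppp,
        "value_consumed_livestock": lc / ppp,
        "value_sold_livestock": ls / ppp,
        "off_farm_income": record.off_farm_income / ppp,
    }


def compute_fa(record: HouseholdRecord, mae: float,
               table: ConversionTable) -> float:
    """Food availability in kcal per MAE per day.

    Calories of consumed produce (direct energy densities where known,
    otherwise consumed value converted at the maize price) plus cash
    income (all sales + off-farm) converted to maize-calorie equivalents:

        FA = [ sum(consumed kcal) + cash x maize_energy / maize_price ]
             / (MAE x 365)
    """
    if mae <= 0:
        raise ValueError("MAE must be > 0")
    maize_price = table.get_maize_price(record.site, record.round)
    energy = table.maize_energy

    kcal = 0.0
    cash = float(record.off_farm_income)
    for row in list(record.crop_rows) + list(record.livestock_product_rows):
        density = table.energy_density(row.product)
        if density is not None:
            kcal += row.consumed * density
        else:
            value = row.consumed * table.price(record.site, record.round,
                                               row.product)
            kcal += value * energy / maize_price
        if row.sale_income is not None:
            cash += row.sale_income
        else:
            cash += row.sold * table.price(record.site, record.round,
                                           row.product)
    kcal += cash * energy / maize_price
    return kcal / (mae * DAYS_PER_YEAR)


def _intensity(numerator: float, denominator: float) -> float:
    """value/denominator; 0 when both are 0; NaN when only the denominator is 0."""
    if denominator > 0:
        return numerator / denominator
    return 0.0 if numerator == 0 else math.nan


def compute_intensities(crop_value: float, livestock_value: float,
                        off_farm: float, land: float, tlu: float,
                        mae: float) -> tuple[float, float, float]:
    """(crop $/ha/yr, livestock $/TLU/yr, off-farm $/MAE/yr)."""
    if mae <= 0:
        raise ValueError("MAE must be > 0")
    return (
        _intensity(crop_value, land),
        _intensity(livestock_value, tlu),
        off_farm / mae,
    )


def compute_indicators(record: HouseholdRecord,
                       table: ConversionTable) -> IndicatorSet:
    """Full indicator set for one household record."""
    mae = compute_mae(record.roster, table)
    tlu = compute_tlu(record.livestock_counts, table.tlu_weights)
    comps = value_production(record, table)
    tva = sum(comps.values())
    crop_value = comps["value_consumed_crops"] + comps["value_sold_crops"]
    livestock_value = (comps["value_consumed_livestock"]
                       + comps["value_sold_livestock"])
    fa = compute_fa(record, mae, table)
    ci, li, oi = compute_intensities(crop_value, livestock_value,
                                     comps["off_farm_income"],
                                     record.land_cultivated, tlu, mae)
    return IndicatorSet(
        household_id=record.household_id,
        site=record.site,
        round=record.round,
        n_members=len(record.roster),
        mae=mae,
        tlu=tlu,
        land_cultivated=record.land_cultivated,
        tva=tva,
        tva_per_mae_day=tva / (mae * DAYS_PER_YEAR),
        fa=fa,
        crop_value=crop_value,
        livestock_value=livestock_value,
        crop_intensity=ci,
        livestock_intensity=li,
        offfarm_intensity=oi,
        **comps,
    )


def indicator_table(records: Iterable[HouseholdRecord],
                    table: ConversionTable) -> pd.DataFrame:
    """Indicator sets for many records as one tidy frame (row per household x round)."""
    rows = [compute_indicators(r, table).as_dict() for r in records]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=[f.name for f in fields(IndicatorSet)])
    return df
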