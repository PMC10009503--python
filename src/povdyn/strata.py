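"""Poverty strata, trajectories, flows, shares, and net-change summaries.

Households are classified per round into three prosperity strata using
two thresholds on the derived indicators:

* **Low** — food availability below the calorie line (default
  3000 kcal/MAE/day): unlikely to secure basic calorie needs.
* **Medium** — meets the calorie line but total value of activities is
  below the international poverty line (default $1.90 PPP/MAE/day).
* **High** — total value of activities at or above the poverty line.

The value test takes precedence: a household above $1.90/day is High
even in the rare case its food-availability score falls below the
calorie line (such discordant households are counted and reported).
Threshold comparisons are closed on the upper side (``>=``).

A household's *trajectory* is its stratum in round 1 paired with its
stratum in round 2, one of nine labels ("Low to Low" ... "High to
High"), each rising, steady, or falling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "STRATA",
    "CALORIE_LINE",
    "POVERTY_LINE",
    "StratumAssignment",
    "Trajectory",
    "classify_stratum",
    "assign_strata",
    "assign_trajectory",
    "assign_trajectories",
    "strata_proportions",
    "flow_matrix",
    "value_land_ratio",
    "share_table",
    "net_change_by_trajectory",
]

#: Stratum labels in increasing prosperity order.
STRATA = ("Low", "Medium", "High")
_RANK = {s: i for i, s in enumerate(STRATA)}

CALORIE_LINE = 3000.0   # kcal per MAE per day
POVERTY_LINE = 1.90     # $PPP per MAE per day


@dataclass(frozen=True)
class StratumAssignment:
    household_id: str
    round: int
    stratum: str
    fa: float
    tva_per_mae_day: float


@dataclass(frozen=True)
class Trajectory:
    household_id: str
    from_stratum: str
    to_stratum: str

    @property
    def label(self) -> str:
        return f"{self.from_stratum} to {self.to_stratum}"

    @property
    def direction(self) -> str:
        d = _RANK[self.to_stratum] - _RANK[self.from_stratum]
        return "rising" if d > 0 else ("falling" if d < 0 else "steady")


def classify_stratum(fa: float, tva_per_mae_day: float,
                     calorie_line: float = CALORIE_LINE,
                     poverty_line: float = POVERTY_LINE) -> str:
    """Classify one household from its FA and TVA-per-MAE-day values.

    High if TVA/MAE/day >= poverty line; else Medium if FA >= calorie
    line; else Low.  Negative inputs are rejected.
    """
    if fa < 0 or tva_per_mae_day < 0:
        raise ValueError("FA and TVA must be non-negative")
    if tva_per_mae_day >= poverty_line:
        return "High"
    if fa >= calorie_line:
        return "Medium"
    return "Low"


def assign_strata(indicators: pd.DataFrame,
                  calorie_line: float = CALORIE_LINE,
                  poverty_line: float = POVERTY_LINE) -> pd.DataFrame:
    """Vectorised classification of an indicator frame.

    Returns a frame with household_id, round, stratum, fa,
    tva_per_mae_day and a ``discordant`` flag marking High-by-value
    households whose FA is below the calorie line.
    """
    fa = indicators["fa"].to_numpy(float)
    tva = indicators["tva_per_mae_day"].to_numpy(float)
    if (fa < 0).any() or (tva < 0).any():
        raise ValueError("FA and TVA must be non-negative")
    stratum = np.where(tva >= poverty_line, "High",
                       np.where(fa >= calorie_line, "Medium", "Low"))
    return pd.DataFrame({
        "household_id": indicators["household_id"].to_numpy(),
        "round": indicators["round"].to_numpy(),
        "stratum": stratum,
        "fa": fa,
        "tva_per_mae_day": tva,
        "discordant": (tva >= poverty_line) & (fa < calorie_line),
    })


def assign_trajectory(r1: StratumAssignment,
                      r2: StratumAssignment) -> Trajectory:
    """Pair a household's two round assignments into a trajectory."""
    if r1.household_id != r2.household_id:
        raise ValueError(
            f"household id mismatch: {r1.household_id!r} vs {r2.household_id!r}"
        )
    return Trajectory(r1.household_id, r1.stratum, r2.stratum)


def assign_trajectories(assignments: pd.DataFrame) -> pd.DataFrame:
    """Trajectories for all households observed in both rounds.

    ``assignments`` is the output of :func:`assign_strata` for both
    rounds stacked; households missing either round are dropped.
    """
    r1 = assignments[assignments["round"] == 1].set_index("household_id")
    r2 = assignments[assignments["round"] == 2].set_index("household_id")
    common = r1.index.intersection(r2.index)
    from_s = r1.loc[common, "stratum"]
    to_s = r2.loc[common, "stratum"]
    rank = from_s.map(_RANK).to_numpy()
    rank2 = to_s.map(_RANK).to_numpy()
    delta = rank2 - rank
    direction = np.where(delta > 0, "rising",
                         np.where(delta < 0, "falling", "steady"))
    return pd.DataFrame({
        "household_id": common.to_numpy(),
        "from_stratum": from_s.to_numpy(),
        "to_stratum": to_s.to_numpy(),
        "label": [f"{a} to {b}" for a, b in zip(from_s, to_s)],
        "direction": direction,
    })


def strata_proportions(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-round proportions of households in each stratum (rows sum to 1)."""
    if assignments.empty:
        raise ValueError("no assignments")
    counts = (assignments.groupby(["round", "stratum"]).size()
              .unstack(fill_value=0).reindex(columns=STRATA, fill_value=0))
    return counts.div(counts.sum(axis=1), axis=0)


def flow_matrix(trajectories: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """3x3 stratum-to-stratum counts and rising/steady/falling shares.

    Row marginals equal round-1 strata counts among the matched panel
    households; the grand total is the number of panel households.
    """
    counts = pd.crosstab(trajectories["from_stratum"],
                         trajectories["to_stratum"])
    counts = counts.reindex(index=STRATA, columns=STRATA, fill_value=0)
    n = len(trajectories)
    shares = {
        d: (trajectories["direction"] == d).sum() / n if n else 0.0
        for d in ("rising", "steady", "falling")
    }
    return counts, shares


def value_land_ratio(value_share: float, land_share: float) -> float:
    """Ratio of a stratum's share of farm-produce value to its share of land.

    Shares may be proportions or percentages, as long as both use the
    same scale.  A ratio above 1 means the stratum produces more value
    than its land share alone would suggest.
    """
    if land_share <= 0:
        raise ValueError("land share must be > 0")
    return value_share / land_share


def share_table(assignments: pd.DataFrame,
                indicators: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum shares of population, land, and farm-produce value.

    One row per round x stratum with percentage columns (summing to 100
    within each round) and the value:land share ratio at full precision.
    """
    ind = indicators.merge(
        assignments[["household_id", "round", "stratum"]],
        on=["household_id", "round"], validate="one_to_one",
    )
    ind = ind.assign(produce_value=ind["crop_value"] + ind["livestock_value"])
    rows = []
    for rnd, grp in ind.groupby("round"):
        total_land = grp["land_cultivated"].sum()
        total_value = grp["produce_value"].sum()
        if total_land <= 0:
            raise ValueError(f"zero total land in round {rnd}")
        if total_value <= 0:
            raise ValueError(f"zero total produce value in round {rnd}")
        for stratum in STRATA:
            sub = grp[grp["stratum"] == stratum]
            pop = 100.0 * len(sub) / len(grp)
            land = 100.0 * sub["land_cultivated"].sum() / total_land
            value = 100.0 * sub["produce_value"].sum() / total_value
            rows.append({
                "round": rnd,
                "stratum": stratum,
                "pct_population": pop,
                "pct_land": land,
                "pct_value": value,
                "value_land_ratio": (value_land_ratio(value, land)
                                     if land > 0 else np.nan),
            })
    return pd.DataFrame(rows)


#: Metrics differenced between rounds in the net-change analysis.
NET_CHANGE_METRICS = (
    "crop_value", "livestock_value", "off_farm_income",
    "crop_intensity", "livestock_intensity", "offfarm_intensity",
)


def net_change_by_trajectory(indicators_r1: pd.DataFrame,
                             indicators_r2: pd.DataFrame,
                             trajectories: pd.DataFrame,
                             metrics: Iterable[str] = NET_CHANGE_METRICS,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Round-2 minus round-1 changes per household, grouped by trajectory.

    Returns ``(deltas, summary)``: per-household differences in long
    form, and per-trajectory-group medians (NaN-aware, so households
    with a missing intensity are excluded from that metric's median).
    Households without both rounds are excluded.
    """
    metrics = list(metrics)
    r1 = indicators_r1.set_index("household_id")
    r2 = indicators_r2.set_index("household_id")
    traj = trajectories.set_index("household_id")
    common = traj.index.intersection(r1.index).intersection(r2.index)
    delta = (r2.loc[common, metrics] - r1.loc[common, metrics])
    delta.insert(0, "label", traj.loc[common, "label"])
    delta.insert(1, "direction", traj.loc[common, "direction"])
    deltas = (delta.reset_index()
              .melt(id_vars=["household_id", "label", "direction"],
                    value_vars=metrics, var_name="metric", value_name="delta"))
    summary = (deltas.groupby(["label", "metric"])["delta"]
               .median().unstack("metric").reindex(columns=metrics))
    return deltas, summary
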