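"""Welfare indicator scoring and strata validation.

Four independent welfare indicators validate the poverty strata:

* **HFIAS** — Household Food Insecurity of Access Scale: nine
  experience items, each scored 0 (never) to 3 (often), summed to a
  0-27 score and mapped to four severity categories by the standard
  decision rules (most-severe condition wins).
* **HDDS** — Household Dietary Diversity Score: count of food groups
  consumed, scored separately for the post-harvest (flush) and lean
  seasons.
* **PPI** — Probability of Poverty Index: a generic scorecard engine;
  answer points are summed and mapped to a poverty likelihood through
  a step-function lookup.  Published country scorecards are data, not
  code; a synthetic fixture scorecard ships with the package.
* **Hungry months** — reported months of food shortage, 0-12.

``validate_strata`` compares each indicator across the three strata
with one-way ANOVA + Tukey HSD and reports whether the median ordering
runs in the better-welfare-in-higher-strata direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .panel_stats import ComparisonResult, anova_posthoc
from .records import HouseholdRecord
from .strata import STRATA

__all__ = [
    "HFIAS_CATEGORIES",
    "DEFAULT_FOOD_GROUPS",
    "PPIScorecard",
    "load_synthetic_scorecard",
    "score_hfias",
    "hfias_category",
    "score_hdds",
    "score_ppi",
    "welfare_scores",
    "validate_strata",
]

HFIAS_ITEMS = tuple(f"q{i}" for i in range(1, 10))
HFIAS_CATEGORIES = ("food secure", "mildly food insecure",
                    "moderately food insecure", "severely food insecure")

#: Default 10 food groups for the dietary diversity score.
DEFAULT_FOOD_GROUPS = (
    "grains", "pulses", "nuts_seeds", "dairy", "meat",
    "eggs", "leafy_greens", "vitamin_a_produce", "other_fruit",
    "other_vegetables",
)


def _check_hfias(items: dict[str, int]) -> Optional[list[int]]:
    """Return frequencies [q1..q9] if complete and in range, else None."""
    freqs = []
    for q in HFIAS_ITEMS:
        v = items.get(q)
        if v is None:
            return None
        v = int(v)
        if not 0 <= v <= 3:
            raise ValueError(f"HFIAS item {q} frequency {v} outside 0..3")
        freqs.append(v)
    return freqs


def score_hfias(items: dict[str, int]) -> Optional[int]:
    """HFIAS score 0-27: the sum of the nine item frequencies.

    Returns None (missing) if any item is unanswered; such households
    are excluded from HFIAS comparisons.
    """
    freqs = _check_hfias(items)
    return None if freqs is None else sum(freqs)


def hfias_category(items: dict[str, int]) -> Optional[str]:
    """Four-class severity category from the item/frequency pattern.

    Standard decision rules, checked from most to least severe:

    * severe   — q5 = 3, or q6 = 3, or any of q7-q9 >= 1
    * moderate — q3 or q4 in {2, 3}, or q5 or q6 in {1, 2}
    * mild     — q1 in {2, 3}, or q2 >= 1, or q3 = 1, or q4 = 1
    * secure   — otherwise (q1 <= 1, all other items 0)
    """
    freqs = _check_hfias(items)
    if freqs is None:
        return None
    q = dict(zip(HFIAS_ITEMS, freqs))
    if q["q5"] == 3 or q["q6"] == 3 or q["q7"] >= 1 or q["q8"] >= 1 or q["q9"] >= 1:
        return HFIAS_CATEGORIES[3]
    if q["q3"] >= 2 or q["q4"] >= 2 or q["q5"] in (1, 2) or q["q6"] in (1, 2):
        return HFIAS_CATEGORIES[2]
    if q["q1"] >= 2 or q["q2"] >= 1 or q["q3"] == 1 or q["q4"] == 1:
        return HFIAS_CATEGORIES[1]
    return HFIAS_CATEGORIES[0]


def score_hdds(food_groups: dict[str, bool],
               groups: Iterable[str] = DEFAULT_FOOD_GROUPS) -> int:
    """Dietary diversity: number of configured food groups consumed."""
    return sum(bool(food_groups.get(g, False)) for g in groups)


@dataclass
class PPIScorecard:
    """A poverty scorecard: per-question option points and a points ->
    likelihood step lookup (non-increasing in points for any published
    scorecard)."""

    name: str
    questions: dict[str, list[float]]          # question id -> option points
    lookup: list[tuple[float, float]] = field(default_factory=list)
    # sorted (min_points, likelihood) steps

    def __post_init__(self) -> None:
        self.lookup = sorted((float(a), float(b)) for a, b in self.lookup)
        if not self.lookup:
            raise ValueError("scorecard needs a points->likelihood lookup")

    @property
    def max_points(self) -> float:
        return sum(max(opts) for opts in self.questions.values())

    def likelihood(self, points: float) -> float:
        """Step-function lookup: the entry with the largest threshold <= points."""
        chosen = self.lookup[0][1]
        for threshold, lik in self.lookup:
            if points >= threshold:
                chosen = lik
        return chosen

    def is_monotone(self) -> bool:
        liks = [lik for _, lik in self.lookup]
        return all(b <= a for a, b in zip(liks, liks[1:]))

    @classmethod
    def from_dict(cls, d: dict) -> "PPIScorecard":
        return cls(
            name=d["name"],
            questions={q["id"]: [float(p) for p in q["points"]]
                       for q in d["questions"]},
            lookup=[(e["min_points"], e["likelihood"]) for e in d["lookup"]],
        )

    @classmethod
    def from_yaml(cls, path) -> "PPIScorecard":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_synthetic_scorecard() -> PPIScorecard:
    """The synthetic fixture scorecard shipped with the package."""
    text = (resources.files("povdyn") / "data" /
            "ppi_scorecard_synthetic.yaml").read_text(encoding="utf-8")
    return PPIScorecard.from_dict(yaml.safe_load(text))


def score_ppi(answers: dict[str, int],
              scorecard: PPIScorecard) -> Optional[tuple[float, float]]:
    """(points, poverty likelihood) for one household.

    Returns None (missing) if any scorecard question is unanswered.
    """
    points = 0.0
    for qid, options in scorecard.questions.items():
        idx = answers.get(qid)
        if idx is None:
            return None
        idx = int(idx)
        if not 0 <= idx < len(options):
            raise ValueError(
                f"answer {idx} out of range for question {qid!r}")
        points += options[idx]
    return points, scorecard.likelihood(points)


def welfare_scores(records: Iterable[HouseholdRecord],
                   scorecard: Optional[PPIScorecard] = None,
                   groups: Iterable[str] = DEFAULT_FOOD_GROUPS) -> pd.DataFrame:
    """Score all four indicators for a set of records (NaN where missing)."""
    if scorecard is None:
        scorecard = load_synthetic_scorecard()
    rows = []
    for rec in records:
        w = rec.welfare
        hfias = score_hfias(w.hfias) if w.hfias else None
        cat = hfias_category(w.hfias) if w.hfias else None
        ppi = score_ppi(w.ppi_answers, scorecard) if w.ppi_answers else None
        rows.append({
            "household_id": rec.household_id,
            "round": rec.round,
            "hfias_score": np.nan if hfias is None else hfias,
            "hfias_category": cat,
            "hdds_flush": (score_hdds(w.hdds_flush, groups)
                           if w.hdds_flush is not None else np.nan),
            "hdds_lean": (score_hdds(w.hdds_lean, groups)
                          if w.hdds_lean is not None else np.nan),
            "ppi_score": np.nan if ppi is None else ppi[0],
            "ppi_likelihood": np.nan if ppi is None else ppi[1],
            "hungry_months": (np.nan if w.months_food_shortage is None
                              else w.months_food_shortage),
        })
    return pd.DataFrame(rows)


#: Indicators used in validation and whether higher values mean better welfare.
VALIDATION_INDICATORS = {
    "hdds_flush": True,
    "hdds_lean": True,
    "hfias_score": False,
    "ppi_likelihood": False,
    "hungry_months": False,
}


def validate_strata(scores: pd.DataFrame, assignments: pd.DataFrame,
                    alpha: float = 0.05, round: int = 2
                    ) -> dict[str, dict]:
    """Compare welfare indicators across strata (round 2 by default).

    For each indicator: one-way ANOVA + Tukey HSD across the three
    strata, the per-stratum medians, and whether the medians run in the
    expected better-welfare-in-higher-strata direction.  Indicators
    with any stratum holding fewer than 2 scored households are skipped.
    """
    merged = scores.merge(
        assignments[["household_id", "round", "stratum"]],
        on=["household_id", "round"])
    merged = merged[merged["round"] == round]
    results: dict[str, dict] = {}
    for indicator, higher_better in VALIDATION_INDICATORS.items():
        sub = merged[["stratum", indicator]].dropna()
        counts = sub.groupby("stratum").size().reindex(STRATA, fill_value=0)
        if (counts < 2).any():
            results[indicator] = {"skipped": True,
                                  "reason": f"stratum counts {counts.to_dict()}"}
            continue
        comparison = anova_posthoc(sub[indicator], sub["stratum"],
                                   method="tukey_hsd", alpha=alpha)
        medians = sub.groupby("stratum")[indicator].median().reindex(list(STRATA))
        ordered = medians.to_numpy()
        diffs = np.diff(ordered)
        direction_ok = bool(np.all(diffs >= 0) if higher_better
                            else np.all(diffs <= 0))
        results[indicator] = {
            "skipped": False,
            "comparison": comparison,
            "medians": medians.to_dict(),
            "higher_is_better": higher_better,
            "direction_ok": direction_ok,
        }
    return results
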