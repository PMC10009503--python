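"""Synthetic two-round household panel generator.

Generates household survey panels with the statistical structure the
analysis assumes, so the full pipeline is testable without any external
data.  Generation is *latent-first*: each household's prosperity
stratum is drawn first (round 1 from the designed proportions, round 2
from the designed transition matrix), and the observable survey fields
(roster, land, livestock, crop and product quantities, incomes) are
then constructed so that the indicator pipeline maps the household back
into its latent stratum.  Ground truth therefore exists for parameter
recovery tests.

Construction of observables
---------------------------
For each household x round a (food availability, TVA-per-MAE-day)
target is drawn from truncated lognormal distributions confined to the
latent stratum's region of indicator space.  The target pair is then
back-solved into product quantities against the generated price table.
Products fall in two buckets with a common calorie yield per unit value
within each bucket — calorie-dense staples (maize, beans, sorghum) and
low-calorie produce (vegetables, milk) — so the two-equation system
(consumed value, consumed calories) has an exact non-negative solution.
Cash (sales + off-farm income) converts to calories at the maize price,
exactly as the food-availability indicator assumes.

Distributional families (lognormal land/TLU, discrete-uniform household
size, right-skewed values) are modelling choices: the emulated study
reports medians and ranges, not families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from statistics import NormalDist
from typing import Optional, Sequence

import numpy as np
import yaml

from .conversions import ConversionTable, DEFAULT_MAIZE_ENERGY
from .indicators import DAYS_PER_YEAR, compute_mae
from .records import HouseholdRecord, Member, ProduceRow, WelfareResponses
from .strata import CALORIE_LINE, POVERTY_LINE
from .welfare import DEFAULT_FOOD_GROUPS, load_synthetic_scorecard

_STD_NORMAL = NormalDist()

__all__ = [
    "SiteConfig",
    "TrajectoryDesign",
    "DEFAULT_SITES",
    "DEFAULT_DESIGN",
    "generate_price_table",
    "generate_panel",
    "design_to_yaml",
    "design_from_yaml",
]


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteConfig:
    """Sampling design and marginal distributions for one site."""

    site_name: str
    n_villages: int = 7
    households_per_village: int = 20
    retention_fraction: float = 0.75
    land_lognormal: tuple[float, float] = (math.log(1.5), 0.6)   # log-ha
    tlu_lognormal: tuple[float, float] = (math.log(2.0), 0.8)    # log-TLU
    household_size_range: tuple[int, int] = (3, 8)
    price_ref: Optional[str] = None   # site key in the conversion table

    def __post_init__(self) -> None:
        if not 0 < self.retention_fraction <= 1:
            raise ValueError("retention_fraction must be in (0, 1]")
        if self.n_villages < 1 or self.households_per_village < 1:
            raise ValueError("need at least one village and one household")
        if self.land_lognormal[1] <= 0 or self.tlu_lognormal[1] <= 0:
            raise ValueError("lognormal scale parameters must be > 0")
        lo, hi = self.household_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid household_size_range")

    @property
    def n_households(self) -> int:
        return self.n_villages * self.households_per_village

    @property
    def n_resurveyed(self) -> int:
        return round(self.retention_fraction * self.n_households)

    @property
    def price_site(self) -> str:
        return self.price_ref or self.site_name


@dataclass(frozen=True)
class TrajectoryDesign:
    """Designed first-round strata proportions and transition structure."""

    target_first_round_proportions: tuple[float, float, float]
    transition_matrix: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.target_first_round_proportions, dtype=float)
        t = np.asarray(self.transition_matrix, dtype=float)
        if p.shape != (3,) or t.shape != (3, 3):
            raise ValueError("need a 3-vector and a 3x3 matrix")
        if (p < 0).any() or (t < 0).any():
            raise ValueError("proportions and transition entries must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("first-round proportions must sum to 1")
        if np.abs(t.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.target_first_round_proportions, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.transition_matrix, dtype=float)


#: Default four-site design: 7 villages x 20 households per site, with
#: resurvey retention fractions of 73.5%, 67.5%, 80% and 80%.
DEFAULT_SITES: tuple[SiteConfig, ...] = (
    SiteConfig("site-A", retention_fraction=0.735),
    SiteConfig("site-B", retention_fraction=0.675),
    SiteConfig("site-C", retention_fraction=0.80),
    SiteConfig("site-D", retention_fraction=0.80),
)

#: Default trajectory design: first-round strata 30/33/37 and a
#: transition structure whose implied second-round mix is ~27/33/40,
#: with the largest flows out of High into Medium and High.
DEFAULT_DESIGN = TrajectoryDesign(
    target_first_round_proportions=(0.30, 0.33, 0.37),
    transition_matrix=(
        (0.34, 0.33, 0.33),
        (0.33, 0.33, 0.34),
        (0.16, 0.33, 0.51),
    ),
)


# ---------------------------------------------------------------------------
# Price table
# ---------------------------------------------------------------------------

#: Product set with energy densities (kcal/kg) and bucket membership.
#: Within a bucket every product yields the same calories per unit of
#: value, which keeps the quantity back-solve exact.
HIGH_CAL_PRODUCTS = {"maize": DEFAULT_MAIZE_ENERGY, "beans": 3450.0,
                     "sorghum": 3430.0}
LOW_CAL_PRODUCTS = {"vegetable": 350.0, "milk": 640.0}
CROP_PRODUCTS = ("maize", "beans", "sorghum", "vegetable")
LIVESTOCK_PRODUCTS = ("milk",)

_BASE_MAIZE_PRICE_PPP = 0.25      # $PPP per kg
_BASE_VEGETABLE_PRICE_PPP = 0.50  # $PPP per kg


def generate_price_table(sites: Sequence[SiteConfig],
                         seed: int) -> ConversionTable:
    """Site x round price/conversion table with positive jittered prices.

    Each site gets a PPP factor (local currency per international $)
    and per-round local prices for every product; maize price and
    energy density are always present.  Deterministic in the seed, and
    stable per site index (adding a site leaves earlier sites' prices
    unchanged).
    """
    prices: dict[tuple[str, int, str], float] = {}
    maize_price: dict[tuple[str, int], float] = {}
    ppp: dict[tuple[str, int], float] = {}
    for idx, site in enumerate(sites):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7919, idx]))
        name = site.price_site
        base_ppp = float(rng.uniform(30, 900))
        maize_ppp = _BASE_MAIZE_PRICE_PPP * float(rng.lognormal(0, 0.10))
        veg_ppp = _BASE_VEGETABLE_PRICE_PPP * float(rng.lognormal(0, 0.10))
        for rnd in (1, 2):
            jitter_m = float(rng.lognormal(0, 0.08)) if rnd == 2 else 1.0
            jitter_v = float(rng.lognormal(0, 0.08)) if rnd == 2 else 1.0
            ppp[(name, rnd)] = base_ppp * (float(rng.lognormal(0, 0.03))
                                           if rnd == 2 else 1.0)
            pm = maize_ppp * jitter_m * ppp[(name, rnd)]
            pv = veg_ppp * jitter_v * ppp[(name, rnd)]
            maize_price[(name, rnd)] = pm
            # high-calorie bucket: equal kcal per unit value as maize
            for product, energy in HIGH_CAL_PRODUCTS.items():
                prices[(name, rnd, product)] = pm * energy / DEFAULT_MAIZE_ENERGY
            # low-calorie bucket: equal kcal per unit value as vegetables
            for product, energy in LOW_CAL_PRODUCTS.items():
                prices[(name, rnd, product)] = pv * energy / LOW_CAL_PRODUCTS[
                    "vegetable"]
    kcal = dict(HIGH_CAL_PRODUCTS) | dict(LOW_CAL_PRODUCTS)
    return ConversionTable(prices=prices, maize_price=maize_price,
                           ppp_factor=ppp, kcal_per_kg=kcal)


# ---------------------------------------------------------------------------
# Household generation
# ---------------------------------------------------------------------------

def _trunc_lognormal(rng: np.random.Generator, median: float, sigma: float,
                     lo: float, hi: float) -> float:
    """One draw from a lognormal(ln median, sigma) truncated to [lo, hi]."""
    if hi <= lo:
        return lo
    mu = math.log(median)
    a = _STD_NORMAL.cdf((math.log(lo) - mu) / sigma)
    b = _STD_NORMAL.cdf((math.log(hi) - mu) / sigma)
    u = rng.uniform(a, b)
    z = _STD_NORMAL.inv_cdf(min(max(u, 1e-12), 1 - 1e-12))
    return float(math.exp(mu + sigma * z))


# per-stratum generation settings: (fa median, fa sigma), (tva median,
# tva sigma), cash-share Beta, off-farm-share Beta, asset multipliers
_FA_MEDIAN = {0: 1500.0, 1: 3500.0, 2: 5000.0}
_TVA_MEDIAN = {0: 0.55, 1: 0.90, 2: 2.5 * POVERTY_LINE}
_CASH_BETA = {0: (2.0, 5.0), 1: (3.0, 3.0), 2: (5.0, 2.0)}
_OFFFARM_BETA = {0: (2.0, 4.0), 1: (2.5, 2.5), 2: (4.0, 2.0)}
_LAND_MULT = (0.7, 1.0, 1.4)
_TLU_MULT = (0.5, 1.0, 2.2)
_EDU_PROBS = {
    0: (0.30, 0.50, 0.15, 0.05),
    1: (0.15, 0.50, 0.25, 0.10),
    2: (0.05, 0.35, 0.40, 0.20),
}
EDUCATION_LEVELS = ("none", "primary", "secondary", "post-secondary")

# classification margin kept clear of both thresholds
_FA_BAND = {0: (400.0, 0.95 * CALORIE_LINE),
            1: (1.02 * CALORIE_LINE, 3.0 * CALORIE_LINE)}
_TVA_CAP = 0.95 * POVERTY_LINE
_TVA_HIGH_BAND = (1.05 * POVERTY_LINE, 12.0 * POVERTY_LINE)


def _draw_targets(rng: np.random.Generator, stratum: int,
                  kcal_per_ppp_staple: float,
                  kcal_per_ppp_low: float) -> tuple[float, float]:
    """Draw a (fa, tva_per_mae_day) pair inside the stratum's region.

    Feasibility of the quantity back-solve requires
    tva * K_low <= fa <= tva * K_staple, where K_* are the calories
    obtainable per $PPP through each product bucket.
    """
    if stratum in (0, 1):
        fa_lo, fa_hi = _FA_BAND[stratum]
        fa = _trunc_lognormal(rng, _FA_MEDIAN[stratum], 0.35, fa_lo, fa_hi)
        tva_lo = 1.02 * fa / kcal_per_ppp_staple
        tva_hi = min(_TVA_CAP, 0.98 * fa / kcal_per_ppp_low)
        tva = _trunc_lognormal(rng, _TVA_MEDIAN[stratum], 0.45, tva_lo, tva_hi)
    else:
        tva = _trunc_lognormal(rng, _TVA_MEDIAN[2], 0.45, *_TVA_HIGH_BAND)
        fa_lo = 1.02 * tva * kcal_per_ppp_low
        fa_hi = 0.98 * tva * kcal_per_ppp_staple
        fa = _trunc_lognormal(rng, max(_FA_MEDIAN[2], 1.1 * fa_lo), 0.40,
                              fa_lo, fa_hi)
    return fa, tva


def _make_roster(rng: np.random.Generator, size: int) -> list[Member]:
    members = [Member(age=int(rng.integers(25, 66)), sex="M")]
    if size >= 2:
        members.append(Member(age=max(18, members[0].age
                                      - int(rng.integers(0, 8))), sex="F"))
    while len(members) < size:
        members.append(Member(age=int(rng.integers(1, 18)),
                              sex="M" if rng.random() < 0.5 else "F"))
    return members


def _age_roster(roster: list[Member], years: int) -> list[Member]:
    return [Member(age=m.age + years, sex=m.sex) for m in roster]


def _livestock_counts(rng: np.random.Generator, tlu_target: float
                      ) -> dict[str, float]:
    counts: dict[str, float] = {}
    cattle = int(tlu_target)
    if cattle:
        counts["cattle"] = cattle
    goats = round((tlu_target - cattle) / 0.2)
    if goats:
        counts["goat"] = goats
    chickens = int(rng.integers(0, 11))
    if chickens:
        counts["chicken"] = chickens
    return counts


def _split(rng: np.random.Generator, total: float,
           alphas: Sequence[float]) -> np.ndarray:
    if total <= 0:
        return np.zeros(len(alphas))
    return total * rng.dirichlet(alphas)


def _build_rows(rng: np.random.Generator, site: str, rnd: int,
                table: ConversionTable, fa: float, tva: float, mae: float,
                stratum: int) -> tuple[list[ProduceRow], list[ProduceRow], float]:
    """Back-solve product rows and off-farm income from the FA/TVA targets.

    Returns (crop rows, livestock-product rows, off-farm income), all in
    the site's local currency, such that the indicator pipeline computes
    exactly the requested fa (kcal/MAE/day) and tva ($PPP/MAE/day).
    """
    ppp = table.get_ppp(site, rnd)
    pm = table.get_maize_price(site, rnd)        # local / kg
    k_staple = table.maize_energy / pm           # kcal per local unit
    pv = table.price(site, rnd, "vegetable")
    k_low = LOW_CAL_PRODUCTS["vegetable"] / pv

    days = mae * DAYS_PER_YEAR
    total_local = tva * days * ppp               # local currency / yr
    total_kcal = fa * days

    # cash must satisfy: (T - cash)*k_low <= total_kcal - cash*k_staple
    cash_max = (total_kcal - total_local * k_low) / (k_staple - k_low)
    cash_max = min(max(cash_max, 0.0), total_local)
    a, b = _CASH_BETA[stratum]
    cash = min(float(rng.beta(a, b)) * total_local, cash_max)

    consumed_value = total_local - cash
    need_kcal = total_kcal - cash * k_staple
    high_value = (need_kcal - consumed_value * k_low) / (k_staple - k_low)
    high_value = min(max(high_value, 0.0), consumed_value)
    low_value = consumed_value - high_value

    # split buckets into products (equal kcal/value within a bucket)
    staple_vals = _split(rng, high_value, (6.0, 1.5, 1.0))  # maize/beans/sorghum
    low_vals = _split(rng, low_value, (1.5, 1.0))           # vegetable/milk

    a, b = _OFFFARM_BETA[stratum]
    off_farm = float(rng.beta(a, b)) * cash
    sold = cash - off_farm
    sold_vals = _split(rng, sold, (3.0, 1.0, 1.0))  # maize/vegetable/milk

    consumed_by_product = {
        "maize": staple_vals[0], "beans": staple_vals[1],
        "sorghum": staple_vals[2], "vegetable": low_vals[0],
        "milk": low_vals[1],
    }
    sold_by_product = {"maize": sold_vals[0], "vegetable": sold_vals[1],
                       "milk": sold_vals[2]}

    crop_rows, livestock_rows = [], []
    for product in CROP_PRODUCTS + LIVESTOCK_PRODUCTS:
        c_val = consumed_by_product.get(product, 0.0)
        s_val = sold_by_product.get(product, 0.0)
        if c_val <= 0 and s_val <= 0:
            continue
        price = table.price(site, rnd, product)
        consumed_kg = c_val / price
        sold_kg = s_val / price
        row = ProduceRow(product=product, produced=consumed_kg + sold_kg,
                         consumed=consumed_kg, sold=sold_kg,
                         sale_income=s_val if s_val > 0 else None)
        (livestock_rows if product in LIVESTOCK_PRODUCTS
         else crop_rows).append(row)
    return crop_rows, livestock_rows, off_farm


@lru_cache(maxsize=1)
def _scorecard():
    return load_synthetic_scorecard()


def _draw_welfare(rng: np.random.Generator, stratum: int) -> WelfareResponses:
    """Welfare block with stratum-dependent shifts (better in higher strata)."""
    p_affirm = (0.55, 0.35, 0.15)[stratum]
    hfias = {}
    for i in range(1, 10):
        if rng.random() < p_affirm:
            hfias[f"q{i}"] = int(rng.choice([1, 2, 3], p=[0.4, 0.35, 0.25]))
        else:
            hfias[f"q{i}"] = 0
    base = np.array([0.95, 0.60, 0.30, 0.40, 0.30,
                     0.25, 0.70, 0.40, 0.35, 0.50])
    shift = 0.12 * (stratum - 1)
    p_flush = np.clip(base + shift, 0.02, 0.98)
    p_lean = np.clip(0.7 * base + shift, 0.02, 0.98)
    hdds_flush = {g: bool(rng.random() < p)
                  for g, p in zip(DEFAULT_FOOD_GROUPS, p_flush)}
    hdds_lean = {g: bool(rng.random() < p)
                 for g, p in zip(DEFAULT_FOOD_GROUPS, p_lean)}
    scorecard = _scorecard()
    p_opt = (0.25, 0.50, 0.75)[stratum]
    ppi = {qid: int(rng.binomial(len(opts) - 1, p_opt))
           for qid, opts in scorecard.questions.items()}
    lam = (4.0, 2.5, 1.0)[stratum]
    months = int(min(rng.poisson(lam), 12))
    return WelfareResponses(hfias=hfias, hdds_flush=hdds_flush,
                            hdds_lean=hdds_lean, ppi_answers=ppi,
                            months_food_shortage=months)


def generate_panel(sites: Sequence[SiteConfig] = DEFAULT_SITES,
                   design: TrajectoryDesign = DEFAULT_DESIGN,
                   seed: int = 0,
                   ) -> tuple[list[HouseholdRecord], list[HouseholdRecord],
                              ConversionTable]:
    """Generate linked round-1 and round-2 household collections.

    Round-2 households are a simple random subsample of round-1
    households of size round(retention x n1) per site.  Latent strata
    are drawn from the design (round 1 i.i.d. from the target
    proportions, round 2 from the transition row of the round-1
    stratum); observables are constructed so the indicator pipeline
    recovers the latent stratum.  One pseudo-random stream per site is
    split from the master seed, so adding a site does not perturb the
    draws of the others.  Welfare responses are generated for round 2
    only, with stratum-dependent shifts.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("need at least one site")
    table = generate_price_table(sites, seed)
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(sites))

    round1: list[HouseholdRecord] = []
    round2: list[HouseholdRecord] = []
    props = design.proportions
    matrix = design.matrix

    for site, stream in zip(sites, streams):
        rng = np.random.default_rng(stream)
        name = site.price_site
        lo, hi = site.household_size_range
        land_mu, land_sigma = site.land_lognormal
        tlu_mu, tlu_sigma = site.tlu_lognormal

        site_records: list[tuple[HouseholdRecord, HouseholdRecord]] = []
        for i in range(site.n_households):
            village = i // site.households_per_village + 1
            hh = i % site.households_per_village + 1
            hid = f"{site.site_name}-v{village:02d}-h{hh:02d}"
            s1 = int(rng.choice(3, p=props))
            s2 = int(rng.choice(3, p=matrix[s1]))

            size = int(rng.integers(lo, hi + 1))
            roster1 = _make_roster(rng, size)
            roster2 = _age_roster(roster1, 4)
            if rng.random() < 0.3:
                roster2 = roster2 + [Member(age=int(rng.integers(0, 4)),
                                            sex="M" if rng.random() < 0.5
                                            else "F")]
            base_land = float(rng.lognormal(land_mu, land_sigma))
            base_tlu = float(rng.lognormal(tlu_mu, tlu_sigma))
            education = EDUCATION_LEVELS[int(rng.choice(4, p=_EDU_PROBS[s1]))]

            recs = []
            for rnd, stratum, roster in ((1, s1, roster1), (2, s2, roster2)):
                mae = compute_mae(roster, table)
                pm = table.get_maize_price(name, rnd)
                ppp = table.get_ppp(name, rnd)
                k_staple_ppp = table.maize_energy / (pm / ppp)
                pv = table.price(name, rnd, "vegetable")
                k_low_ppp = LOW_CAL_PRODUCTS["vegetable"] / (pv / ppp)
                fa, tva = _draw_targets(rng, stratum, k_staple_ppp, k_low_ppp)
                crop_rows, ls_rows, off_farm = _build_rows(
                    rng, name, rnd, table, fa, tva, mae, stratum)
                land = base_land * _LAND_MULT[stratum] * float(
                    rng.lognormal(0, 0.10))
                tlu_t = base_tlu * _TLU_MULT[stratum] * float(
                    rng.lognormal(0, 0.15))
                welfare = (_draw_welfare(rng, stratum) if rnd == 2
                           else WelfareResponses())
                recs.append(HouseholdRecord(
                    household_id=hid, site=name, round=rnd, roster=roster,
                    land_cultivated=land,
                    livestock_counts=_livestock_counts(rng, tlu_t),
                    crop_rows=crop_rows, livestock_product_rows=ls_rows,
                    off_farm_income=off_farm, education=education,
                    welfare=welfare,
                ))
            site_records.append((recs[0], recs[1]))

        round1.extend(r1 for r1, _ in site_records)
        keep = rng.choice(len(site_records), size=site.n_resurveyed,
                          replace=False)
        for idx in sorted(keep):
            round2.append(site_records[idx][1])
    return round1, round2, table


# ---------------------------------------------------------------------------
# Design file round-trip
# ---------------------------------------------------------------------------

def design_to_yaml(sites: Sequence[SiteConfig], design: TrajectoryDesign,
                   path) -> None:
    doc = {
        "sites": [
            {
                "site_name": s.site_name,
                "n_villages": s.n_villages,
                "households_per_village": s.households_per_village,
                "retention_fraction": s.retention_fraction,
                "land_lognormal": list(s.land_lognormal),
                "tlu_lognormal": list(s.tlu_lognormal),
                "household_size_range": list(s.household_size_range),
                "price_ref": s.price_ref,
            }
            for s in sites
        ],
        "design": {
            "target_first_round_proportions":
                list(design.target_first_round_proportions),
            "transition_matrix": [list(r) for r in design.transition_matrix],
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def design_from_yaml(path) -> tuple[list[SiteConfig], TrajectoryDesign]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    sites = [
        SiteConfig(
            site_name=s["site_name"],
            n_villages=int(s.get("n_villages", 7)),
            households_per_village=int(s.get("households_per_village", 20)),
            retention_fraction=float(s["retention_fraction"]),
            land_lognormal=tuple(s.get("land_lognormal",
                                       (math.log(1.5), 0.6))),
            tlu_lognormal=tuple(s.get("tlu_lognormal", (math.log(2.0), 0.8))),
            household_size_range=tuple(s.get("household_size_range", (3, 8))),
            price_ref=s.get("price_ref"),
        )
        for s in doc["sites"]
    ]
    d = doc["design"]
    design = TrajectoryDesign(
        target_first_round_proportions=tuple(
            d["target_first_round_proportions"]),
        transition_matrix=tuple(tuple(r) for r in d["transition_matrix"]),
    )
    return sites, design
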