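"""Site-level conversion data: prices, PPP factors, TLU weights, MAE factors.

The conversion table carries everything needed to turn raw survey
quantities into comparable indicators:

* local market prices per product, site and panel round (currency/kg);
* the staple (maize) price and energy density used to express cash as
  calorie equivalents;
* purchasing-power-parity factors (local currency per international $);
* tropical livestock unit weights per species (1 TLU = one 250 kg cow =
  five goats);
* male-adult-equivalent factors per age band and sex.

The default MAE factor table and maize energy density (3580 kcal/kg) are
shipped as documented, overridable configuration: they follow standard
energy-requirement scales rather than any single published table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = [
    "MAEBand",
    "ConversionTable",
    "DEFAULT_TLU_WEIGHTS",
    "DEFAULT_MAE_FACTORS",
    "DEFAULT_MAIZE_ENERGY",
]

#: kcal per kg of dry maize grain (overridable).
DEFAULT_MAIZE_ENERGY = 3580.0

#: TLU per head.  Cattle and small ruminants follow the 250 kg-cow /
#: five-goats equivalence; the remaining species use standard reference
#: weights for tropical herds.
DEFAULT_TLU_WEIGHTS: dict[str, float] = {
    "cattle": 1.0,
    "goat": 0.2,
    "sheep": 0.2,
    "pig": 0.3,
    "donkey": 0.5,
    "chicken": 0.01,
    "duck": 0.01,
}


@dataclass(frozen=True)
class MAEBand:
    """One row of the MAE factor table: [age_min, age_max] x sex -> factor.

    ``sex`` of None applies to both sexes.  Factors express calorie demand
    relative to an adult male (factor 1.0).
    """

    age_min: float
    age_max: float
    sex: Optional[str]
    factor: float


#: Calorie-demand factors relative to an adult male, by age band and sex.
DEFAULT_MAE_FACTORS: tuple[MAEBand, ...] = (
    MAEBand(0, 3, None, 0.30),
    MAEBand(4, 9, None, 0.60),
    MAEBand(10, 17, "M", 0.90),
    MAEBand(10, 17, "F", 0.80),
    MAEBand(18, 59, "M", 1.00),
    MAEBand(18, 59, "F", 0.80),
    MAEBand(60, 200, "M", 0.80),
    MAEBand(60, 200, "F", 0.65),
)


@dataclass
class ConversionTable:
    """Prices and conversion factors keyed by site and panel round."""

    prices: dict[tuple[str, int, str], float] = field(default_factory=dict)
    maize_price: dict[tuple[str, int], float] = field(default_factory=dict)
    ppp_factor: dict[tuple[str, int], float] = field(default_factory=dict)
    maize_energy: float = DEFAULT_MAIZE_ENERGY
    tlu_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TLU_WEIGHTS)
    )
    mae_factors: tuple[MAEBand, ...] = DEFAULT_MAE_FACTORS
    #: Optional per-product energy densities (kcal/kg).  Products absent
    #: from this table have their consumed value converted to calories via
    #: the maize price, the same route used for cash.
    kcal_per_kg: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        bad = [k for k, v in self.prices.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive prices for {bad[:5]}")
        if any(v <= 0 for v in self.maize_price.values()):
            raise ValueError("maize prices must be > 0")
        if any(v <= 0 for v in self.ppp_factor.values()):
            raise ValueError("PPP factors must be > 0")
        if self.maize_energy <= 0:
            raise ValueError("maize energy density must be > 0")
        if any(w <= 0 for w in self.tlu_weights.values()):
            raise ValueError("TLU weights must be > 0")

    # -- lookups ---------------------------------------------------------

    def price(self, site: str, round: int, product: str) -> float:
        try:
            return self.prices[(site, round, product)]
        except KeyError:
            raise KeyError(
                f"no price for product {product!r} at site {site!r}, round {round}"
            ) from None

    def get_maize_price(self, site: str, round: int) -> float:
        try:
            return self.maize_price[(site, round)]
        except KeyError:
            raise KeyError(f"no maize price for site {site!r}, round {round}") from None

    def get_ppp(self, site: str, round: int) -> float:
        try:
            return self.ppp_factor[(site, round)]
        except KeyError:
            raise KeyError(f"no PPP factor for site {site!r}, round {round}") from None

    def mae_factor(self, age: float, sex: str) -> float:
        """Calorie-demand factor for one member; raises on negative age."""
        if age < 0:
            raise ValueError(f"negative age {age}")
        for band in self.mae_factors:
            if band.age_min <= age <= band.age_max and band.sex in (None, sex):
                return band.factor
        raise KeyError(f"no MAE factor band covers age={age}, sex={sex}")

    def energy_density(self, product: str) -> Optional[float]:
        """kcal/kg for a product, or None if it has no direct energy entry.

        Maize always resolves to ``maize_energy`` so that the calorie
        content of consumed maize is exactly consumed kg x maize_energy.
        """
        if product == "maize":
            return self.maize_energy
        if self.kcal_per_kg is not None:
            return self.kcal_per_kg.get(product)
        return None

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "maize_energy": self.maize_energy,
            "tlu_weights": dict(self.tlu_weights),
            "mae_factors": [
                {"age_min": b.age_min, "age_max": b.age_max, "sex": b.sex,
                 "factor": b.factor}
                for b in self.mae_factors
            ],
            "kcal_per_kg": dict(self.kcal_per_kg) if self.kcal_per_kg else None,
            "prices": [
                {"site": s, "round": r, "product": p, "price": v}
                for (s, r, p), v in sorted(self.prices.items())
            ],
            "maize_price": [
                {"site": s, "round": r, "price": v}
                for (s, r), v in sorted(self.maize_price.items())
            ],
            "ppp_factor": [
                {"site": s, "round": r, "factor": v}
                for (s, r), v in sorted(self.ppp_factor.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConversionTable":
        return cls(
            prices={
                (e["site"], int(e["round"]), e["product"]): float(e["price"])
                for e in d.get("prices", [])
            },
            maize_price={
                (e["site"], int(e["round"])): float(e["price"])
                for e in d.get("maize_price", [])
            },
            ppp_factor={
                (e["site"], int(e["round"])): float(e["factor"])
                for e in d.get("ppp_factor", [])
            },
            maize_energy=float(d.get("maize_energy", DEFAULT_MAIZE_ENERGY)),
            tlu_weights=dict(d.get("tlu_weights") or DEFAULT_TLU_WEIGHTS),
            mae_factors=tuple(
                MAEBand(b["age_min"], b["age_max"], b["sex"], b["factor"])
                for b in d.get("mae_factors", [])
            ) or DEFAULT_MAE_FACTORS,
            kcal_per_kg=dict(d["kcal_per_kg"]) if d.get("kcal_per_kg") else None,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ConversionTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
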