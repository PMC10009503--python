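"""Core data model: one household in one panel round.

A household record holds everything the survey captured for a single
household in a single round: the member roster, land cultivated, a
livestock inventory by species, long-format crop and livestock-product
rows (quantities produced / consumed / sold plus reported sale income),
off-farm income, and the welfare-question block (round 2 only in the
emulated study design).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Member",
    "ProduceRow",
    "WelfareResponses",
    "HouseholdRecord",
    "RecordError",
    "PRODUCTION_TOLERANCE",
]

#: Relative tolerance for the consistency check consumed + sold <= produced.
#: Survey quantities are recall-based; small overshoots are accepted.
PRODUCTION_TOLERANCE = 0.05

EDUCATION_LEVELS = ["none", "primary", "secondary", "post-secondary"]


@dataclass(frozen=True)
class Member:
    """One household member: age in years and sex ('M' or 'F')."""

    age: float
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass
class ProduceRow:
    """One crop or livestock product over the 12-month recall period.

    Quantities are kg; ``sale_income`` is in local currency.  A missing
    (None) sale income means the sold quantity is valued at the local
    market price instead.
    """

    product: str
    produced: float = 0.0
    consumed: float = 0.0
    sold: float = 0.0
    sale_income: Optional[float] = None

    def check(self, tolerance: float = PRODUCTION_TOLERANCE) -> Optional[str]:
        """Return an error message if the row violates its invariants, else None."""
        for name in ("produced", "consumed", "sold"):
            if getattr(self, name) < 0:
                return f"{self.product}: negative {name}"
        if self.sale_income is not None and self.sale_income < 0:
            return f"{self.product}: negative sale_income"
        allowance = self.produced * (1.0 + tolerance)
        if self.consumed + self.sold > allowance + 1e-9:
            return (
                f"{self.product}: consumed+sold ({self.consumed + self.sold:g}) "
                f"exceeds produced ({self.produced:g}) by more than "
                f"{tolerance:.0%}"
            )
        return None


@dataclass
class WelfareResponses:
    """Welfare-question block (HFIAS items, food-group checklists, PPI, hungry months).

    Any component may be None, meaning the instrument was not administered
    (the first panel round in the emulated design); scoring functions treat
    None as missing, not zero.
    """

    hfias: Optional[dict[str, int]] = None            # "q1".."q9" -> 0..3
    hdds_flush: Optional[dict[str, bool]] = None      # food group -> consumed?
    hdds_lean: Optional[dict[str, bool]] = None
    ppi_answers: Optional[dict[str, int]] = None      # question id -> option index
    months_food_shortage: Optional[int] = None        # 0..12


@dataclass
class HouseholdRecord:
    household_id: str
    site: str
    round: int
    roster: list[Member]
    land_cultivated: float = 0.0                      # ha
    livestock_counts: dict[str, float] = field(default_factory=dict)
    crop_rows: list[ProduceRow] = field(default_factory=list)
    livestock_product_rows: list[ProduceRow] = field(default_factory=list)
    off_farm_income: float = 0.0                      # local currency / yr
    education: Optional[str] = None                   # ordered attainment level
    welfare: WelfareResponses = field(default_factory=WelfareResponses)

    def check(self, tolerance: float = PRODUCTION_TOLERANCE) -> list[str]:
        """Validate the record's invariants; return a list of error messages."""
        errors: list[str] = []
        if self.round not in (1, 2):
            errors.append(f"round must be 1 or 2, got {self.round}")
        if not self.roster:
            errors.append("roster is empty")
        for m in self.roster:
            if m.age < 0:
                errors.append(f"negative member age {m.age}")
        if self.land_cultivated < 0:
            errors.append("negative land_cultivated")
        if self.off_farm_income < 0:
            errors.append("negative off_farm_income")
        for species, count in self.livestock_counts.items():
            if count < 0:
                errors.append(f"negative livestock count for {species}")
        for row in list(self.crop_rows) + list(self.livestock_product_rows):
            msg = row.check(tolerance)
            if msg is not None:
                errors.append(msg)
        return errors

    def copy(self) -> "HouseholdRecord":
        return replace(
            self,
            roster=list(self.roster),
            livestock_counts=dict(self.livestock_counts),
            crop_rows=[replace(r) for r in self.crop_rows],
            livestock_product_rows=[replace(r) for r in self.livestock_product_rows],
            welfare=replace(self.welfare),
        )


@dataclass
class RecordError:
    """A per-row validation failure attributed to a household."""

    household_id: str
    round: int
    message: str
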