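import math

import pytest

from povdyn import (ConversionTable, HouseholdRecord, Member, ProduceRow,
                    SiteConfig, generate_panel)
from povdyn.conversions import MAEBand
from povdyn.synthetic import DEFAULT_DESIGN


@pytest.fixture(scope="session")
def simple_table():
    """Hand-built conversion table for arithmetic-by-hand tests.

    Site "X", both rounds: PPP factor 1 (values already in $), maize at
    0.5/kg, vegetables at 2.0/kg (no direct energy entry, so consumed
    vegetables convert via the maize route), milk at 1.0/kg.
    """
    prices = {}
    maize_price = {}
    ppp = {}
    for rnd in (1, 2):
        prices[("X", rnd, "maize")] = 0.5
        prices[("X", rnd, "vegetable")] = 2.0
        prices[("X", rnd, "milk")] = 1.0
        maize_price[("X", rnd)] = 0.5
        ppp[("X", rnd)] = 1.0
    return ConversionTable(prices=prices, maize_price=maize_price,
                           ppp_factor=ppp)


@pytest.fixture(scope="session")
def half_factor_table(simple_table):
    """Conversion table whose MAE bands include a 0.5-factor child band."""
    factors = (
        MAEBand(0, 17, None, 0.5),
        MAEBand(18, 200, "M", 1.0),
        MAEBand(18, 200, "F", 0.8),
    )
    return ConversionTable(prices=dict(simple_table.prices),
                           maize_price=dict(simple_table.maize_price),
                           ppp_factor=dict(simple_table.ppp_factor),
                           mae_factors=factors)


@pytest.fixture
def basic_record():
    """A plain two-adult household growing maize on site X."""
    return HouseholdRecord(
        household_id="hh-1", site="X", round=1,
        roster=[Member(age=35, sex="M"), Member(age=30, sex="F")],
        land_cultivated=2.0,
        livestock_counts={"goat": 5},
        crop_rows=[ProduceRow("maize", produced=600, consumed=500, sold=100,
                              sale_income=50.0)],
        off_farm_income=100.0,
    )


@pytest.fixture(scope="session")
def small_panel():
    """One small site, generated once per session (fast downstream tests)."""
    sites = [SiteConfig("mini", n_villages=3, households_per_village=15,
                        retention_fraction=0.8)]
    return generate_panel(sites, DEFAULT_DESIGN, seed=11)


@pytest.fixture(scope="session")
def default_panel():
    """The default four-site design (560 round-1 households), seed 5."""
    return generate_panel(seed=5)


def records_close(a: HouseholdRecord, b: HouseholdRecord,
                  tol: float = 1e-9) -> bool:
    """Field-level equality with tolerance on reals (round-trip checks)."""
    if (a.household_id, a.site, a.round, a.education) != \
            (b.household_id, b.site, b.round, b.education):
        return False
    if len(a.roster) != len(b.roster):
        return False
    for m1, m2 in zip(a.roster, b.roster):
        if m1.sex != m2.sex or not math.isclose(m1.age, m2.age, abs_tol=tol):
            return False
    if not math.isclose(a.land_cultivated, b.land_cultivated, rel_tol=tol):
        return False
    if not math.isclose(a.off_farm_income, b.off_farm_income, rel_tol=tol):
        return False
    if set(a.livestock_counts) != set(b.livestock_counts):
        return False
    for k in a.livestock_counts:
        if not math.isclose(a.livestock_counts[k], b.livestock_counts[k],
                            rel_tol=tol):
            return False
    for rows_a, rows_b in ((a.crop_rows, b.crop_rows),
                           (a.livestock_product_rows,
                            b.livestock_product_rows)):
        if len(rows_a) != len(rows_b):
            return False
        for r1, r2 in zip(sorted(rows_a, key=lambda r: r.product),
                          sorted(rows_b, key=lambda r: r.product)):
            if r1.product != r2.product:
                return False
            for f in ("produced", "consumed", "sold"):
                if not math.isclose(getattr(r1, f), getattr(r2, f),
                                    rel_tol=tol, abs_tol=tol):
                    return False
            if (r1.sale_income is None) != (r2.sale_income is None):
                return False
            if r1.sale_income is not None and not math.isclose(
                    r1.sale_income, r2.sale_income, rel_tol=tol, abs_tol=tol):
                return False
    wa, wb = a.welfare, b.welfare
    if (wa.hfias, wa.hdds_flush, wa.hdds_lean, wa.ppi_answers,
            wa.months_food_shortage) != \
            (wb.hfias, wb.hdds_flush, wb.hdds_lean, wb.ppi_answers,
             wb.months_food_shortage):
        return False
    return True
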