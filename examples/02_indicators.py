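"""Compute per-household indicators: MAE, TLU, TVA and Food Availability.

Food Availability (FA) expresses everything the household produced or
earned as calories per male adult equivalent per day: consumed produce
counts its calories directly, and cash income (sales + off-farm)
converts to calories at the local staple (maize) price.  The Total
Value of Activities (TVA) is the $PPP/yr value of all produce consumed
and sold plus off-farm income.
"""

from povdyn import (ConversionTable, HouseholdRecord, Member, ProduceRow,
                    compute_indicators)

# a two-adult, two-child household growing maize and vegetables
table = ConversionTable(
    prices={("demo", 1, "maize"): 0.5, ("demo", 1, "vegetable"): 2.0},
    maize_price={("demo", 1): 0.5},      # local currency per kg
    ppp_factor={("demo", 1): 1.0},       # values already in $PPP
)
household = HouseholdRecord(
    household_id="demo-1", site="demo", round=1,
    roster=[Member(38, "M"), Member(35, "F"), Member(9, "F"), Member(6, "M")],
    land_cultivated=1.5,
    livestock_counts={"cattle": 1, "goat": 5, "chicken": 4},
    crop_rows=[
        ProduceRow("maize", produced=900, consumed=700, sold=200,
                   sale_income=95.0),
        ProduceRow("vegetable", produced=120, consumed=40, sold=80,
                   sale_income=170.0),
    ],
    off_farm_income=260.0,
)

ind = compute_indicators(household, table)
print(f"MAE (male adult equivalents): {ind.mae:.2f}")
print(f"TLU (tropical livestock units): {ind.tlu:.2f}")
print(f"TVA: {ind.tva:.0f} $PPP/yr  "
      f"({ind.tva_per_mae_day:.2f} $PPP/MAE/day vs the $1.90 line)")
print(f"FA: {ind.fa:.0f} kcal/MAE/day vs the 3000 kcal line")
print(f"crop intensity: {ind.crop_intensity:.0f} $PPP/ha/yr, "
      f"livestock intensity: {ind.livestock_intensity:.0f} $PPP/TLU/yr, "
      f"off-farm intensity: {ind.offfarm_intensity:.0f} $PPP/MAE/yr")

# The 1 cow + 5 goats + 4 chickens herd is 1.0 + 1.0 + 0.04 = 2.04 TLU;
# an FA below 3000 with a TVA below 1.90 would place this household in
# the Low stratum, FA above 3000 in Medium, TVA above 1.90 in High.
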