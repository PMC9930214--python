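"""Costing primitives and the trial sample-size formula.

Shows the wage-based lost-productivity rule, the ten-year medication
present value, rial/dollar conversion, and both variants of the
net-monetary-benefit sample-size calculation.
"""

from cardiocea import SampleSizeInputs, sample_size
from cardiocea.costing import lost_productivity, medication_present_value, rial_to_usd

days = 8.05  # average CABG hospitalization, days
print(f"lost productivity for {days} days: "
      f"${lost_productivity(days):.2f}  (= days x $311 / 26 working days)")

six_month_drug = 34.95  # per-capita CABG medication bill, USD
pv = medication_present_value(six_month_drug, rate=0.03, years=10)
print(f"10-year medication present value of a ${six_month_drug} six-month bill: "
      f"${pv:.2f}  (annual = 2x bill, 3% annuity)")

print(f"1,000,000 rials = ${rial_to_usd(1_000_000):.2f} (2014 rate: 26,509 IRR/USD)")

inputs = SampleSizeInputs()  # the study's design values
print(f"\nsample size per group, squared z-term: {sample_size(inputs, 'squared')}")
print(f"sample size per group, linear z-term:  {sample_size(inputs, 'linear')}")
# The squared variant (the conventional NMB formula) gives 201/group,
# consistent with the study's recruitment of 215 per arm; the formula as
# printed (linear z-sum) would give only 69.
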