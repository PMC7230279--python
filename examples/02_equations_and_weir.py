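"""Reduce gas exchange to measured REE and compare the five equations.

For one 13-year-old boy: the modified Weir formula turns VO2/VCO2 into
kcal/day, and each classical equation predicts REE from weight/height/age.
"""

from pedree import predict_all, respiratory_quotient, weir_ree

vo2, vco2 = 0.20, 0.17          # L/min, a typical steady-state reading
ree = weir_ree(vo2, vco2)
print(f"RQ  = {respiratory_quotient(vo2, vco2):.2f}")
print(f"REE = {ree:.1f} kcal/day (modified Weir, no urinary nitrogen term)")

preds = predict_all(sex="M", age=13.0, weight=62.8, height=156.5)
for eq, value in preds.items():
    print(f"{eq:16s} {value:7.1f} kcal/day  (error {value - ree:+6.1f})")

# Every equation overshoots this child's measured 1405.8 kcal/day by
# 150-350 kcal/day - the individual-level disagreement that motivates a
# nonlinear model.
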