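"""Generate a synthetic pediatric cohort and inspect its marginals.

The generator emulates a mixed healthy 2-17-year population (about
two-thirds boys, a fifth obese) with gas-exchange values that are exactly
Weir-consistent with each child's measured REE.
"""

from pedree import CohortConfig, generate_cohort
from pedree.synthetic import cohort_to_frame

cohort = generate_cohort(CohortConfig(n=561, seed=1))
df = cohort_to_frame(cohort)

print(f"n = {len(df)}, males = {(df.sex == 'M').mean():.1%}")
for col in ("age", "weight_kg", "height_cm", "ree_kcal_d"):
    print(f"{col:12s} mean {df[col].mean():8.1f}  sd {df[col].std():6.1f}")

# The means sit near the emulated population profile (age ~13 y,
# weight ~63 kg, height ~156 cm, REE ~1418 kcal/day); REE noise SD is
# 90 kcal/day, which bounds how well any model can predict individuals.
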