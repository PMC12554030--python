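"""Score epidemiological dementia risk profiles with the CAIDE point table.

CAIDE sums integer points over age, education, sex, systolic blood
pressure, BMI, total cholesterol and physical inactivity; higher = more
midlife dementia risk factors.
"""

import pandas as pd

from memoscore.caide import CaidePointTable, caide_score

profiles = pd.DataFrame([
    # a low-risk and a high-risk profile
    dict(age_at_test=45, sex="female", education=14, sbp=118, bmi=23,
         total_chol=4.8, inactive=False),
    dict(age_at_test=62, sex="male", education=6, sbp=155, bmi=31,
         total_chol=7.1, inactive=True),
    dict(age_at_test=55, sex="female", education=8, sbp=145, bmi=28,
         total_chol=6.0, inactive=False),
])

table = CaidePointTable()
scores = caide_score(profiles, table)
for (_, row), s in zip(profiles.iterrows(), scores):
    print(f"age {row.age_at_test:>2.0f}, {row.sex:>6}, edu {row.education:>2.0f}y, "
          f"SBP {row.sbp:.0f}, BMI {row.bmi:.0f}, chol {row.total_chol:.1f}, "
          f"inactive={row.inactive!s:>5}  ->  CAIDE = {s:>2d} / {table.max_score}")
# 0 = no risk factors; 15 = every component past its cutoff.
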