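"""CAIDE dementia risk score from seven epidemiological components.

The CAIDE (Cardiovascular Risk Factors, Aging, and Incidence of Dementia)
score sums integer points for age, education, sex, systolic blood pressure,
body-mass index, total cholesterol, and physical inactivity.  The default
point table is the original midlife model without APOE: age > 53 -> 4 points,
47-53 -> 3; education < 7 years -> 3, 7-9 -> 2; male sex -> 1; SBP
> 140 mmHg -> 2; BMI > 30 kg/m^2 -> 2; total cholesterol > 6.5 mmol/L -> 2;
physically inactive -> 1.  Maximum 15.  The table is configuration, not a
constant: cutoffs and points load from YAML so cohort-specific variants can
be swapped in.  Thresholds for SBP/BMI/cholesterol are strict (">"), as
printed in the source model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

#: CohortTable columns the score needs
CAIDE_COMPONENTS = ["age_at_test", "sex", "education", "sbp", "bmi",
                    "total_chol", "inactive"]


class MissingComponentError(ValueError):
    """A CAIDE component is absent or NaN for some sample."""


@dataclass
class CaidePointTable:
    """Cutoffs (strict '>' for continuous components, '<'/range for education)."""

    age_cuts: tuple = (47.0, 53.0)          # <=c0 -> 0, (c0, c1] -> mid, > c1 -> high
    age_points: tuple = (0, 3, 4)
    education_cuts: tuple = (7.0, 9.0)      # < c0 -> high, [c0, c1] -> mid, > c1 -> 0
    education_points: tuple = (0, 2, 3)
    sex_points: dict = field(default_factory=lambda: {"female": 0, "male": 1})
    sbp_cut: float = 140.0
    sbp_points: tuple = (0, 2)
    bmi_cut: float = 30.0
    bmi_points: tuple = (0, 2)
    chol_cut: float = 6.5
    chol_points: tuple = (0, 2)
    inactivity_points: tuple = (0, 1)

    @property
    def max_score(self) -> int:
        return (max(self.age_points) + max(self.education_points)
                + max(self.sex_points.values()) + max(self.sbp_points)
                + max(self.bmi_points) + max(self.chol_points)
                + max(self.inactivity_points))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "CaidePointTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("age_cuts", "age_points", "education_cuts", "education_points",
                    "sbp_points", "bmi_points", "chol_points", "inactivity_points"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def caide_score(cohort: pd.DataFrame, table: CaidePointTable | None = None) -> np.ndarray:
    """Integer CAIDE score per row of a cohort table.

    Raises :class:`MissingComponentError` naming the first offending field if
    any of the seven components is missing — no silent imputation.
    """
    table = table or CaidePointTable()
    for col in CAIDE_COMPONENTS:
        if col not in cohort.columns:
            raise MissingComponentError(f"CAIDE component column missing: {col}")
        if cohort[col].isna().any():
            raise MissingComponentError(f"CAIDE component has missing values: {col}")

    age = cohort["age_at_test"].to_numpy(float)
    edu = cohort["education"].to_numpy(float)
    sbp = cohort["sbp"].to_numpy(float)
    bmi = cohort["bmi"].to_numpy(float)
    chol = cohort["total_chol"].to_numpy(float)
    inactive = cohort["inactive"].to_numpy()
    sex = cohort["sex"].astype(str).str.lower().to_numpy()
    bad_sex = ~np.isin(sex, list(table.sex_points))
    if bad_sex.any():
        raise MissingComponentError(
            f"unrecognized sex value(s): {sorted(set(sex[bad_sex]))}"
        )

    pts = np.zeros(len(cohort), dtype=int)
    a0, a1 = table.age_cuts
    pts += np.select([age > a1, age > a0], [table.age_points[2], table.age_points[1]],
                     table.age_points[0])
    e0, e1 = table.education_cuts
    pts += np.select([edu < e0, edu <= e1],
                     [table.education_points[2], table.education_points[1]],
                     table.education_points[0])
    pts += np.vectorize(table.sex_points.get)(sex)
    pts += np.where(sbp > table.sbp_cut, table.sbp_points[1], table.sbp_points[0])
    pts += np.where(bmi > table.bmi_cut, table.bmi_points[1], table.bmi_points[0])
    pts += np.where(chol > table.chol_cut, table.chol_points[1], table.chol_points[0])
    pts += np.where(inactive.astype(bool), table.inactivity_points[1],
                    table.inactivity_points[0])
    return pts


def add_caide(cohort: pd.DataFrame, table: CaidePointTable | None = None) -> pd.DataFrame:
    """Return a copy of the cohort table with a ``caide`` integer column."""
    out = cohort.copy()
    out["caide"] = caide_score(cohort, table)
    return out
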