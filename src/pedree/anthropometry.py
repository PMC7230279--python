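"""BMI, LMS growth z-scores, upper-arm composition and nutritional status.

The upper-arm areas follow the classical circumference/skinfold derivation
(Frisancho): with arm circumference C in cm and triceps skinfold T in cm,

    TUA = C² / 4π             total upper-arm area
    UME = (C − πT)² / 4π      upper-arm muscle area estimate
    UFE = TUA − UME           upper-arm fat area estimate
    arm fat % = 100 · UFE / TUA

Skinfolds are *stored* in mm throughout the package and converted to cm
inside :func:`arm_composition`.

Growth z-scores use the LMS method: z = ((x/M)^L − 1) / (L·S), with the
log-limit form for L = 0. Reference tables (WHO-style ``sex,age_months,L,M,S``
CSV) are pluggable inputs; a smooth synthetic reference ships with the
package for self-contained runs (see :mod:`pedree.synthetic`).

Nutritional status follows the WHO convention: obese at z ≥ +2 SDS, wasted
at z < −2 SDS; BMI-for-age is the classifying index from age 5 years,
weight-for-length below 5 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, OutOfReferenceError

#: The thirteen modelling variables, in canonical order.
FEATURE_NAMES = [
    "age", "female", "male", "weight", "height", "bmi", "arm_circumference",
    "biceps_sf", "triceps_sf", "tua", "ume", "ufe", "arm_fat_pct",
]


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m², from weight (kg) and height (cm)."""
    if weight <= 0 or height <= 0:
        raise InvalidMeasurementError(
            f"weight and height must be positive, got {weight}, {height}"
        )
    return weight / (height / 100.0) ** 2


def arm_composition(
    arm_circumference: float, triceps_sf: float
) -> tuple[float, float, float, float]:
    """(TUA, UME, UFE, arm fat %) from circumference (cm) and triceps (mm)."""
    if arm_circumference <= 0:
        raise InvalidMeasurementError(
            f"arm circumference must be positive, got {arm_circumference}"
        )
    if triceps_sf < 0:
        raise InvalidMeasurementError(f"negative skinfold {triceps_sf}")
    t_cm = triceps_sf / 10.0
    muscle_circ = arm_circumference - math.pi * t_cm
    if muscle_circ <= 0:
        raise InvalidMeasurementError(
            f"triceps skinfold {triceps_sf} mm infeasible for "
            f"circumference {arm_circumference} cm"
        )
    tua = arm_circumference**2 / (4.0 * math.pi)
    ume = muscle_circ**2 / (4.0 * math.pi)
    ufe = tua - ume
    return tua, ume, ufe, 100.0 * ufe / tua


def lms_zscore(value: float, L: float, M: float, S: float) -> float:
    """LMS z-score of ``value`` against (L, M, S); log form when L = 0."""
    if M <= 0 or S <= 0:
        raise InvalidMeasurementError(f"M and S must be positive, got {M}, {S}")
    if value <= 0:
        raise InvalidMeasurementError(f"value must be positive, got {value}")
    if L == 0.0:
        return math.log(value / M) / S
    return ((value / M) ** L - 1.0) / (L * S)


def lms_value(z: float, L: float, M: float, S: float) -> float:
    """Inverse of :func:`lms_zscore`: the measurement at a given z."""
    if L == 0.0:
        return M * math.exp(S * z)
    return M * (1.0 + L * S * z) ** (1.0 / L)


@dataclass
class LmsReference:
    """An LMS growth-reference table for one index (e.g. BMI-for-age).

    ``table`` has columns ``sex`` (M/F), ``x`` (age in months for *-for-age
    references, length in cm for weight-for-length) and ``L``, ``M``, ``S``.
    L/M/S are linearly interpolated in ``x`` within each sex.
    """

    table: pd.DataFrame
    index_name: str = "bmi_for_age"

    def __post_init__(self) -> None:
        required = {"sex", "x", "L", "M", "S"}
        missing = required - set(self.table.columns)
        if missing:
            raise OutOfReferenceError(f"reference table missing columns {missing}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise OutOfReferenceError("M and S must be positive throughout")
        for _, g in self.table.groupby("sex"):
            if not g["x"].is_monotonic_increasing or g["x"].duplicated().any():
                raise OutOfReferenceError("x must be strictly increasing per sex")

    @classmethod
    def from_csv(cls, path: str | Path, index_name: str = "bmi_for_age") -> "LmsReference":
        df = pd.read_csv(path)
        if "age_months" in df.columns:
            df = df.rename(columns={"age_months": "x"})
        return cls(df, index_name)

    def to_csv(self, path: str | Path) -> None:
        out = self.table.rename(columns={"x": "age_months"})
        out.to_csv(path, index=False)

    def lms_at(self, sex: str, x: float) -> tuple[float, float, float]:
        g = self.table[self.table["sex"] == sex]
        if g.empty:
            raise OutOfReferenceError(f"no reference rows for sex {sex!r}")
        xs = g["x"].to_numpy()
        if x < xs[0] or x > xs[-1]:
            raise OutOfReferenceError(
                f"{self.index_name}: x={x} outside reference range "
                f"[{xs[0]}, {xs[-1]}] for sex {sex}"
            )
        return (
            float(np.interp(x, xs, g["L"].to_numpy())),
            float(np.interp(x, xs, g["M"].to_numpy())),
            float(np.interp(x, xs, g["S"].to_numpy())),
        )

    def zscore(self, sex: str, x: float, value: float) -> float:
        return lms_zscore(value, *self.lms_at(sex, x))

    def value_at(self, sex: str, x: float, z: float) -> float:
        return lms_value(z, *self.lms_at(sex, x))


def classify_status(age: float, z: float) -> str:
    """WHO nutritional status from the classifying z-score.

    ``z`` must already be the right index for the age: BMI-for-age at
    age ≥ 5 y, weight-for-length below 5 y (the caller picks; see
    :func:`derive_features`).
    """
    if not math.isfinite(z):
        raise InvalidMeasurementError(f"non-finite z-score {z}")
    if z >= 2.0:
        return "obese"
    if z < -2.0:
        return "wasted"
    return "normal"


def derive_features(
    record,
    bmi_reference: LmsReference | None = None,
    wfl_reference: LmsReference | None = None,
) -> dict:
    """Assemble the thirteen modelling variables (plus z and status) for one child.

    ``record`` is any object with the raw-measurement attributes of a
    subject record. When references are given, ``bmi_zscore`` and WHO
    ``status`` are filled in; BMI-for-age classifies children aged ≥ 5 y
    and weight-for-length those below 5 y.
    """
    bmi = compute_bmi(record.weight, record.height)
    tua, ume, ufe, fat_pct = arm_composition(record.arm_circumference, record.triceps_sf)
    male = 1 if record.sex == "M" else 0
    out = {
        "subject_id": record.subject_id,
        "age": record.age,
        "female": 1 - male,
        "male": male,
        "weight": record.weight,
        "height": record.height,
        "bmi": bmi,
        "arm_circumference": record.arm_circumference,
        "biceps_sf": record.biceps_sf,
        "triceps_sf": record.triceps_sf,
        "tua": tua,
        "ume": ume,
        "ufe": ufe,
        "arm_fat_pct": fat_pct,
        "bmi_zscore": float("nan"),
        "status": "",
    }
    if bmi_reference is not None:
        out["bmi_zscore"] = bmi_reference.zscore(record.sex, record.age * 12.0, bmi)
        if record.age < 5.0 and wfl_reference is not None:
            z_classify = wfl_reference.zscore(record.sex, record.height, record.weight)
        else:
            z_classify = out["bmi_zscore"]
        out["status"] = classify_status(record.age, z_classify)
    return out


def derive_features_frame(
    records,
    bmi_reference: LmsReference | None = None,
    wfl_reference: LmsReference | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort, columns in the canonical variable order."""
    rows = [derive_features(r, bmi_reference, wfl_reference) for r in records]
    cols = ["subject_id", *FEATURE_NAMES, "bmi_zscore", "status"]
    return pd.DataFrame(rows)[cols]
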