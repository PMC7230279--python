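"""Classical pediatric resting-energy-expenditure prediction equations.

Five formulae are provided, the set most commonly used in pediatric
nutrition practice:

* ``harris_benedict`` — Harris & Benedict (1919) adult equations,
  sex-specific in weight, height and age, applied unchanged to children
  (no pediatric bands were ever published for it).
* ``who`` — FAO/WHO/UNU (1985) weight-only equations with pediatric age
  bands <3, 3–10 and 10–18 years.
* ``schofield_w`` / ``schofield_wh`` — Schofield (1985) weight-only and
  weight+height forms, same three bands.
* ``oxford`` — Henry (2005) "Oxford" weight-only equations, same bands.

Coefficients are data, not code: they live in
``data/equation_coefficients.csv``, transcribed from the published tables
with MJ/day forms converted to kcal/day (× 239.006) at transcription time.
Each band declares its own height unit so the published form is preserved
exactly (Harris–Benedict uses cm, Schofield weight+height uses metres).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import InvalidMeasurementError, OutOfBandError

EQUATION_IDS = ("harris_benedict", "who", "schofield_w", "schofield_wh", "oxford")

#: Human-readable labels, used in reports.
EQUATION_LABELS = {
    "harris_benedict": "Harris-Benedict",
    "who": "WHO",
    "schofield_w": "Schofield weight",
    "schofield_wh": "Schofield weight and height",
    "oxford": "Oxford",
}


@dataclass(frozen=True)
class CoefficientBand:
    """One (equation, sex, age-band) row of the published coefficient tables.

    Ages are half-open ``[age_lo, age_hi)`` so a 10.0-year-old falls in the
    10–18 band. ``h_unit`` is the height unit the published form uses
    (``cm`` or ``m``); ``a_coef`` is the per-year age coefficient, non-zero
    only for Harris–Benedict.
    """

    equation: str
    sex: str
    age_lo: float
    age_hi: float
    intercept: float
    w_coef: float
    h_coef: float
    h_unit: str
    a_coef: float
    source_note: str = ""


class EquationTable:
    """Coefficient bands for the five equations, loaded from CSV."""

    def __init__(self, bands: list[CoefficientBand]):
        self.bands = list(bands)
        self._index: dict[tuple[str, str], list[CoefficientBand]] = {}
        for b in self.bands:
            self._index.setdefault((b.equation, b.sex), []).append(b)
        for key in self._index:
            self._index[key].sort(key=lambda b: b.age_lo)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EquationTable":
        df = pd.read_csv(path)
        bands = [
            CoefficientBand(
                equation=r.equation, sex=r.sex,
                age_lo=float(r.age_lo), age_hi=float(r.age_hi),
                intercept=float(r.intercept), w_coef=float(r.w_coef),
                h_coef=float(r.h_coef), h_unit=str(r.h_unit),
                a_coef=float(r.a_coef), source_note=str(r.source_note),
            )
            for r in df.itertuples()
        ]
        return cls(bands)

    @classmethod
    def bundled(cls) -> "EquationTable":
        """The package's shipped transcription of the published tables."""
        with resources.as_file(
            resources.files("pedree.data").joinpath("equation_coefficients.csv")
        ) as p:
            return cls.from_csv(p)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([vars(b) for b in self.bands]).to_csv(path, index=False)

    def band_for(self, equation: str, sex: str, age: float) -> CoefficientBand:
        if equation not in EQUATION_IDS:
            raise OutOfBandError(f"unknown equation id {equation!r}")
        for b in self._index.get((equation, sex), []):
            if b.age_lo <= age < b.age_hi:
                return b
        raise OutOfBandError(
            f"no {equation} band covers sex={sex!r}, age={age} y"
        )


_BUNDLED: EquationTable | None = None


def _table(table: EquationTable | None) -> EquationTable:
    global _BUNDLED
    if table is not None:
        return table
    if _BUNDLED is None:
        _BUNDLED = EquationTable.bundled()
    return _BUNDLED


def predict_ree(
    equation: str,
    sex: str,
    age: float,
    weight: float,
    height: float | None = None,
    table: EquationTable | None = None,
) -> float:
    """Predict REE (kcal/day) with one published equation.

    ``sex`` is ``"M"`` or ``"F"``; ``weight`` in kg, ``height`` in cm
    (converted internally when a band was published per metre). ``height``
    may be omitted for weight-only equations.
    """
    if weight <= 0:
        raise InvalidMeasurementError(f"weight must be positive, got {weight}")
    band = _table(table).band_for(equation, sex, age)
    value = band.intercept + band.w_coef * weight + band.a_coef * age
    if band.h_coef != 0.0:
        if height is None or height <= 0:
            raise InvalidMeasurementError(
                f"{equation} requires a positive height, got {height}"
            )
        h = height / 100.0 if band.h_unit == "m" else height
        value += band.h_coef * h
    return value


def predict_all(
    sex: str,
    age: float,
    weight: float,
    height: float,
    table: EquationTable | None = None,
) -> dict[str, float]:
    """All five equation predictions for one child; never partial."""
    out: dict[str, float] = {}
    for eq in EQUATION_IDS:
        try:
            out[eq] = predict_ree(eq, sex, age, weight, height, table=table)
        except OutOfBandError as e:
            raise OutOfBandError(f"{eq}: {e}") from e
    return out


def predict_cohort(
    features: pd.DataFrame, table: EquationTable | None = None
) -> pd.DataFrame:
    """Equation predictions for a feature table.

    Expects columns ``subject_id, age, male, weight, height``; returns one
    row per subject with one column per equation id.
    """
    rows = []
    for r in features.itertuples():
        sex = "M" if r.male == 1 else "F"
        preds = predict_all(sex, r.age, r.weight, r.height, table=table)
        preds["subject_id"] = r.subject_id
        rows.append(preds)
    return pd.DataFrame(rows)[["subject_id", *EQUATION_IDS]]
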