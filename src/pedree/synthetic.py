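"""Synthetic pediatric cohorts with a known REE-generating mechanism.

Nothing in the downstream pipeline depends on real data: this module
fabricates cohorts whose marginal distributions mimic a mixed healthy
pediatric population (2–17 years, roughly two-thirds boys, about a fifth
obese), together with the gas-exchange values an indirect calorimeter
would record, and — crucially for testing — the *latent* REE law that
produced them.

The generative mechanism, in order:

1. age — truncated normal on [2, 17] years;
2. sex and nutritional category (obese / underweight / normal) — assigned
   in exact configured proportions, then shuffled;
3. a BMI z-score sampled per category (obese: z ≥ 2; wasted: z < −2),
   mapped through the package's synthetic LMS references to BMI (age ≥ 5 y)
   or weight-for-length (age < 5 y), so the WHO classifier recovers the
   injected categories by construction;
4. height from a piecewise-linear sex-specific growth curve plus noise;
   weight = BMI · height²;
5. skinfolds log-normally linked to the BMI z-score; arm circumference
   linear in age and z;
6. latent REE from a smooth allometric law in a fat-free-mass proxy,

       REE* = k · (W·(1 − 0.5·fat%/100))^0.75 · (1 + s·male) + a·age,

   deliberately nonlinear in what the classical equations use, so a
   flexible model has genuine headroom over them;
7. measured REE = REE* + N(0, ree_noise_sd), and VO2/VCO2 back-solved
   through the Weir relation at a uniformly sampled respiratory quotient —
   applying the Weir formula to a record's gas values returns its
   ``ree_measured`` exactly.

All constants below were calibrated once, at n = 20 000, against the
target marginal profile; they are conventions of this generator, not
estimates of any real population's covariance structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .anthropometry import FEATURE_NAMES, LmsReference, arm_composition, compute_bmi
from .calorimetry import vo2_from_ree, weir_ree
from .errors import InvalidConfigError

#: Target marginal profile: per-variable (mean, SD) of the emulated population.
TABLE1_PROFILE: dict[str, tuple[float, float]] = {
    "age": (13.0, 3.5),          # years
    "weight": (62.8, 23.0),      # kg
    "height": (156.5, 18.6),     # cm
    "ree": (1417.6, 368.5),      # kcal/day
}

# -- growth-curve knots (age years -> height cm), per sex -------------------
_HEIGHT_KNOTS_AGE = [2.0, 5.0, 10.0, 13.0, 15.0, 17.0]
_HEIGHT_KNOTS_M = [88.0, 110.0, 139.0, 160.0, 173.0, 178.0]
_HEIGHT_KNOTS_F = [86.0, 109.0, 139.0, 157.0, 162.0, 164.0]
_HEIGHT_NOISE_SD = 6.0

# -- synthetic LMS reference shape ------------------------------------------
_BMI_M_KNOTS_AGE = [2.0, 5.0, 10.0, 13.0, 17.0]
_BMI_M_KNOTS = {"M": [16.2, 15.8, 18.6, 21.4, 23.6], "F": [16.0, 15.6, 18.4, 21.2, 23.2]}
_BMI_L, _BMI_S = -1.6, 0.12
_WFL_L, _WFL_S = -0.4, 0.11

# -- BMI z-score mixture (per nutritional category) -------------------------
_Z_NORMAL_MEAN, _Z_NORMAL_SD = 1.05, 0.90
_Z_OBESE_SD = 0.35            # z = 2 + |N(0, sd)|, clipped at 3.6
_Z_WASTED_SD = 0.30           # z = -2.01 - |N(0, sd)|, clipped at -3.5

# -- skinfolds / arm circumference ------------------------------------------
# log-normal: ln(sf) = ln(base) + slope*z + N(0, sigma)
_SKINFOLD_PARAMS = {          # base mm, z-slope, log-sd
    "biceps_sf": (8.8, 0.30, 0.32),
    "triceps_sf": (15.0, 0.30, 0.24),
    "subscapular_sf": (13.2, 0.36, 0.34),
    "suprailiac_sf": (17.5, 0.36, 0.27),
}
_ARM_CIRC = (13.3, 1.00, 2.30, 3.0)   # intercept, per-year, per-z, noise SD

# -- latent REE law ----------------------------------------------------------
_REE_K = 65.5                 # allometric scale, kcal/day per (kg FFM-proxy)^0.75
_REE_EXP = 0.75
_REE_MALE_BONUS = 0.06        # multiplicative sex modulation
_REE_AGE_COEF = 12.0          # kcal/day per year
_FFM_FAT_WEIGHT = 0.5         # FFM proxy = W * (1 - 0.5 * armfat%/100)


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for one synthetic cohort."""

    n: int = 561
    seed: int = 0
    male_fraction: float = 0.675
    age_range: tuple[float, float] = (2.0, 17.0)
    target_profile: dict = field(default_factory=lambda: dict(TABLE1_PROFILE))
    obese_fraction: float = 0.20
    underweight_fraction: float = 0.03
    ree_noise_sd: float = 90.0
    rq_range: tuple[float, float] = (0.71, 0.95)
    qc_fail_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InvalidConfigError(f"n must be >= 0, got {self.n}")
        for name in ("male_fraction", "obese_fraction", "underweight_fraction",
                     "qc_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0,1], got {v}")
        if self.obese_fraction + self.underweight_fraction > 1.0:
            raise InvalidConfigError("obese + underweight fractions exceed 1")
        lo, hi = self.age_range
        if not (2.0 <= lo < hi <= 17.0):
            raise InvalidConfigError(f"age_range must lie within [2,17], got {self.age_range}")
        if self.ree_noise_sd < 0:
            raise InvalidConfigError("ree_noise_sd must be >= 0")
        rlo, rhi = self.rq_range
        if not (0.67 <= rlo < rhi <= 1.3):
            raise InvalidConfigError(f"rq_range must lie within [0.67,1.3], got {self.rq_range}")


@dataclass(frozen=True)
class SubjectRecord:
    """One child's raw measurements (anthropometry + gas exchange)."""

    subject_id: str
    age: float            # years
    sex: str              # M | F
    weight: float         # kg
    height: float         # cm
    arm_circumference: float  # cm
    biceps_sf: float      # mm
    triceps_sf: float     # mm
    subscapular_sf: float  # mm
    suprailiac_sf: float  # mm
    vo2: float            # L/min
    vco2: float           # L/min
    ree_measured: float   # kcal/day
    ree_true_latent: float | None = None  # synthetic only: noise-free law value


@dataclass(frozen=True)
class CalorimetryTrace:
    """Minute-by-minute gas-exchange series for one measurement session."""

    subject_id: str
    timestamps: np.ndarray   # minutes from start, strictly increasing
    vo2_series: np.ndarray   # L/min
    vco2_series: np.ndarray  # L/min
    ve_series: np.ndarray    # L/min minute ventilation


def synthetic_bmi_reference() -> LmsReference:
    """Smooth synthetic BMI-for-age LMS reference (24–216 months, both sexes)."""
    rows = []
    months = np.arange(24, 217, 6)
    for sex in ("M", "F"):
        m_knots = _BMI_M_KNOTS[sex]
        for mo in months:
            M = float(np.interp(mo / 12.0, _BMI_M_KNOTS_AGE, m_knots))
            rows.append({"sex": sex, "x": float(mo), "L": _BMI_L, "M": M, "S": _BMI_S})
    return LmsReference(pd.DataFrame(rows), "bmi_for_age")


def synthetic_wfl_reference() -> LmsReference:
    """Synthetic weight-for-length LMS reference (70–130 cm, both sexes)."""
    rows = []
    for sex in ("M", "F"):
        base_bmi = 15.9 if sex == "M" else 15.7
        for h in np.arange(60.0, 151.0, 5.0):
            rows.append({"sex": sex, "x": h, "L": _WFL_L,
                         "M": base_bmi * (h / 100.0) ** 2, "S": _WFL_S})
    return LmsReference(pd.DataFrame(rows), "weight_for_length")


def _heights(age: np.ndarray, male: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h = np.where(
        male == 1,
        np.interp(age, _HEIGHT_KNOTS_AGE, _HEIGHT_KNOTS_M),
        np.interp(age, _HEIGHT_KNOTS_AGE, _HEIGHT_KNOTS_F),
    )
    return h + rng.normal(0.0, _HEIGHT_NOISE_SD, size=len(age))


def _category_counts(n: int, config: CohortConfig) -> np.ndarray:
    n_ob = int(round(config.obese_fraction * n))
    n_uw = int(round(config.underweight_fraction * n))
    cats = np.array(["obese"] * n_ob + ["wasted"] * n_uw + ["normal"] * (n - n_ob - n_uw))
    return cats


def _sample_z(cats: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    z = np.empty(len(cats))
    nrm = cats == "normal"
    a = (-1.99 - _Z_NORMAL_MEAN) / _Z_NORMAL_SD
    b = (1.99 - _Z_NORMAL_MEAN) / _Z_NORMAL_SD
    z[nrm] = stats.truncnorm.rvs(a, b, loc=_Z_NORMAL_MEAN, scale=_Z_NORMAL_SD,
                                 size=nrm.sum(), random_state=rng)
    ob = cats == "obese"
    z[ob] = np.minimum(2.0 + np.abs(rng.normal(0.0, _Z_OBESE_SD, ob.sum())), 3.6)
    uw = cats == "wasted"
    z[uw] = np.maximum(-2.01 - np.abs(rng.normal(0.0, _Z_WASTED_SD, uw.sum())), -3.5)
    return z


def latent_ree(weight, arm_fat_pct, male, age) -> np.ndarray:
    """The generator's noise-free REE law (kcal/day). Strictly increasing in weight."""
    ffm_proxy = np.asarray(weight) * (1.0 - _FFM_FAT_WEIGHT * np.asarray(arm_fat_pct) / 100.0)
    return (
        _REE_K * ffm_proxy**_REE_EXP * (1.0 + _REE_MALE_BONUS * np.asarray(male))
        + _REE_AGE_COEF * np.asarray(age)
    )


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate a cohort; deterministic for a fixed ``config.seed``."""
    n = config.n
    if n == 0:
        return []
    rng = np.random.default_rng(config.seed)
    bmi_ref = synthetic_bmi_reference()
    wfl_ref = synthetic_wfl_reference()

    lo, hi = config.age_range
    mean_t, sd_t = config.target_profile.get("age", TABLE1_PROFILE["age"])
    a_shape, b_shape = _age_beta_params(lo, hi, mean_t, sd_t)
    age = lo + (hi - lo) * rng.beta(a_shape, b_shape, size=n)

    n_male = int(round(config.male_fraction * n))
    male = np.zeros(n, dtype=int)
    male[:n_male] = 1
    rng.shuffle(male)

    cats = _category_counts(n, config)
    rng.shuffle(cats)
    z = _sample_z(cats, rng)

    height = _heights(age, male, rng)
    sexes = np.where(male == 1, "M", "F")

    weight = np.empty(n)
    for i in range(n):
        if age[i] < 5.0:
            weight[i] = wfl_ref.value_at(sexes[i], float(height[i]), z[i])
        else:
            bmi_i = bmi_ref.value_at(sexes[i], age[i] * 12.0, z[i])
            weight[i] = bmi_i * (height[i] / 100.0) ** 2

    sf = {}
    for name, (base, slope, sigma) in _SKINFOLD_PARAMS.items():
        sf[name] = np.exp(np.log(base) + slope * z + rng.normal(0.0, sigma, n))
    c0, c_age, c_z, c_sd = _ARM_CIRC
    arm = c0 + c_age * age + c_z * z + rng.normal(0.0, c_sd, n)
    arm = np.maximum(arm, 12.0)
    # keep triceps physically feasible: pi * T(cm) must stay below C
    sf["triceps_sf"] = np.minimum(sf["triceps_sf"], 0.8 * 10.0 * arm / math.pi)

    fat_pct = np.array([
        arm_composition(arm[i], sf["triceps_sf"][i])[3] for i in range(n)
    ])
    ree_latent = latent_ree(weight, fat_pct, male, age)
    ree_meas = ree_latent + rng.normal(0.0, config.ree_noise_sd, n)
    ree_meas = np.maximum(ree_meas, 200.0)

    rq = rng.uniform(*config.rq_range, size=n)
    if config.qc_fail_fraction > 0:
        n_fail = int(round(config.qc_fail_fraction * n))
        fail_idx = rng.choice(n, size=n_fail, replace=False)
        half = n_fail // 2
        rq[fail_idx[:half]] = rng.uniform(0.50, 0.66, size=half)
        rq[fail_idx[half:]] = rng.uniform(1.31, 1.45, size=n_fail - half)

    records = []
    for i in range(n):
        vo2, vco2 = vo2_from_ree(float(ree_meas[i]), float(rq[i]))
        records.append(SubjectRecord(
            subject_id=f"S{i + 1:04d}",
            age=float(age[i]), sex=str(sexes[i]),
            weight=float(weight[i]), height=float(height[i]),
            arm_circumference=float(arm[i]),
            biceps_sf=float(sf["biceps_sf"][i]),
            triceps_sf=float(sf["triceps_sf"][i]),
            subscapular_sf=float(sf["subscapular_sf"][i]),
            suprailiac_sf=float(sf["suprailiac_sf"][i]),
            vo2=vo2, vco2=vco2,
            ree_measured=float(weir_ree(vo2, vco2)),
            ree_true_latent=float(ree_latent[i]),
        ))
    return records


def _age_beta_params(lo: float, hi: float, mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters matching the target age mean/SD on [lo, hi].

    A Beta shape is used because the default profile (mean 13.0 y, SD 3.5 y
    on [2, 17]) demands more spread than any truncated normal with that mean
    admits; the resulting density leans towards adolescence, as pediatric
    metabolic cohorts typically do.
    """
    m = (mean - lo) / (hi - lo)
    v = (sd / (hi - lo)) ** 2
    if not 0 < m < 1 or v <= 0 or v >= m * (1 - m):
        raise InvalidConfigError(
            f"age profile mean={mean}, sd={sd} infeasible on [{lo}, {hi}]"
        )
    common = m * (1 - m) / v - 1.0
    return m * common, (1 - m) * common


def generate_trace(
    subject: SubjectRecord,
    duration: float = 20.0,
    sampling: float = 1.0,
    jitter: float = 0.02,
    seed: int = 0,
    ventilatory_equivalent: float = 28.0,
) -> CalorimetryTrace:
    """Synthetic minute-by-minute trace fluctuating around the subject's gas values.

    Each sample multiplies VO2/VCO2/VE independently by ``1 + jitter·N(0,1)``
    (clipped to stay positive); ``jitter=0`` yields a constant trace.
    """
    if sampling <= 0 or duration < sampling:
        raise InvalidConfigError(
            f"need duration >= sampling > 0, got duration={duration}, sampling={sampling}"
        )
    if jitter < 0:
        raise InvalidConfigError(f"jitter must be >= 0, got {jitter}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, sampling)
    m = len(t)

    def wobble(base: float) -> np.ndarray:
        return base * np.maximum(1.0 + jitter * rng.standard_normal(m), 0.05)

    return CalorimetryTrace(
        subject_id=subject.subject_id,
        timestamps=t,
        vo2_series=wobble(subject.vo2),
        vco2_series=wobble(subject.vco2),
        ve_series=wobble(ventilatory_equivalent * subject.vo2),
    )


# ---------------------------------------------------------------------------
# feature-selection benchmark
# ---------------------------------------------------------------------------

#: The seven columns that drive the benchmark target.
BENCHMARK_INFORMATIVE = ("age", "female", "weight", "bmi", "tua", "ume", "arm_fat_pct")


def generate_selection_benchmark(
    n: int = 561, seed: int = 0, noise_sd: float = 50.0
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """A 13-variable regression problem where exactly seven variables matter.

    Unlike real anthropometry (where TUA = UME + UFE makes the "true subset"
    ill-defined), all 13 columns here are sampled independently, so the
    informative set is identifiable. The target mixes linear terms with a
    weight×TUA interaction. Returns ``(X, y, true_mask)`` with ``true_mask``
    aligned with the canonical feature order.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "age": rng.uniform(2.0, 17.0, n),
        "female": rng.binomial(1, 0.325, n).astype(float),
        "male": rng.binomial(1, 0.675, n).astype(float),
        "weight": np.clip(rng.normal(62.8, 23.0, n), 10.0, None),
        "height": np.clip(rng.normal(156.5, 18.6, n), 80.0, None),
        "bmi": np.clip(rng.normal(24.6, 5.9, n), 12.0, None),
        "arm_circumference": np.clip(rng.normal(28.7, 5.7, n), 12.0, None),
        "biceps_sf": np.clip(rng.normal(13.3, 6.6, n), 1.0, None),
        "triceps_sf": np.clip(rng.normal(22.5, 9.0, n), 1.0, None),
        "tua": np.clip(rng.normal(68.1, 25.8, n), 10.0, None),
        "ume": np.clip(rng.normal(33.8, 12.1, n), 5.0, None),
        "ufe": np.clip(rng.normal(34.4, 18.4, n), 2.0, None),
        "arm_fat_pct": np.clip(rng.normal(47.8, 13.5, n), 5.0, 95.0),
    })[FEATURE_NAMES]
    y = (
        250.0
        + 18.0 * X["age"]
        - 90.0 * X["female"]
        + 9.0 * X["weight"]
        + 6.0 * X["bmi"]
        + 1.8 * X["tua"]
        + 2.4 * X["ume"]
        - 3.5 * X["arm_fat_pct"]
        + 0.004 * X["weight"] * X["tua"]
        + rng.normal(0.0, noise_sd, n)
    )
    mask = np.array([name in BENCHMARK_INFORMATIVE for name in FEATURE_NAMES])
    return X, y.rename("ree"), mask


# ---------------------------------------------------------------------------
# CSV contracts
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "subject_id", "age", "sex", "weight_kg", "height_cm", "arm_circ_cm",
    "biceps_mm", "triceps_mm", "subscapular_mm", "suprailiac_mm",
    "vo2_lmin", "vco2_lmin", "ree_kcal_d",
]


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = [{
        "subject_id": r.subject_id, "age": r.age, "sex": r.sex,
        "weight_kg": r.weight, "height_cm": r.height,
        "arm_circ_cm": r.arm_circumference,
        "biceps_mm": r.biceps_sf, "triceps_mm": r.triceps_sf,
        "subscapular_mm": r.subscapular_sf, "suprailiac_mm": r.suprailiac_sf,
        "vo2_lmin": r.vo2, "vco2_lmin": r.vco2, "ree_kcal_d": r.ree_measured,
    } for r in records]
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def write_cohort_csv(records: list[SubjectRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    return [
        SubjectRecord(
            subject_id=str(r.subject_id), age=float(r.age), sex=str(r.sex),
            weight=float(r.weight_kg), height=float(r.height_cm),
            arm_circumference=float(r.arm_circ_cm),
            biceps_sf=float(r.biceps_mm), triceps_sf=float(r.triceps_mm),
            subscapular_sf=float(r.subscapular_mm), suprailiac_sf=float(r.suprailiac_mm),
            vo2=float(r.vo2_lmin), vco2=float(r.vco2_lmin),
            ree_measured=float(r.ree_kcal_d),
        )
        for r in df.itertuples()
    ]


def write_trace_csv(traces: list[CalorimetryTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame({
            "subject_id": tr.subject_id, "t_min": tr.timestamps,
            "vo2": tr.vo2_series, "vco2": tr.vco2_series, "ve": tr.ve_series,
        })
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> list[CalorimetryTrace]:
    df = pd.read_csv(path)
    return [
        CalorimetryTrace(
            subject_id=str(sid),
            timestamps=g["t_min"].to_numpy(float),
            vo2_series=g["vo2"].to_numpy(float),
            vco2_series=g["vco2"].to_numpy(float),
            ve_series=g["ve"].to_numpy(float),
        )
        for sid, g in df.groupby("subject_id", sort=False)
    ]
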