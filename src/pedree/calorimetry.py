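"""Indirect-calorimetry reduction: Weir formula, steady state, QC.

REE is computed with the modified Weir formula without the urinary-nitrogen
term:

    REE (kcal/day) = (3.941 · VO2 + 1.106 · VCO2) · 1440,   gas in L/min.

Steady state is the earliest sliding window of at least ``window_min``
minutes in which the respiratory quotient varies by less than 5% and VO2
and minute ventilation each by less than 10%. "Variation" defaults to the
coefficient of variation (SD/mean) over the window, the usual calorimetry
convention; a range-based alternative ((max − min)/mean) is available via
``variation="range"``. Subjects with no steady-state window, or a
steady-state RQ outside [0.67, 1.3], are excluded (boundary values kept:
the exclusion is strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidMeasurementError

RQ_MIN = 0.67
RQ_MAX = 1.3


def respiratory_quotient(vo2: float, vco2: float) -> float:
    """RQ = VCO2/VO2 (dimensionless)."""
    if vo2 <= 0:
        raise InvalidMeasurementError(f"VO2 must be positive, got {vo2}")
    return vco2 / vo2


def weir_ree(vo2, vco2):
    """Modified Weir REE in kcal/day from VO2/VCO2 in L/min (vectorised)."""
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 <= 0) or np.any(vco2 <= 0):
        raise InvalidMeasurementError("gas volumes must be positive")
    out = (3.941 * vo2 + 1.106 * vco2) * 1440.0
    return float(out) if out.ndim == 0 else out


def vo2_from_ree(ree: float, rq: float) -> tuple[float, float]:
    """Invert Weir: (VO2, VCO2) in L/min reproducing ``ree`` at quotient ``rq``."""
    if ree <= 0:
        raise InvalidMeasurementError(f"REE must be positive, got {ree}")
    vo2 = ree / (1440.0 * (3.941 + 1.106 * rq))
    return vo2, rq * vo2


@dataclass(frozen=True)
class SteadyStateWindow:
    """A qualifying steady-state segment of a calorimetry trace."""

    start: float  # minutes
    end: float    # minutes
    rq_variation: float
    vo2_variation: float
    ve_variation: float
    mean_vo2: float
    mean_vco2: float

    @property
    def mean_rq(self) -> float:
        return self.mean_vco2 / self.mean_vo2


@dataclass(frozen=True)
class QcOutcome:
    """Keep/exclude decision for one subject, with the reason."""

    subject_id: str
    kept: bool
    reason: str  # ok | no_steady_state | rq_out_of_range


def _variation(x: np.ndarray, mode: str) -> float:
    m = float(np.mean(x))
    if m == 0:
        return float("inf")
    if mode == "cv":
        return float(np.std(x) / abs(m))
    if mode == "range":
        return float((np.max(x) - np.min(x)) / abs(m))
    raise ValueError(f"unknown variation mode {mode!r}")


def detect_steady_state(
    trace,
    window_min: float = 5.0,
    rq_tol: float = 0.05,
    vo2_tol: float = 0.10,
    ve_tol: float = 0.10,
    variation: str = "cv",
) -> SteadyStateWindow | None:
    """Earliest window of length ≥ ``window_min`` minutes meeting the tolerances.

    Windows are defined by elapsed time on the trace's native timestamps.
    Returns ``None`` when no window qualifies (including traces shorter than
    the window) — absence of steady state is an outcome, not an error.
    """
    if window_min <= 0:
        raise InvalidMeasurementError(f"window_min must be positive, got {window_min}")
    t = np.asarray(trace.timestamps, dtype=float)
    vo2 = np.asarray(trace.vo2_series, dtype=float)
    vco2 = np.asarray(trace.vco2_series, dtype=float)
    ve = np.asarray(trace.ve_series, dtype=float)
    n = len(t)
    if n < 2 or t[-1] - t[0] < window_min:
        return None
    rq = vco2 / vo2
    for i in range(n):
        # smallest j with elapsed time >= window_min
        j = int(np.searchsorted(t, t[i] + window_min, side="left"))
        if j >= n:
            break
        sl = slice(i, j + 1)
        rq_var = _variation(rq[sl], variation)
        vo2_var = _variation(vo2[sl], variation)
        ve_var = _variation(ve[sl], variation)
        if rq_var < rq_tol and vo2_var < vo2_tol and ve_var < ve_tol:
            return SteadyStateWindow(
                start=float(t[i]), end=float(t[j]),
                rq_variation=rq_var, vo2_variation=vo2_var, ve_variation=ve_var,
                mean_vo2=float(np.mean(vo2[sl])), mean_vco2=float(np.mean(vco2[sl])),
            )
    return None


def qc_filter(windows: dict[str, SteadyStateWindow | None]) -> list[QcOutcome]:
    """Apply the exclusion rules to per-subject steady-state results.

    ``windows`` maps subject id → detected window (or ``None``). A subject
    is kept iff a steady state was found and its mean RQ lies in
    [0.67, 1.3] inclusive.
    """
    outcomes = []
    for sid, w in windows.items():
        if w is None:
            outcomes.append(QcOutcome(sid, False, "no_steady_state"))
            continue
        rq = w.mean_rq
        if rq < RQ_MIN or rq > RQ_MAX:
            outcomes.append(QcOutcome(sid, False, "rq_out_of_range"))
        else:
            outcomes.append(QcOutcome(sid, True, "ok"))
    return outcomes


def qc_filter_records(records) -> list[QcOutcome]:
    """QC straight from subject records' recorded gas values (no traces)."""
    outcomes = []
    for r in records:
        rq = respiratory_quotient(r.vo2, r.vco2)
        if rq < RQ_MIN or rq > RQ_MAX:
            outcomes.append(QcOutcome(r.subject_id, False, "rq_out_of_range"))
        else:
            outcomes.append(QcOutcome(r.subject_id, True, "ok"))
    return outcomes
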