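"""Accuracy statistics, method-comparison tables, subgroup reports.

The metric bundle for one method against measured REE:

* MAE — mean |pred − true|, plus the SD of the absolute errors;
* RMSE — √mean((pred − true)²);
* NMSE — MSE normalised by the variance of the true series;
* real (signed) error — mean(pred − true), an interpretation of the
  "real error" named in the source metric suite, which never defines it;
* imprecision % — 100 · MAE / mean(true) of the evaluated group, each
  subgroup using its own mean;
* Pearson r and r², Kendall tau-b (tie-corrected: REE values can tie after
  rounding), and the two-sided paired t-test of pred vs true.

Raw p-values are always emitted; the conventional significance threshold
for these comparisons is p < 0.001 (many tests run at once).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataContractError, DegenerateVariableError

SIGNIFICANCE_LEVEL = 0.001


@dataclass(frozen=True)
class FitMetrics:
    """Accuracy of one prediction method against measured values."""

    method: str
    n: int
    mean_prediction: float   # kcal/day
    mae: float               # kcal/day
    mae_sd: float            # kcal/day
    rmse: float              # kcal/day
    nmse: float
    real_error: float        # signed mean error, kcal/day
    imprecision_pct: float
    pearson_r: float
    pearson_r2: float
    kendall_tau: float
    paired_t: float
    paired_p: float

    @classmethod
    def average(cls, a: "FitMetrics", b: "FitMetrics", method: str) -> "FitMetrics":
        """Field-wise mean of two runs' metrics (n is summed)."""
        vals = {}
        for f in fields(cls):
            if f.name == "method":
                vals[f.name] = method
            elif f.name == "n":
                vals[f.name] = a.n + b.n
            else:
                vals[f.name] = (getattr(a, f.name) + getattr(b, f.name)) / 2.0
        return cls(**vals)


def imprecision_pct(mae: float, mean_true: float) -> float:
    """Imprecision % = 100 · MAE / mean measured value of the group."""
    if mean_true <= 0:
        raise DataContractError(f"mean of true values must be positive, got {mean_true}")
    return 100.0 * mae / mean_true


def fit_metrics(pred, true, method: str = "") -> FitMetrics:
    """Full metric bundle for one prediction series."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise DataContractError(f"shape mismatch: {p.shape} vs {t.shape}")
    n = len(p)
    if n < 3:
        raise DataContractError(f"need at least 3 records, got {n}")
    err = p - t
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    var_t = float(np.var(t))
    nmse = float(np.mean(err**2) / var_t) if var_t > 0 else float("inf")
    r, _ = stats.pearsonr(p, t)
    tau, _ = stats.kendalltau(p, t)  # tau-b by default
    tt = stats.ttest_rel(p, t)
    return FitMetrics(
        method=method, n=n,
        mean_prediction=float(np.mean(p)),
        mae=mae, mae_sd=float(np.std(np.abs(err))),
        rmse=rmse, nmse=nmse,
        real_error=float(np.mean(err)),
        imprecision_pct=imprecision_pct(mae, float(np.mean(t))),
        pearson_r=float(r), pearson_r2=float(r) ** 2,
        kendall_tau=float(tau),
        paired_t=float(tt.statistic), paired_p=float(tt.pvalue),
    )


def correlation_matrix(method_outputs: Mapping[str, np.ndarray], true=None) -> pd.DataFrame:
    """Pairwise Pearson correlations among method outputs (and measured values).

    ``true``, when given, is appended as the last row/column under the name
    ``measured_ree``.
    """
    series = {k: np.asarray(v, dtype=float) for k, v in method_outputs.items()}
    if true is not None:
        series["measured_ree"] = np.asarray(true, dtype=float)
    lengths = {len(v) for v in series.values()}
    if len(lengths) != 1:
        raise DataContractError(f"series lengths differ: {lengths}")
    for name, v in series.items():
        if np.std(v) == 0:
            raise DegenerateVariableError(f"constant series {name!r} has no correlation")
    df = pd.DataFrame(series)
    return df.corr(method="pearson")


def tendency_line(series, degree: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial of a series against its rank index.

    Used for the smooth "tendency line" drawn over predictions ordered by
    true REE. Returns (coefficients in ascending degree order, fitted values).
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n <= degree:
        raise DataContractError(f"need more than {degree} points, got {n}")
    x = np.arange(n, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    return coeffs, fitted


@dataclass
class SubgroupReport:
    """Per-subgroup metric panels: one Table-2-shaped block per status."""

    panels: dict[str, list[FitMetrics]]        # subgroup -> one entry per method
    unavailable: dict[str, str]                # subgroup -> reason

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, metrics in self.panels.items():
            for m in metrics:
                row = {"subgroup": group, **{f.name: getattr(m, f.name) for f in fields(FitMetrics)}}
                rows.append(row)
        return pd.DataFrame(rows)


def subgroup_report(
    predictions: Mapping[str, np.ndarray],
    true,
    status,
    min_n: int = 3,
) -> SubgroupReport:
    """Metrics per method for the overall cohort and each nutritional status.

    ``predictions`` maps method name → prediction series; ``status`` holds
    one label per record (``obese`` / ``wasted`` / ``normal``). Subgroups
    with fewer than ``min_n`` records are flagged unavailable, never
    fabricated.
    """
    t = np.asarray(true, dtype=float)
    s = np.asarray(status)
    if len(t) != len(s):
        raise DataContractError("status labels must cover every record")
    panels: dict[str, list[FitMetrics]] = {}
    unavailable: dict[str, str] = {}
    groups = {"overall": np.ones(len(t), dtype=bool)}
    for label in ("obese", "wasted", "normal"):
        groups[label] = s == label
    for label, mask in groups.items():
        if mask.sum() < min_n:
            unavailable[label] = f"n={int(mask.sum())} < {min_n}"
            continue
        panels[label] = [
            fit_metrics(np.asarray(p, dtype=float)[mask], t[mask], method=name)
            for name, p in predictions.items()
        ]
    return SubgroupReport(panels, unavailable)
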