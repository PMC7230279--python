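"""End-to-end study pipeline: cohort → features → QC → equations → map →
variable selection → two-run ANN → comparison report.

Every stage reads and writes plain CSV/JSON artifacts under a run
directory, so stages can be re-run and diffed independently; the
orchestrator simply chains the same stage functions. All randomness flows
from one global seed through per-stage seeds (CRC32 of "seed:stage"), so a
rerun with the same configuration is byte-identical at the artifact level.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anthropometry import FEATURE_NAMES, derive_features_frame
from .autocm import semantic_map
from .calorimetry import qc_filter_records
from .equations import EQUATION_IDS, EquationTable, predict_cohort
from .errors import DataContractError
from .metrics import correlation_matrix, fit_metrics, subgroup_report
from .mlp import MlpSettings, two_run_protocol
from .synthetic import (
    CohortConfig, generate_cohort, read_cohort_csv, synthetic_bmi_reference,
    synthetic_wfl_reference, write_cohort_csv,
)
from .twist import TwistConfig, run_twist

log = logging.getLogger("pedree")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Configuration of a full study run."""

    out_dir: str = "run"
    seed: int = 0
    cohort_csv: str | None = None        # exactly one input source:
    cohort: CohortConfig | None = None   # a CSV path or a generator config
    equation_csv: str | None = None      # None -> bundled coefficients
    twist: TwistConfig | None = None
    mlp_hidden: int = 4
    mlp_epochs: int = 2000
    autocm_epochs: int = 200

    def __post_init__(self) -> None:
        if self.cohort_csv is not None and self.cohort is not None:
            raise DataContractError("give either cohort_csv or a generator config, not both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = raw.pop("cohort", None)
        twist = raw.pop("twist", None)
        cfg = cls(**raw)
        if cohort is not None:
            cfg.cohort = CohortConfig(**cohort)
        if twist is not None:
            cfg.twist = TwistConfig(**twist)
        return cfg


# ---------------------------------------------------------------------------
# stages: each consumes/produces documented file contracts
# ---------------------------------------------------------------------------

def stage_simulate(config: CohortConfig, out_csv: Path) -> None:
    write_cohort_csv(generate_cohort(config), out_csv)


def stage_features(cohort_csv: Path, out_csv: Path) -> None:
    records = read_cohort_csv(cohort_csv)
    feats = derive_features_frame(records, synthetic_bmi_reference(), synthetic_wfl_reference())
    feats["ree_measured"] = [r.ree_measured for r in records]
    feats.to_csv(out_csv, index=False)


def stage_qc(cohort_csv: Path, out_csv: Path) -> None:
    records = read_cohort_csv(cohort_csv)
    outcomes = qc_filter_records(records)
    pd.DataFrame(
        [{"subject_id": o.subject_id, "kept": o.kept, "reason": o.reason} for o in outcomes]
    ).to_csv(out_csv, index=False)


def stage_equations(features_csv: Path, out_csv: Path, equation_csv: str | None = None) -> None:
    feats = pd.read_csv(features_csv)
    table = EquationTable.from_csv(equation_csv) if equation_csv else None
    predict_cohort(feats, table=table).to_csv(out_csv, index=False)


def stage_map(features_csv: Path, out_json: Path, out_dot: Path, max_epochs: int = 200) -> None:
    feats = pd.read_csv(features_csv)
    _, cmap = semantic_map(feats[FEATURE_NAMES], max_epochs=max_epochs)
    cmap.to_json(out_json)
    cmap.to_dot(out_dot)


def stage_twist(features_csv: Path, qc_csv: Path, out_json: Path,
                config: TwistConfig) -> None:
    feats, target = _kept_features(features_csv, qc_csv)
    result = run_twist(feats[FEATURE_NAMES], target, config)
    Path(out_json).write_text(json.dumps(result.to_json_dict(), indent=2))


def stage_fit(features_csv: Path, qc_csv: Path, twist_json: Path, out_csv: Path,
              hidden: int = 4, epochs: int = 2000, seed: int = 0) -> None:
    feats, target = _kept_features(features_csv, qc_csv)
    tw = json.loads(Path(twist_json).read_text())
    sel = tw["selected_variables"]
    a_ids = [i for i in tw["subset_a_ids"] if i in feats.index]
    b_ids = [i for i in tw["subset_b_ids"] if i in feats.index]
    settings = MlpSettings(n_inputs=len(sel), n_hidden=hidden, max_epochs=epochs, seed=seed)
    report = two_run_protocol(
        feats.loc[a_ids, sel], target.loc[a_ids],
        feats.loc[b_ids, sel], target.loc[b_ids],
        settings, ids_a=a_ids, ids_b=b_ids,
    )
    combined = report.combined
    rows = [
        {"subject_id": sid, "ree_pred_kcal_d": combined[sid],
         "run": "ab" if sid in set(b_ids) else "ba"}
        for sid in feats.index
    ]
    pd.DataFrame(rows).to_csv(out_csv, index=False)


def stage_report(features_csv: Path, qc_csv: Path, equations_csv: Path,
                 predictions_csv: Path, out_metrics: Path, out_correlations: Path) -> dict:
    feats, target = _kept_features(features_csv, qc_csv)
    eq = pd.read_csv(equations_csv).set_index("subject_id").loc[feats.index]
    ann = pd.read_csv(predictions_csv).set_index("subject_id").loc[feats.index]

    predictions = {"neural_network": ann["ree_pred_kcal_d"].to_numpy()}
    for eq_id in EQUATION_IDS:
        predictions[eq_id] = eq[eq_id].to_numpy()

    status = feats["status"].to_numpy()
    report = subgroup_report(predictions, target.to_numpy(), status)
    report.to_frame().to_csv(out_metrics, index=False)

    corr = correlation_matrix(predictions, target.to_numpy())
    corr.to_csv(out_correlations)

    overall = {m.method: m for m in report.panels["overall"]}
    return {
        "n": int(len(feats)),
        "ann_mae": overall["neural_network"].mae,
        "ann_r2": overall["neural_network"].pearson_r2,
        "equation_mae": {e: overall[e].mae for e in EQUATION_IDS},
    }


def _kept_features(features_csv: Path, qc_csv: Path) -> tuple[pd.DataFrame, pd.Series]:
    feats = pd.read_csv(features_csv).set_index("subject_id")
    qc = pd.read_csv(qc_csv).set_index("subject_id")
    kept = qc.index[qc["kept"]]
    feats = feats.loc[kept]
    return feats, feats["ree_measured"]


def run_full_study(config: RunConfig) -> Path:
    """Execute every stage in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    cohort_csv = out / "cohort.csv"
    if config.cohort_csv is not None:
        cohort_csv = Path(config.cohort_csv)
    else:
        cohort_cfg = config.cohort or CohortConfig(seed=stage_seed(config.seed, "simulate"))
        _timed("simulate", stage_simulate, cohort_cfg, cohort_csv)

    features_csv = out / "features.csv"
    qc_csv = out / "qc.csv"
    equations_csv = out / "equations.csv"
    map_json = out / "map.json"
    map_dot = out / "map.dot"
    twist_json = out / "twist.json"
    predictions_csv = out / "predictions.csv"

    _timed("features", stage_features, cohort_csv, features_csv)
    _timed("qc", stage_qc, cohort_csv, qc_csv)
    _timed("equations", stage_equations, features_csv, equations_csv, config.equation_csv)
    _timed("map", stage_map, features_csv, map_json, map_dot, config.autocm_epochs)
    twist_cfg = config.twist or TwistConfig(seed=stage_seed(config.seed, "twist"))
    _timed("twist", stage_twist, features_csv, qc_csv, twist_json, twist_cfg)
    _timed("fit", stage_fit, features_csv, qc_csv, twist_json, predictions_csv,
           config.mlp_hidden, config.mlp_epochs, stage_seed(config.seed, "fit"))
    summary = _timed("report", stage_report, features_csv, qc_csv, equations_csv,
                     predictions_csv, out / "metrics_by_subgroup.csv", out / "method_correlations.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in
                        ("simulate", "twist", "fit")},
        "config": _config_dict(config),
        "summary": summary,
        "selected_variables": json.loads(twist_json.read_text())["selected_variables"],
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
        "elapsed_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _timed(name, fn, *args):
    t0 = time.time()
    result = fn(*args)
    log.info("stage %-10s %6.2fs", name, time.time() - t0)
    return result
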