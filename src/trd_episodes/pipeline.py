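"""End-to-end orchestration: cohort -> episodes -> regimens -> TRD ->
report, as one deterministic, manifest-producing run.

Every numeric rule is a configuration field; rerunning with identical
inputs and configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import cohort as _cohort
from . import episodes as _episodes
from . import outcomes as _outcomes
from . import regimens as _regimens
from . import trd as _trd
from .model import load_dataset, validate_dataset

log = logging.getLogger(__name__)


class Params(BaseModel):
    """Day-window and threshold parameters of the episode algorithm."""

    episode_gap: int = Field(120, gt=0)
    washout: int = Field(120, gt=0)
    eligibility_pre: int = Field(120, gt=0)
    eligibility_post: int = Field(720, gt=0)
    regimen_lock: int = Field(30, gt=0)
    grace: int = Field(60, gt=0)
    blank_threshold: int = Field(30, gt=0)
    min_failures: int = Field(2, gt=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    bonferroni_n: int | None = None
    composition_wide_exemption: bool = True


class RunConfig(BaseModel):
    input_dir: str
    codemap_path: str | None = None  # defaults to input_dir/codemaps.yaml
    out_dir: str = "trd_run"
    params: Params = Params()
    seed: int = 0


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if obj is pd.NA:
        return None
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the standard output set.

    Writes cohort.csv, cascade.json, episodes.csv, regimens.csv,
    lots.csv, report.json, tables/*.csv and manifest.json under
    ``config.out_dir``; returns the manifest.
    """
    p = config.params
    in_dir = Path(config.input_dir)
    codemap = Path(config.codemap_path or in_dir / "codemaps.yaml")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)

    ds = load_dataset(in_dir, codemap)
    issues = validate_dataset(ds)
    if issues:
        counts: dict[str, int] = {}
        for i in issues:
            counts[i.rule] = counts.get(i.rule, 0) + 1
        log.warning("validation: %d issue(s): %s", len(issues), counts)

    cohort_df, cascade = _cohort.select_cohort(
        ds, p.washout, p.eligibility_pre, p.eligibility_post
    )
    eps = _episodes.build_all_episodes(ds, cohort_df, p.episode_gap)
    regs = _regimens.build_all_regimens(
        ds, eps, p.regimen_lock, p.grace, p.blank_threshold
    )
    lots = {k: _regimens.derive_lots(v) for k, v in regs.items()}
    _trd.label_episodes(eps, regs, p.composition_wide_exemption, p.min_failures)

    episodes_df = _episodes.episodes_frame(eps)
    regimens_df = _regimens.regimens_frame(regs)
    lots_df = _regimens.lots_frame(lots)
    patients_df = ds.patients.merge(
        cohort_df[["patient_id", "age_at_index"]], on="patient_id", how="left"
    )

    report = _outcomes.build_report(
        episodes_df, patients_df, regimens_df, lots_df,
        ds.dx_claims, ds.rx_claims, ds.code_maps,
        alpha=p.alpha, bonferroni_n=p.bonferroni_n,
    )

    cohort_df.to_csv(out / "cohort.csv", index=False)
    (out / "cascade.json").write_text(
        json.dumps(cascade.as_dict(), indent=2) + "\n"
    )
    episodes_df.to_csv(out / "episodes.csv", index=False)
    regimens_df.to_csv(out / "regimens.csv", index=False)
    lots_df.to_csv(out / "lots.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2) + "\n"
    )

    tables = {
        "table1_characteristics": pd.DataFrame(report["groups"]).T.reset_index(
            names="group"),
        "table2_lot_durations": pd.DataFrame(report["lot_durations"]),
        "fig2_lot_distribution": pd.DataFrame(report["lot_distribution"]),
        "table3_class_usage": pd.DataFrame(report["class_usage"]),
        "table4_5_regimen_mix_by_lot": pd.DataFrame(report["regimen_mix_by_lot"]),
        "regimen_mono_combo": pd.DataFrame(report["regimen_mix"]),
        "table6_comorbidity": pd.DataFrame(report["comorbidity"]),
        "table7_mru": pd.DataFrame(report["mru"]),
    }
    for name, df in tables.items():
        df.to_csv(out / "tables" / f"{name}.csv", index=False)

    config_json = json.dumps(config.model_dump(), sort_keys=True)
    manifest = {
        "config": config.model_dump(),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "inputs": {
            f.name: _sha256(f)
            for f in sorted(in_dir.glob("*.csv")) + [codemap]
            if f.exists()
        },
        "validation_issues": len(issues),
        "stage_counts": {
            "patients": int(len(ds.patients)),
            "dx_claims": int(len(ds.dx_claims)),
            "rx_claims": int(len(ds.rx_claims)),
            "cascade": cascade.as_dict(),
            "included_patients": int(cohort_df["included"].sum())
            if len(cohort_df) else 0,
            "episodes": int(len(episodes_df)),
            "treated_episodes": int(episodes_df["treated"].sum())
            if len(episodes_df) else 0,
            "trd_episodes": int(episodes_df["trd"].sum())
            if len(episodes_df) else 0,
            "regimens": int(len(regimens_df)),
            "lots": int(len(lots_df)),
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=2, sort_keys=True) + "\n"
    )
    return manifest
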