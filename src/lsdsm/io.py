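"""File round-tripping: cohort CSVs, parameter JSON, prediction and
report CSVs, and run manifests.

Longitudinal CSV: ``patient_id, time, <biomarker...>`` (empty cell =
missing).  Baseline CSV: ``patient_id, <covariate...>``.  Survival CSV:
``patient_id, time, event``.  Times are in the unit of the grid step
``dt``.  Floats are written with 17 significant digits so a write/read
round trip reproduces the in-memory values exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .prediction import SurvivalCurve

__all__ = [
    "write_cohort",
    "read_cohort_frames",
    "write_predictions",
    "read_predictions",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_cohort(cohort, outdir, prefix: str = "cohort") -> dict:
    """Write a simulated cohort's three standard CSVs plus the truth bundle.

    Returns the mapping of artifact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long_df, base_df, surv_df = cohort.to_frames()
    paths = {
        "longitudinal": outdir / f"{prefix}_longitudinal.csv",
        "baseline": outdir / f"{prefix}_baseline.csv",
        "survival": outdir / f"{prefix}_survival.csv",
        "truth": outdir / f"{prefix}_truth.csv",
    }
    _write_csv(long_df, paths["longitudinal"])
    _write_csv(base_df, paths["baseline"])
    _write_csv(surv_df, paths["survival"])
    _write_csv(cohort.truth_frame(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_cohort_frames(longitudinal_path, baseline_path, survival_path):
    """Read the three standard CSVs back as DataFrames."""
    long_df = pd.read_csv(longitudinal_path)
    base_df = pd.read_csv(baseline_path)
    surv_df = pd.read_csv(survival_path)
    return long_df, base_df, surv_df


def write_predictions(curves: list[SurvivalCurve], path) -> None:
    """Write predicted curves as patient_id, landmark, horizon_time,
    survival_probability rows."""
    rows = []
    for c in curves:
        for t, s in zip(c.horizon_times, c.survival):
            rows.append(
                {
                    "patient_id": c.patient_id,
                    "landmark": c.landmark,
                    "horizon_time": t,
                    "survival_probability": s,
                }
            )
    _write_csv(pd.DataFrame(rows), path)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(path, seed, config: dict, artifacts: dict | None = None) -> dict:
    """Record seed, config hash and artifact list for reproducibility."""
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "artifact_version": 1,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "artifacts": artifacts or {},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
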