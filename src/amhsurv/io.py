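"""Readers and writers for the data and chain text formats.

Data tables are plain CSV with header ``time1,status1,time2,status2``
(one row per subject, status 1 = event, 0 = right-censored).  Chain
output is CSV with header ``iter,alpha1,beta1,alpha2,beta2,phi`` plus a
JSON sidecar carrying the config, seed, acceptance rates and posterior
summaries needed to regenerate the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import BivariateSurvivalData
from .samplers import ChainOutput, MCMCConfig

__all__ = [
    "read_survival_table",
    "write_survival_table",
    "write_chain",
    "read_chain",
    "convert_retinopathy_table",
]

_COLUMNS = ("time1", "status1", "time2", "status2")


def read_survival_table(path) -> BivariateSurvivalData:
    """Read a 4-column survival CSV, validating row by row.

    Raises ``ValueError`` naming the first offending data row (1-based)
    for nonpositive times or status values outside {0, 1}.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("time1", "time2"):
        bad = ~(pd.to_numeric(df[col], errors="coerce") > 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: nonpositive or invalid {col} at row {row}")
    for col in ("status1", "status2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: {col} outside {{0,1}} at row {row}")
    return BivariateSurvivalData(
        df["time1"].to_numpy(float), df["time2"].to_numpy(float),
        df["status1"].to_numpy(int), df["status2"].to_numpy(int),
    )


def write_survival_table(data: BivariateSurvivalData, path) -> None:
    pd.DataFrame({
        "time1": data.t1, "status1": data.delta1,
        "time2": data.t2, "status2": data.delta2,
    }).to_csv(path, index=False)


def write_chain(output: ChainOutput, path) -> Path:
    """Write kept draws as CSV and a JSON sidecar; returns sidecar path."""
    path = Path(path)
    output.to_frame().to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    meta = {
        "config": dataclasses.asdict(output.config),
        "seed": output.seed,
        "acceptance_rates": output.acceptance_rates,
        "estimates": output.estimates,
        "ci_lower": output.ci_lower,
        "ci_upper": output.ci_upper,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_chain(path) -> ChainOutput:
    """Rebuild a ChainOutput from a chain CSV and its JSON sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    draws = df[["alpha1", "beta1", "alpha2", "beta2", "phi"]].to_numpy(float)
    return ChainOutput(
        draws=draws,
        iterations=df["iter"].to_numpy(int),
        acceptance_rates=meta["acceptance_rates"],
        estimates=meta["estimates"],
        ci_lower=meta["ci_lower"],
        ci_upper=meta["ci_upper"],
        config=MCMCConfig(**meta["config"]),
        seed=meta["seed"],
    )


def convert_retinopathy_table(in_path, out_path) -> None:
    """Convert a long-format paired-eye export to the 4-column format.

    Expects columns ``id``, ``trt`` (1 = treated eye), ``time`` and
    ``status`` (as exported from the R ``survival`` package's diabetic
    retinopathy data); pairs the treated eye as margin 1 and the control
    eye as margin 2, one row per patient.
    """
    df = pd.read_csv(in_path)
    need = {"id", "trt", "time", "status"}
    if not need.issubset(df.columns):
        raise ValueError(f"{in_path}: need columns {sorted(need)}")
    rows = []
    for pid, grp in df.groupby("id", sort=True):
        trt = grp[grp.trt == 1]
        ctl = grp[grp.trt == 0]
        if len(trt) != 1 or len(ctl) != 1:
            raise ValueError(f"{in_path}: patient {pid} lacks a treated/control pair")
        rows.append({
            "time1": float(trt.time.iloc[0]), "status1": int(trt.status.iloc[0]),
            "time2": float(ctl.time.iloc[0]), "status2": int(ctl.status.iloc[0]),
        })
    pd.DataFrame(rows).to_csv(out_path, index=False)
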