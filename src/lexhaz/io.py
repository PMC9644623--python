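"""Cohort file reading/writing and configuration handling.

Cohorts are delimited text with a header; a column map renames arbitrary
input headers onto the required roles (``id``, ``entry``, ``exit``,
``event``) and any offset/gate/covariate columns.  All times are stored
internally in years; day-denominated inputs are converted at 365.24
days/year.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
import yaml

from .model import DAYS_PER_YEAR, ModelSpec

__all__ = ["read_cohort", "write_cohort", "load_config", "config_hash"]

_TIME_COLS = ("entry", "exit")


def read_cohort(path, column_map: dict | None = None, units: str = "years",
                time_columns: tuple = ("entry", "exit", "r"),
                log=None) -> pd.DataFrame:
    """Read and validate a subjects/episodes table.

    ``column_map`` maps file headers to canonical names; ``units`` is
    "years" or "days" for every column named in ``time_columns`` that is
    present.  Row-level violations are reported with line numbers (header
    = line 1).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty cohort file")
    if column_map:
        missing = [c for c in column_map if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: mapped columns not in file: {missing}")
        df = df.rename(columns=column_map)
    for col in ("id", "entry", "exit", "event"):
        if col not in df.columns:
            if col == "entry":
                df["entry"] = 0.0
                continue
            raise ValueError(f"{path}: missing required column '{col}'")
    if units == "days":
        for col in time_columns:
            if col in df.columns:
                df[col] = df[col] / DAYS_PER_YEAR
    elif units != "years":
        raise ValueError(f"unknown time units {units!r}")
    problems = []
    for col in ("entry", "exit"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[vals.isna()][:5]:
            problems.append(f"line {i + 2}: non-numeric {col}")
        df[col] = vals
    bad = df.index[~(df["entry"] < df["exit"])]
    problems += [f"line {i + 2}: exit <= entry" for i in bad[:5]]
    bad = df.index[~df["event"].isin([0, 1])]
    problems += [f"line {i + 2}: event not 0/1" for i in bad[:5]]
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    if log is not None:
        py = float((df["exit"] - df["entry"]).sum())
        log(
            f"read {path}: {df['id'].nunique()} subjects, "
            f"{int(df['event'].sum())} events, {py:.1f} person-years"
        )
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


_ALLOWED_TOP = {"data", "model", "fit", "split", "simulate", "predict", "bootstrap"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    extra = set(d) - allowed
    if extra:
        raise ValueError(f"unknown config keys in {where}: {sorted(extra)}")


def load_config(path) -> dict:
    """Load a YAML/JSON config; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _check_keys(cfg, _ALLOWED_TOP, "config")
    if "data" in cfg:
        _check_keys(cfg["data"], {"path", "columns", "units", "expand_tvc"}, "data")
    if "model" in cfg:
        cfg["model_spec"] = ModelSpec.from_dict(cfg["model"])
    if "fit" in cfg:
        _check_keys(cfg["fit"], {"n_nodes", "tol", "max_iter"}, "fit")
    if "split" in cfg:
        _check_keys(cfg["split"], {"width_days"}, "split")
    return cfg


def config_hash(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()[:12]
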