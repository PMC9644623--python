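"""Declarative model specification for log-hazard models with multiple time-scales.

A model has one *reference* time-scale, on which entry/exit are recorded,
and any number of secondary scales, each expressed as the reference time
minus a per-subject offset (e.g. attained age = follow-up time + age at
diagnosis, so the offset column holds ``-a0``; time since relapse uses the
relapse time ``r`` as offset).  A secondary scale may be *gated* by a 0/1
indicator column so that its spline contribution (and an optional jump
term) switch on only after an intermediate event.

The linear predictor for the log hazard at reference time ``t`` is::

    log h(t) = intercept
             + p0(t)                                  reference-scale spline
             + sum_s  gate_s * [ s0(t - offset_s) + jump_s ]
             + covariate terms (linear or spline-expanded)
             + optional covariate x time-scale interaction columns

Episodes are rows of a DataFrame with ``entry``, ``exit`` (reference
scale, years), ``event`` (0/1), plus offset/gate/covariate columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .splines import SplineBasis, place_knots, rcs_design

__all__ = [
    "TimeScale",
    "Covariate",
    "ModelSpec",
    "validate_episodes",
    "expand_tvc_rows",
    "build_bases",
    "design_matrix",
]

DAYS_PER_YEAR = 365.24


@dataclass(frozen=True)
class TimeScale:
    """One time-scale of the model.

    The reference scale has ``offset=None``; a secondary scale's value at
    reference time ``t`` is ``t - row[offset]``.  ``gate`` names a 0/1
    indicator column switching the scale's terms on; ``gate_jump`` adds the
    indicator itself as a step change in the log hazard (set False to force
    hazard continuity at the transition).
    """

    name: str
    offset: str | None = None
    gate: str | None = None
    n_knots: int = 4
    log: bool = False
    knots: tuple | None = None  # explicit knots (on the log scale when log=True)
    gate_jump: bool = True

    @property
    def label(self) -> str:
        return f"log({self.name})" if self.log else self.name


@dataclass(frozen=True)
class Covariate:
    """A covariate term: linear, or an RCS expansion with ``n_knots`` knots.

    ``interact_with`` names a time-scale whose spline basis is multiplied by
    the (linear) covariate, producing non-proportional-hazards columns.
    """

    column: str
    n_knots: int | None = None
    knots: tuple | None = None
    interact_with: str | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Full model: time-scales (first = reference) plus covariate terms."""

    scales: tuple
    covariates: tuple = ()

    def __post_init__(self):
        scales = tuple(self.scales)
        covariates = tuple(self.covariates)
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "covariates", covariates)
        if not scales:
            raise ValueError("model needs at least one time-scale")
        if scales[0].offset is not None or scales[0].gate is not None:
            raise ValueError("the first time-scale is the reference: no offset/gate")
        for s in scales[1:]:
            if s.offset is None:
                raise ValueError(f"secondary scale '{s.name}' needs an offset column")
        names = [s.name for s in scales]
        if len(set(names)) != len(names):
            raise ValueError("duplicate time-scale names")

    @property
    def reference(self) -> TimeScale:
        return self.scales[0]

    @property
    def secondary(self) -> tuple:
        return self.scales[1:]

    def scale_by_name(self, name: str) -> TimeScale:
        for s in self.scales:
            if s.name == name:
                return s
        raise KeyError(f"no time-scale named '{name}'")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "scales": [asdict(s) for s in self.scales],
            "covariates": [asdict(c) for c in self.covariates],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        known_s = {f for f in TimeScale.__dataclass_fields__}
        known_c = {f for f in Covariate.__dataclass_fields__}
        for block, known in (("scales", known_s), ("covariates", known_c)):
            for entry in d.get(block, []):
                extra = set(entry) - known
                if extra:
                    raise ValueError(f"unknown keys in {block} entry: {sorted(extra)}")
        scales = tuple(
            TimeScale(**{**s, "knots": tuple(s["knots"]) if s.get("knots") else None})
            for s in d["scales"]
        )
        covs = tuple(
            Covariate(**{**c, "knots": tuple(c["knots"]) if c.get("knots") else None})
            for c in d.get("covariates", [])
        )
        return cls(scales=scales, covariates=covs)


def validate_episodes(df: pd.DataFrame, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Check episode table invariants, returning the (unmodified) frame."""
    for col in ("entry", "exit", "event"):
        if col not in df.columns:
            raise ValueError(f"episode table missing column '{col}'")
    bad = df.index[~(df["entry"] < df["exit"])]
    if len(bad):
        raise ValueError(f"entry >= exit in rows {list(bad[:5])}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    if (df["entry"] < 0).any():
        raise ValueError("negative entry times")
    if spec is not None:
        for s in spec.secondary:
            if s.offset not in df.columns:
                raise ValueError(f"missing offset column '{s.offset}' for scale '{s.name}'")
            if s.gate is not None:
                if s.gate not in df.columns:
                    raise ValueError(f"missing gate column '{s.gate}' for scale '{s.name}'")
                g = df[s.gate].to_numpy()
                if not np.isin(g, [0, 1]).all():
                    raise ValueError(f"gate '{s.gate}' must be 0/1")
                on = g == 1
                v = df.loc[on, "exit"].to_numpy() - df.loc[on, s.offset].to_numpy()
                if np.any(v <= 0):
                    raise ValueError(
                        f"scale '{s.name}': non-positive value at exit for gated rows"
                    )
        for c in spec.covariates:
            if c.column not in df.columns:
                raise ValueError(f"missing covariate column '{c.column}'")
    return df


def expand_tvc_rows(
    subjects: pd.DataFrame,
    event_time_col: str = "r",
    gate_col: str = "I_RM",
) -> pd.DataFrame:
    """Expand a one-row-per-subject table into gated episodes.

    Subjects with an intermediate-event time (non-missing ``event_time_col``)
    get two rows: (entry, r] with gate 0 and event 0, then (r, exit] carrying
    the subject's event with gate 1 and offset column ``r``.  Others keep a
    single gate-0 row.  Person-time and event counts are conserved exactly.
    """
    if "entry" not in subjects.columns:
        subjects = subjects.assign(entry=0.0)
    validate_episodes(subjects)
    out = []
    for _, row in subjects.iterrows():
        r = row.get(event_time_col, np.nan)
        base = row.to_dict()
        if pd.isna(r):
            out.append({**base, gate_col: 0})
            continue
        if r > row["exit"]:
            raise ValueError(
                f"subject {row.get('id', '?')}: intermediate event at {r} "
                f"after exit {row['exit']}"
            )
        if r == row["exit"]:
            # transition at the instant of exit contributes no gated risk
            # time; the episode stays ungated (no interior split point)
            out.append({**base, gate_col: 0})
            continue
        if r <= row["entry"]:
            warnings.warn(
                f"subject {row.get('id', '?')}: intermediate event at or before "
                "entry; emitting a single gated episode",
                stacklevel=2,
            )
            out.append({**base, gate_col: 1})
            continue
        out.append({**base, "exit": r, "event": 0, gate_col: 0})
        out.append({**base, "entry": r, gate_col: 1})
    df = pd.DataFrame(out)
    df[gate_col] = df[gate_col].astype(int)
    return df.reset_index(drop=True)


def build_bases(spec: ModelSpec, episodes: pd.DataFrame) -> dict:
    """Place knots for every spline in the model from the event distribution.

    Time-scale knots use event times measured on that scale, restricted to
    episodes where the scale is active (gate on); covariate-spline knots use
    equally spaced centiles of the covariate over subjects (unique ``id``
    when present).  Explicit knots in the spec are honoured as given.
    """
    validate_episodes(episodes, spec)
    bases: dict[str, SplineBasis] = {}
    ev = episodes[episodes["event"] == 1]
    for s in spec.scales:
        if s.knots is not None:
            bases[s.name] = SplineBasis(np.asarray(s.knots, float), s.log, name=s.name)
            continue
        if s.n_knots == 0:  # constant (exponential) contribution on this scale
            continue
        rows = ev if s.gate is None else ev[ev[s.gate] == 1]
        values = rows["exit"].to_numpy(float)
        if s.offset is not None:
            values = values - rows[s.offset].to_numpy(float)
        if values.size == 0:
            raise ValueError(f"scale '{s.name}': no events to place knots on")
        bases[s.name] = place_knots(values, s.n_knots, transform=s.log, name=s.name)
    for c in spec.covariates:
        if c.n_knots is None:
            continue
        key = f"cov:{c.column}"
        if c.knots is not None:
            bases[key] = SplineBasis(np.asarray(c.knots, float), False, name=c.column)
            continue
        tab = episodes.drop_duplicates("id") if "id" in episodes.columns else episodes
        bases[key] = place_knots(
            tab[c.column].to_numpy(float), c.n_knots, transform=False, name=c.column
        )
    return bases


def coefficient_names(spec: ModelSpec, bases: dict) -> list[str]:
    """Column names of the design matrix, in design order."""
    names: list[str] = []
    for s in spec.secondary:
        if s.gate is not None and s.gate_jump:
            names.append(s.gate)
    for c in spec.covariates:
        if c.interact_with is not None:
            tgt = spec.scale_by_name(c.interact_with)
            names += [f"{c.column} x {n}" for n in bases[tgt.name].column_names(tgt.label)]
        elif c.n_knots is not None:
            names += bases[f"cov:{c.column}"].column_names(c.column)
        else:
            names.append(c.column)
    for s in spec.scales:
        if s.name in bases:
            names += bases[s.name].column_names(s.label)
    names.append("intercept")
    return names


def design_matrix(
    spec: ModelSpec,
    bases: dict,
    rows: pd.DataFrame,
    t: np.ndarray,
) -> np.ndarray:
    """Linear-predictor design rows at reference times ``t``.

    ``rows`` supplies offsets/gates/covariates (one row per element of
    ``t``); gated spline columns are exactly zero where the gate is off.
    Construction is pure: identical inputs give a bit-identical matrix.
    """
    t = np.asarray(t, dtype=float)
    n = t.size
    if len(rows) != n:
        raise ValueError("rows and t must align")
    cols: list[np.ndarray] = []
    for s in spec.secondary:
        if s.gate is not None and s.gate_jump:
            cols.append(rows[s.gate].to_numpy(float).reshape(-1, 1))
    for c in spec.covariates:
        x = rows[c.column].to_numpy(float)
        if c.interact_with is not None:
            tgt = spec.scale_by_name(c.interact_with)
            v = t if tgt.offset is None else t - rows[tgt.offset].to_numpy(float)
            cols.append(x[:, None] * rcs_design(v, bases[tgt.name]))
        elif c.n_knots is not None:
            cols.append(rcs_design(x, bases[f"cov:{c.column}"]))
        else:
            cols.append(x.reshape(-1, 1))
    # reference-scale spline
    if spec.reference.name in bases:
        cols.append(rcs_design(t, bases[spec.reference.name]))
    for s in spec.secondary:
        basis = bases.get(s.name)
        if basis is None:
            continue
        v = t - rows[s.offset].to_numpy(float)
        g = np.ones(n) if s.gate is None else rows[s.gate].to_numpy(float)
        on = g != 0
        block = np.zeros((n, basis.n_basis))
        if on.any():
            if basis.log_transform and np.any(v[on] <= 0):
                raise ValueError(
                    f"scale '{s.name}': log basis needs positive values for gated rows"
                )
            block[on] = g[on, None] * rcs_design(v[on], basis)
        cols.append(block)
    cols.append(np.ones((n, 1)))
    return np.hstack(cols)
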