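"""Post-fit predictions: rates, rate ratios, survival, bootstrap intervals.

Rates and rate ratios get delta-method confidence intervals on the log
scale (the linear predictor is linear in the coefficients, so the gradient
is just the design row).  Survival proportions are obtained by integrating
the fitted hazard along a piecewise-constant covariate path with the same
Gauss-Legendre rule used in fitting; their intervals use the
bias-corrected percentile bootstrap, resampling whole subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import design_matrix
from .splines import rcs_design

__all__ = [
    "CovariatePath",
    "PredictionResult",
    "predict_hazard",
    "predict_rate_ratio",
    "predict_survival",
    "conditional_survival",
    "bca_bootstrap",
]

Z975 = 1.959963984540054


@dataclass(frozen=True)
class CovariatePath:
    """Piecewise-constant covariate/gate trajectory on the reference scale.

    ``covariates`` holds the values from time 0 (gates that are initially
    off must be 0 here); each entry of ``changes`` is ``(time, updates)``
    applied from that time onwards, e.g. ``(r, {"I_RM": 1, "r": r})`` for
    an intermediate event at ``r``.
    """

    covariates: dict
    changes: tuple = ()
    horizon: float | None = None

    def __post_init__(self):
        chg = tuple((float(t), dict(u)) for t, u in self.changes)
        object.__setattr__(self, "changes", tuple(sorted(chg, key=lambda c: c[0])))
        times = [t for t, _ in self.changes]
        if any(t <= 0 for t in times) or np.any(np.diff(times) <= 0):
            raise ValueError("change-points must be strictly increasing and > 0")
        if self.horizon is not None and times and times[-1] >= self.horizon:
            raise ValueError("change-points must lie within (0, horizon)")

    def state_at(self, t: float) -> dict:
        """Covariate values in effect at time ``t`` (changes act from t on)."""
        row = dict(self.covariates)
        for ct, updates in self.changes:
            if ct <= t:
                row.update(updates)
        return row

    def rows_for(self, times) -> pd.DataFrame:
        return pd.DataFrame([self.state_at(float(t)) for t in np.atleast_1d(times)])


@dataclass
class PredictionResult:
    """A prediction grid with point estimates and 95% bounds."""

    grid: np.ndarray
    estimate: np.ndarray
    lo: np.ndarray | None
    hi: np.ndarray | None
    scale: str  # "rate per 1000 person-years" | "ratio" | "proportion"

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.grid, "estimate": self.estimate}
        if self.lo is not None:
            d["lo"], d["hi"] = self.lo, self.hi
        out = pd.DataFrame(d)
        out["scale"] = self.scale
        return out


def _extrapolation_warning(model, t):
    ref = model.bases_.get(model.spec.reference.name)
    if ref is None:  # constant-hazard reference scale
        return
    u = np.log(np.asarray(t, float)) if ref.log_transform else np.asarray(t, float)
    if np.any(u > ref.knots[-1]) or np.any(u < ref.knots[0]):
        warnings.warn(
            "prediction grid extends beyond the boundary knots of the "
            f"reference scale; the spline is linearly extrapolated there",
            stacklevel=3,
        )


def predict_hazard(model, path: CovariatePath, grid) -> PredictionResult:
    """Hazard rate per 1000 person-years along the reference scale.

    Delta-method 95% CI on the log scale: ``var = z' V z`` with ``z`` the
    design row, exponentiated.
    """
    grid = np.atleast_1d(np.asarray(grid, float))
    _extrapolation_warning(model, grid)
    rows = path.rows_for(grid)
    Z = design_matrix(model.spec, model.bases_, rows, grid)
    lp = Z @ model.coef_
    se = np.sqrt(np.einsum("ij,jk,ik->i", Z, model.cov_, Z))
    return PredictionResult(
        grid=grid,
        estimate=1000.0 * np.exp(lp),
        lo=1000.0 * np.exp(lp - Z975 * se),
        hi=1000.0 * np.exp(lp + Z975 * se),
        scale="rate per 1000 person-years",
    )


def predict_rate_ratio(model, grid, scale: str | None = None) -> PredictionResult:
    """Rate ratio gated-on vs gated-off as a function of the secondary scale.

    Under proportional hazards ``RR(t2) = exp(jump + s0(t2))`` — independent
    of the reference time, the event time and the covariates.  Requesting
    this for a specification with covariate-time interactions is an error:
    use :func:`predict_hazard` at explicit time pairs instead.
    """
    spec = model.spec
    if any(c.interact_with is not None for c in spec.covariates):
        raise ValueError(
            "rate ratio is time-scale-dependent under non-proportional hazards; "
            "use predict_hazard at explicit (reference time, event time) pairs"
        )
    gated = [s for s in spec.secondary if s.gate is not None]
    if scale is None:
        if len(gated) != 1:
            raise ValueError("specify the gated scale by name")
        ts = gated[0]
    else:
        ts = spec.scale_by_name(scale)
        if ts.gate is None:
            raise ValueError(f"scale '{ts.name}' has no gate")
    grid = np.atleast_1d(np.asarray(grid, float))
    basis = model.bases_[ts.name]
    names = model.coef_names_
    p = len(names)
    G = np.zeros((grid.size, p))
    if ts.gate_jump:
        G[:, names.index(ts.gate)] = 1.0
    spline_cols = [names.index(n) for n in basis.column_names(ts.label)]
    if basis.log_transform and np.any(grid <= 0):
        raise ValueError("log-scale basis cannot be evaluated at t2 <= 0")
    # with all-positive knots every basis column vanishes at t2 = 0, so
    # RR(0) = exp(jump) falls out automatically
    G[:, spline_cols] = rcs_design(grid, basis)
    lp = G @ model.coef_
    se = np.sqrt(np.einsum("ij,jk,ik->i", G, model.cov_, G))
    return PredictionResult(
        grid=grid,
        estimate=np.exp(lp),
        lo=np.exp(lp - Z975 * se),
        hi=np.exp(lp + Z975 * se),
        scale="ratio",
    )


def _knot_times_along_path(model, path: CovariatePath, horizon: float) -> list:
    """Reference-scale times where the integrand loses smoothness (spline
    knots of the reference scale, and of gated scales once active)."""
    cuts: list[float] = []
    ref = model.bases_.get(model.spec.reference.name)
    if ref is not None:
        k = np.exp(ref.knots) if ref.log_transform else ref.knots
        cuts += [float(v) for v in k]
    states = [(0.0, path.covariates)] + [(t, path.state_at(t)) for t, _ in path.changes]
    for since, state in states:
        for s in model.spec.secondary:
            basis = model.bases_.get(s.name)
            if basis is None or s.offset not in state:
                continue
            if s.gate is not None and not state.get(s.gate, 0):
                continue
            k = np.exp(basis.knots) if basis.log_transform else basis.knots
            cuts += [float(state[s.offset] + v) for v in k if since < state[s.offset] + v]
    return [c for c in cuts if 0.0 < c < horizon]


def _cumulative_hazard_path(model, path: CovariatePath, times, n_nodes=30):
    """Cumulative hazard at each requested time, accumulated piecewise
    between path change-points and spline-knot crossings."""
    times = np.atleast_1d(np.asarray(times, float))
    if np.any(times < 0):
        raise ValueError("negative times")
    change_ts = [t for t, _ in path.changes]
    knot_ts = _knot_times_along_path(model, path, float(times.max(initial=0.0)))
    breaks = np.unique(np.concatenate([[0.0], times, change_ts, knot_ts]))
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    cum = {0.0: 0.0}
    acc = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        half, mid = 0.5 * (b - a), 0.5 * (b + a)
        nodes = mid + half * x
        state = path.state_at(a + 1e-12 * max(b, 1.0))  # regime of (a, b)
        rows = pd.DataFrame([state] * n_nodes)
        Z = design_matrix(model.spec, model.bases_, rows, nodes)
        acc += half * float(w @ np.exp(Z @ model.coef_))
        cum[b] = acc
    return np.array([cum[t] for t in times])


def predict_survival(model, path: CovariatePath, grid, n_nodes: int = 30) -> PredictionResult:
    """Survival proportion ``S(t) = exp(-int_0^t h(u; path) du)``.

    The integral is accumulated piecewise between the path's change-points
    (S stays continuous even where the hazard jumps).  A non-monotone
    result is an error, never silently clipped.
    """
    grid = np.atleast_1d(np.asarray(grid, float))
    S = np.exp(-_cumulative_hazard_path(model, path, grid, n_nodes))
    order = np.argsort(grid)
    if np.any(np.diff(S[order]) > 1e-12):
        raise ValueError("survival is non-monotone along the grid (numerical fault)")
    return PredictionResult(grid=grid, estimate=S, lo=None, hi=None, scale="proportion")


def conditional_survival(model, path: CovariatePath, from_time: float, deltas,
                         n_nodes: int = 30) -> PredictionResult:
    """Survival ``S(from_time + delta) / S(from_time)`` along the path.

    The default reading of "survival since the intermediate event": the
    ratio of unconditional survival proportions along a path in which the
    event happens at ``from_time``.
    """
    deltas = np.atleast_1d(np.asarray(deltas, float))
    times = np.concatenate([[from_time], from_time + deltas])
    H = _cumulative_hazard_path(model, path, times, n_nodes)
    S = np.exp(-(H[1:] - H[0]))
    return PredictionResult(grid=deltas, estimate=S, lo=None, hi=None, scale="proportion")


def bca_bootstrap(statistic, data: pd.DataFrame, B: int = 1000, seed: int = 0,
                  group: str = "id", accelerated: bool = False,
                  max_failures: float = 0.05):
    """Bias-corrected percentile bootstrap interval(s) for ``statistic``.

    Resampling is by whole subject (all episodes of a subject move
    together); resampled subjects get fresh ids so downstream grouping
    treats repeated draws as distinct.  ``statistic`` maps a data frame to
    a scalar or vector.  With ``accelerated=True`` the jackknife
    acceleration term is added (BCa proper); the default matches the plain
    bias-corrected method.  Deterministic given ``seed``.

    Returns ``(lo, hi)`` arrays (scalars for scalar statistics).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    point = np.atleast_1d(np.asarray(statistic(data), float))
    if group in data.columns:
        groups = [g for _, g in data.groupby(group, sort=True)]
    else:
        groups = [data.iloc[[i]] for i in range(len(data))]
    n = len(groups)
    reps, failures = [], 0
    for _ in range(B):
        draw = rng.integers(0, n, size=n)
        parts = []
        for new_id, j in enumerate(draw):
            g = groups[j].copy()
            if group in g.columns:
                g[group] = new_id
            parts.append(g)
        sample = pd.concat(parts, ignore_index=True)
        try:
            reps.append(np.atleast_1d(np.asarray(statistic(sample), float)))
        except Exception:
            failures += 1
    if failures > max_failures * B:
        raise ValueError(f"{failures}/{B} bootstrap replicates failed")
    if failures:
        warnings.warn(f"dropped {failures} failed bootstrap replicates", stacklevel=2)
    boot = np.vstack(reps)
    lo = np.empty(point.size)
    hi = np.empty(point.size)
    for k in range(point.size):
        bk = boot[:, k]
        if np.all(bk == bk[0]):
            lo[k] = hi[k] = bk[0]
            continue
        frac = np.mean(bk < point[k])
        frac = min(max(frac, 0.5 / len(bk)), 1 - 0.5 / len(bk))
        z0 = norm.ppf(frac)
        if accelerated:
            jack = []
            for i in range(n):
                sub = pd.concat(groups[:i] + groups[i + 1:], ignore_index=True)
                jack.append(np.atleast_1d(np.asarray(statistic(sub), float))[k])
            jack = np.asarray(jack)
            d = jack.mean() - jack
            denom = 6.0 * (np.sum(d**2) ** 1.5)
            a = np.sum(d**3) / denom if denom > 0 else 0.0
        else:
            a = 0.0
        alphas = []
        for z in (-Z975, Z975):
            zadj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
            alphas.append(norm.cdf(zadj))
        lo[k], hi[k] = np.quantile(bk, alphas)
    if point.size == 1:
        return float(lo[0]), float(hi[0])
    return lo, hi
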