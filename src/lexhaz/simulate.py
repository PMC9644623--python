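"""Synthetic cohorts with a known two-time-scale log-hazard structure.

Two generators mirror the study designs the model is meant for:

* an illness-death cohort in which an intermediate event (relapse or
  metastasis, "RM") switches on a second time-scale, with administrative
  censoring at 10 years of follow-up; and
* a matched cohort in which each exposed case shares its age at diagnosis
  and sex with four unexposed comparators, the reference scale is attained
  age, time-since-diagnosis applies only to the exposed, and the first 30
  days of follow-up are excluded (delayed entry).

Truth hazards are smooth parametric forms (power/Gompertz per scale with a
saturating-exponential secondary-scale effect), so recovery targets are
well defined independently of any knot placement.  Event times are drawn
by inverting the path-specific cumulative hazard, analytically where a
closed form exists and otherwise by bracketed root-finding on the
quadrature-evaluated integral.  All draws come from one seeded generator,
so a cohort is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import DAYS_PER_YEAR

__all__ = [
    "TvcTruth",
    "MatchedTruth",
    "invert_survival",
    "simulate_tvc_cohort",
    "simulate_matched_cohort",
]


def invert_survival(cumulative_hazard, u: float, horizon: float, tol: float = 1e-10):
    """Solve ``H(t) = -log(u)`` for the event time ``t``.

    ``cumulative_hazard`` is the path-specific ``H`` with ``H(0) = 0``;
    returns ``None`` (administrative censoring) when the event does not
    occur before ``horizon``.  As ``u -> 1`` the solution tends to 0.
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must be in (0, 1)")
    target = -np.log(u)
    if cumulative_hazard(horizon) < target:
        return None
    return brentq(lambda t: cumulative_hazard(t) - target, 0.0, horizon,
                  xtol=tol, rtol=8.9e-16)


def _bisect_invert(log_hazard, start, horizon, target, n_nodes=40, iters=60):
    """Vectorised inversion of quadrature-evaluated cumulative hazards.

    Solves ``int_start^t exp(log_hazard(u)) du = target`` per subject;
    subjects whose hazard never accumulates to the target by ``horizon``
    get NaN (censored).  ``log_hazard(t)`` must broadcast over arrays.
    """
    x, w = np.polynomial.legendre.leggauss(n_nodes)

    def H(upper):
        half = 0.5 * (upper - start)
        nodes = (0.5 * (upper + start))[:, None] + half[:, None] * x[None, :]
        return half * (np.exp(log_hazard(nodes)) @ w)

    censored = H(horizon) < target
    lo = np.full_like(start, 0.0) + start
    hi = np.asarray(horizon, float) * np.ones_like(start)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = H(mid) < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    t = 0.5 * (lo + hi)
    return np.where(censored, np.nan, t)


# ---------------------------------------------------------------------------
# illness-death / time-varying covariate scenario


@dataclass(frozen=True)
class TvcTruth:
    """True hazards for the illness-death cohort.

    Pre-event mortality is a power-of-time (Weibull-type) hazard on time
    since entry; the intermediate event multiplies it by
    ``exp(gate_jump + s(t2))`` with ``s(t2) = s_rise (1 - e^(-t2/s_tau)) -
    s_slope t2`` (rises then falls, s(0) = 0, so the jump is the rate
    ratio at zero time since the event).  The event-incidence hazard is
    Weibull with decreasing shape, putting the median time to the event
    around 2.4 years among those who experience it within follow-up.
    """

    base_level: float = -4.93      # log mortality hazard at t1 = 1
    base_power: float = 0.2        # exponent of t1
    gate_jump: float = 3.19
    s_rise: float = 1.05
    s_tau: float = 1.5
    s_slope: float = 0.09
    beta_age: float = 0.02         # per year of age over 50
    beta_horm: float = 0.32
    rm_shape: float = 0.65
    rm_scale: float = 18.0         # Lambda(t) = (t / scale)^shape
    censor: float = 10.0
    age_mean: float = 55.0
    age_sd: float = 12.0
    horm_prevalence: float = 0.33

    def s(self, t2):
        return self.s_rise * (1.0 - np.exp(-t2 / self.s_tau)) - self.s_slope * t2

    def covariate_lp(self, age, horm):
        return self.beta_age * (age - 50.0) + self.beta_horm * horm

    def log_hazard(self, t1, t2, gate, age, horm):
        lp = self.base_level + self.base_power * np.log(t1) + self.covariate_lp(age, horm)
        return lp + gate * (self.gate_jump + self.s(np.where(gate > 0, t2, 1.0)))


def simulate_tvc_cohort(truth: TvcTruth | None = None, n: int = 3000,
                        seed: int = 0) -> pd.DataFrame:
    """One row per subject: id, exit, event, r (NaN = no intermediate event),
    age, hormon.  Expand with :func:`lexhaz.model.expand_tvc_rows` before
    fitting."""
    truth = truth or TvcTruth()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(truth.age_mean, truth.age_sd, n), 25.0, 90.0)
    horm = (rng.random(n) < truth.horm_prevalence).astype(int)
    cov = truth.covariate_lp(age, horm)
    # intermediate-event time: Weibull inversion
    u_rm = rng.random(n)
    t_rm = truth.rm_scale * (-np.log(u_rm)) ** (1.0 / truth.rm_shape)
    # pre-event death: power hazard, closed-form inverse
    g1 = truth.base_power + 1.0
    u_d = rng.random(n)
    t_d0 = (g1 * -np.log(u_d) / np.exp(truth.base_level + cov)) ** (1.0 / g1)
    had_rm = t_rm < np.minimum(t_d0, truth.censor)
    exit_ = np.minimum(t_d0, truth.censor)
    event = (t_d0 < truth.censor).astype(int)
    r = np.where(had_rm, t_rm, np.nan)
    # post-event death: numeric inversion from r
    if had_rm.any():
        idx = np.flatnonzero(had_rm)
        start = t_rm[idx]
        target = -np.log(rng.random(idx.size))
        covI = cov[idx]

        def lh(t):
            t2 = t - start[:, None]
            return (truth.base_level + truth.base_power * np.log(t)
                    + covI[:, None] + truth.gate_jump + truth.s(t2))

        t_d1 = _bisect_invert(lh, start, truth.censor, target)
        exit_[idx] = np.where(np.isnan(t_d1), truth.censor, t_d1)
        event[idx] = (~np.isnan(t_d1)).astype(int)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "entry": 0.0,
            "exit": exit_,
            "event": event,
            "r": r,
            "age": age,
            "hormon": horm,
        }
    )


# ---------------------------------------------------------------------------
# matched-cohort scenario


@dataclass(frozen=True)
class MatchedTruth:
    """True hazards for the matched cohort on the attained-age scale.

    Background mortality is Gompertz in attained age; exposure multiplies
    it by ``exp(exposure_jump + v(t2))`` with ``v(t2) = -v_drop (1 -
    e^(-t2/v_tau))``: a high early excess that settles to
    ``exp(exposure_jump - v_drop)`` — about 2.5 with the defaults.
    """

    gompertz_level: float = -3.244     # log hazard at attained age 70
    gompertz_slope: float = 0.095      # per year of attained age
    beta_sex: float = -0.33            # women (I_sex = 1) vs men
    exposure_jump: float = 1.56
    v_drop: float = 0.64
    v_tau: float = 0.8
    n_comparators: int = 4
    entry_delay: float = 30.0 / DAYS_PER_YEAR
    follow_up: float = 10.0
    a0_mean: float = 70.0
    a0_sd: float = 10.0
    a0_range: tuple = (40.0, 92.0)
    p_female: float = 0.45

    def v(self, t2):
        return -self.v_drop * (1.0 - np.exp(-t2 / self.v_tau))

    def log_hazard(self, t1, a0, exposed, sex):
        lp = (self.gompertz_level + self.gompertz_slope * (t1 - 70.0)
              + self.beta_sex * sex)
        return lp + exposed * (self.exposure_jump + self.v(t1 - a0))


def simulate_matched_cohort(truth: MatchedTruth | None = None, n_cases: int = 5000,
                            seed: int = 0) -> pd.DataFrame:
    """Matched cohort on the attained-age reference scale.

    Each case gets ``n_comparators`` comparators sharing age at diagnosis
    ``a0`` and sex; everyone enters at ``a0 + 30 days`` (delayed entry) and
    is administratively censored ``follow_up`` years after diagnosis.
    Columns: id, set, entry, exit, event, a0, I_MPN, I_sex.
    """
    truth = truth or MatchedTruth()
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    a0 = np.clip(rng.normal(truth.a0_mean, truth.a0_sd, n_cases), *truth.a0_range)
    sex = (rng.random(n_cases) < truth.p_female).astype(int)
    m = truth.n_comparators
    a0_all = np.concatenate([a0, np.repeat(a0, m)])
    sex_all = np.concatenate([sex, np.repeat(sex, m)])
    exposed = np.concatenate([np.ones(n_cases, int), np.zeros(n_cases * m, int)])
    set_id = np.concatenate([np.arange(n_cases), np.repeat(np.arange(n_cases), m)])
    entry = a0_all + truth.entry_delay
    horizon = a0_all + truth.follow_up
    target = -np.log(rng.random(a0_all.size))
    # comparators: Gompertz with closed-form conditional inverse
    comp = exposed == 0
    b = truth.gompertz_slope
    A = np.exp(truth.gompertz_level + truth.beta_sex * sex_all[comp])
    e_ent = np.exp(b * (entry[comp] - 70.0))
    t_comp = 70.0 + np.log(e_ent + b * target[comp] / A) / b
    exit_ = np.empty(a0_all.size)
    exit_[comp] = np.minimum(t_comp, horizon[comp])
    event = np.empty(a0_all.size, int)
    event[comp] = (t_comp < horizon[comp]).astype(int)
    # cases: numeric inversion (the diagnosis-time effect has no closed form)
    idx = np.flatnonzero(exposed == 1)

    def lh(t):
        return truth.log_hazard(t, a0_all[idx][:, None], 1.0, sex_all[idx][:, None])

    t_case = _bisect_invert(lh, entry[idx], horizon[idx], target[idx])
    exit_[idx] = np.where(np.isnan(t_case), horizon[idx], t_case)
    event[idx] = (~np.isnan(t_case)).astype(int)
    return pd.DataFrame(
        {
            "id": np.arange(a0_all.size),
            "set": set_id,
            "entry": entry,
            "exit": exit_,
            "event": event,
            "a0": a0_all,
            "I_MPN": exposed,
            "I_sex": sex_all,
        }
    )
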