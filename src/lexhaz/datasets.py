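"""Example data: the Rotterdam breast-cancer cohort.

The 2,982-subject Rotterdam cohort (primary surgery 1978-1993, follow-up
for relapse/metastasis and death) ships with the R ``survival`` package;
:func:`load_rotterdam` extracts it at run time via ``Rscript`` and applies
the standard analysis preparation:

* follow-up censored at 10 years post surgery;
* the 43 known-anomalous subjects (no recorded recurrence but a death
  date beyond their disease-free follow-up) are censored at their
  disease-free time;
* times converted from days to years at 365.24 days/year.

The prepared table has one row per subject: ``id``, ``entry`` (0),
``exit``, ``event``, ``r`` (time of relapse/metastasis, NaN if none),
``age`` (at surgery) and ``hormon`` (hormonal-therapy indicator), ready
for :func:`lexhaz.model.expand_tvc_rows`.
"""

from __future__ import annotations

import io
import subprocess

import numpy as np
import pandas as pd

from .model import DAYS_PER_YEAR

__all__ = ["load_rotterdam"]

_R_SNIPPET = "library(survival); write.csv(rotterdam, stdout(), row.names=FALSE)"


def _raw_rotterdam() -> pd.DataFrame:
    try:
        out = subprocess.run(
            ["Rscript", "-e", _R_SNIPPET],
            capture_output=True, text=True, check=True,
        ).stdout
    except (OSError, subprocess.CalledProcessError) as exc:
        raise RuntimeError(
            "could not extract the Rotterdam cohort from the R 'survival' "
            "package (is Rscript with survival installed?)"
        ) from exc
    return pd.read_csv(io.StringIO(out))


def load_rotterdam(follow_up_years: float = 10.0) -> pd.DataFrame:
    raw = _raw_rotterdam()
    cap = follow_up_years * DAYS_PER_YEAR
    dtime = raw["dtime"].to_numpy(float)
    death = raw["death"].to_numpy(int)
    rtime = raw["rtime"].to_numpy(float)
    recur = raw["recur"].to_numpy(int)
    # deaths recorded beyond disease-free follow-up without a recurrence:
    # censor at the disease-free time
    odd = (recur == 0) & (death == 1) & (dtime > rtime)
    fu = np.where(odd, rtime, dtime)
    ev = np.where(odd, 0, death)
    exit_ = np.minimum(fu, cap)
    event = np.where(fu <= cap, ev, 0).astype(int)
    has_rm = (recur == 1) & (rtime <= exit_)
    r = np.where(has_rm, rtime, np.nan)
    # relapse recorded on the exit date: relapse precedes death/censoring,
    # so keep the subject's end state post-relapse by backdating the
    # transition one day (the post-relapse episode gets one day of exposure)
    same_day = has_rm & (rtime >= exit_)
    r = np.where(same_day, exit_ - 1.0, r)
    df = pd.DataFrame(
        {
            "id": raw["pid"].to_numpy(int),
            "entry": 0.0,
            "exit": exit_ / DAYS_PER_YEAR,
            "event": event,
            "r": r / DAYS_PER_YEAR,
            "age": raw["age"].to_numpy(float),
            "hormon": raw["hormon"].to_numpy(int),
        }
    )
    return df
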