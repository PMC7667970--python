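"""Mucus growth-rate estimation from repeated ex vivo thickness measurements.

In the explant chamber the mucus surface is tracked with 10-µm beads and a
micromanipulator: thickness is read every 15 min at up to five locations
for up to 45 min.  Net mucus growth (secretion minus proteolytic
processing) is summarized as the slope of a pooled ordinary-least-squares
fit of thickness against time, in µm/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GrowthRateResult", "fit_growth_rate"]


@dataclass
class GrowthRateResult:
    rate_um_per_min: float
    initial_thickness_um: float
    rate_std_error: float
    r_squared: float
    n_obs: int
    used_intercept: bool  # no t=0 measurement: initial thickness is the fitted intercept
    mouse_id: str = ""


def fit_growth_rate(
    series: pd.DataFrame, per_location: bool = False, mouse_id: str = ""
) -> GrowthRateResult:
    """OLS slope of thickness on time, pooling all locations.

    ``series`` is tidy with columns ``time_min`` and ``thickness_um``
    (``location`` optional).  The initial thickness is the mean measured
    thickness at t = 0 when present, otherwise the fitted intercept
    (flagged via ``used_intercept``).  With ``per_location`` the slope is
    instead the average of per-location slopes (the pooled standard error
    and r² are still reported from the pooled fit).
    """
    t = np.asarray(series["time_min"], dtype=float)
    y = np.asarray(series["thickness_um"], dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("need at least two distinct time points")

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        # perfectly constant thickness: zero growth, exact fit
        slope, intercept, se, r2 = 0.0, float(y[0]), 0.0, 1.0
    else:
        fit = stats.linregress(t, y)
        slope, intercept, se = float(fit.slope), float(fit.intercept), float(fit.stderr)
        resid = y - (intercept + slope * t)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot

    if per_location and "location" in series.columns:
        slopes = []
        for _, grp in series.groupby("location"):
            tt = np.asarray(grp["time_min"], dtype=float)
            yy = np.asarray(grp["thickness_um"], dtype=float)
            if np.unique(tt).size >= 2 and np.ptp(yy) > 0:
                slopes.append(stats.linregress(tt, yy).slope)
            else:
                slopes.append(0.0)
        slope = float(np.mean(slopes))

    at_zero = t == 0
    if at_zero.any():
        initial = float(y[at_zero].mean())
        used_intercept = False
    else:
        initial = intercept
        used_intercept = True
    return GrowthRateResult(
        rate_um_per_min=slope,
        initial_thickness_um=initial,
        rate_std_error=se,
        r_squared=min(max(r2, 0.0), 1.0),
        n_obs=t.size,
        used_intercept=used_intercept,
        mouse_id=mouse_id or (str(series["mouse"].iloc[0]) if "mouse" in series else ""),
    )
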