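"""Exponential-decay modelling of the CS-window freezing curve.

Freezing during prolonged CS presentation is modelled as
``y(t) = y0 * exp(-b t)`` with t = 0 at CS onset (bin 13) and one unit
per 30-s bin.  Taking natural logs gives a straight line,
``log y(t) = log y0 - b t``, fitted by ordinary least squares — so the
decay rate is minus the slope and the CS-onset level is the
exponentiated intercept.  Sustained (bins 18-24) and phasic (bins 13-17)
mean freezing are computed on the raw, untransformed percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .session import FreezingSession, cs_window, phasic_window, sustained_window

#: feature columns used for phenotype clustering, in canonical order
FEATURE_COLUMNS = ("sustained_mean", "b", "y0")

#: default floor (percent) applied before the log transform; 0% bins
#: would otherwise have -inf log-freezing
DEFAULT_FLOOR_EPS = 0.1


@dataclass(frozen=True)
class CurveFit:
    """Fitted decay parameters and component means for one animal-session.

    ``b`` is the decay rate per 30-s bin (positive = freezing decays);
    ``y0`` the fitted freezing at CS onset in percent.  ``r_squared`` is
    the coefficient of determination of the log-linear fit (the scale on
    which the model is estimated).  ``degenerate`` flags curves where
    every CS bin sat at the log floor, for which a flat fit with b = 0
    and r_squared = 0 is returned.
    """

    animal_id: str
    session: str
    y0: float
    b: float
    sustained_mean: float
    phasic_mean: float
    r_squared: float
    n_bins: int = 12
    degenerate: bool = False


def fit_loglinear(y, floor_eps: float = DEFAULT_FLOOR_EPS
                  ) -> tuple[float, float, float, bool]:
    """OLS fit of ``log y(t) = log y0 - b t`` to a positive curve.

    Values below ``floor_eps`` are clipped to ``floor_eps`` before the
    log transform so that 0% bins have bounded influence.  Returns
    ``(y0, b, r_squared, degenerate)`` where degenerate means every
    value sat at the floor (flat fit, b = 0, r_squared = 0).
    """
    if floor_eps <= 0:
        raise ValueError("floor_eps must be > 0")
    y = np.asarray(y, dtype=float)
    y_floored = np.maximum(y, floor_eps)
    t = np.arange(y.size, dtype=float)
    log_y = np.log(y_floored)

    if np.all(y <= floor_eps):
        return floor_eps, 0.0, 0.0, True
    if np.ptp(log_y) == 0.0:
        # constant curve: zero slope exactly; R^2 undefined (SS_tot = 0)
        return float(np.exp(log_y[0])), 0.0, 0.0, False
    res = stats.linregress(t, log_y)
    return float(np.exp(res.intercept)), float(-res.slope), float(res.rvalue**2), False


def fit_decay(session: FreezingSession, floor_eps: float = DEFAULT_FLOOR_EPS) -> CurveFit:
    """Fit the log-linear decay model to one session's CS window."""
    y = cs_window(session)
    y0, b, r2, degenerate = fit_loglinear(y, floor_eps=floor_eps)
    return CurveFit(
        animal_id=session.animal_id,
        session=session.session,
        y0=y0,
        b=b,
        sustained_mean=float(np.mean(sustained_window(session))),
        phasic_mean=float(np.mean(phasic_window(session))),
        r_squared=r2,
        n_bins=y.size,
        degenerate=degenerate,
    )


def fit_cohort(sessions: Sequence[FreezingSession],
               floor_eps: float = DEFAULT_FLOOR_EPS) -> list[CurveFit]:
    """Fit every session in a cohort."""
    return [fit_decay(s, floor_eps=floor_eps) for s in sessions]


def build_features(fits: Sequence[CurveFit]) -> pd.DataFrame:
    """Assemble the clustering feature matrix for one session.

    Returns a DataFrame indexed by ``animal_id`` with columns exactly
    ``(sustained_mean, b, y0)`` in input order.  Degenerate (unfittable)
    curves are excluded with a warning.
    """
    if not fits:
        raise ValueError("no curve fits supplied")
    sessions = {f.session for f in fits}
    if len(sessions) > 1:
        raise ValueError(f"feature matrix must come from a single session, got {sorted(sessions)}")
    kept: list[CurveFit] = []
    for f in fits:
        if f.degenerate:
            warnings.warn(
                f"animal {f.animal_id!r}: degenerate flat fit excluded from feature matrix",
                stacklevel=2,
            )
            continue
        kept.append(f)
    ids = [f.animal_id for f in kept]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate animal_id in curve fits: {dupes}")
    return pd.DataFrame(
        {
            "sustained_mean": [f.sustained_mean for f in kept],
            "b": [f.b for f in kept],
            "y0": [f.y0 for f in kept],
        },
        index=pd.Index(ids, name="animal_id"),
    )


def fits_to_frame(fits: Sequence[CurveFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"animal_id": f.animal_id, "session": f.session, "y0": f.y0, "b": f.b,
             "sustained_mean": f.sustained_mean, "phasic_mean": f.phasic_mean,
             "r_squared": f.r_squared}
            for f in fits
        ]
    )


def write_fits(fits: Sequence[CurveFit], path: str | Path) -> None:
    fits_to_frame(fits).to_csv(path, index=False, float_format="%.17g")


def read_fits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
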