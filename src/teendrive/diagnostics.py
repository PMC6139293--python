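"""Historical-fit diagnostics: Theil inequality decomposition, RMSE, MAPE.

The Theil decomposition (Sterman's form, standard in system dynamics)
partitions the mean squared error between a simulated series S and an
observed series A into three fractions:

    MSE = (S.mean - A.mean)**2 + (s_S - s_A)**2 + 2*(1 - r)*s_S*s_A
    Um  = bias fraction, Us = unequal-variance fraction,
    Uc  = unequal-covariation fraction,  Um + Us + Uc = 1,

with population (1/n) standard deviations and Pearson correlation r.  A large
Um flags systematic bias; error concentrated in Uc means the model tracks the
trend but diverges point-by-point, which is typically unsystematic noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Trajectory

__all__ = ["TheilDecomposition", "theil", "rmse", "mape", "fit_report"]


@dataclass(frozen=True)
class TheilDecomposition:
    """MSE decomposition plus scale diagnostics for one series pair.

    ``um``/``us``/``uc`` are None when MSE = 0 (perfect fit), where the
    decomposition is undefined by convention.  ``mape_excluded`` counts
    points dropped from MAPE because the actual value was zero.
    """

    um: float | None
    us: float | None
    uc: float | None
    rmse: float
    mape: float | None
    mape_excluded: int = 0

    @property
    def mse(self) -> float:
        return self.rmse**2


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D series")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series must be finite")
    return arr


def rmse(actual, simulated) -> float:
    """Root mean squared error between two equal-length series."""
    a, s = _as_series(actual), _as_series(simulated)
    if len(a) != len(s) or len(a) < 1:
        raise ValueError("series must have equal length >= 1")
    return float(np.sqrt(np.mean((s - a) ** 2)))


def mape(actual, simulated, *, return_excluded: bool = False):
    """Mean absolute percentage error, in percent.

    Points where the actual value is zero are excluded (the relative error is
    undefined there); the exclusion count is available via
    ``return_excluded=True``.  All-zero actuals raise.
    """
    a, s = _as_series(actual), _as_series(simulated)
    if len(a) != len(s) or len(a) < 1:
        raise ValueError("series must have equal length >= 1")
    keep = a != 0
    excluded = int(np.sum(~keep))
    if not np.any(keep):
        raise ValueError("MAPE undefined: all actual values are zero")
    with np.errstate(over="ignore"):
        value = float(np.mean(np.abs((a[keep] - s[keep]) / a[keep])) * 100.0)
    if return_excluded:
        return value, excluded
    return value


def theil(actual, simulated) -> TheilDecomposition:
    """Theil inequality decomposition of the MSE between two series.

    Uses population (1/n) standard deviations so the three components sum
    exactly to the MSE.  When either series has zero variance the correlation
    is undefined but its term vanishes (s_S * s_A = 0), so Uc is 0 there.
    Returns component fractions as None when MSE = 0.
    """
    a, s = _as_series(actual), _as_series(simulated)
    if len(a) != len(s) or len(a) < 2:
        raise ValueError("series must have equal length >= 2")
    err = s - a
    mse = float(np.mean(err**2))
    root = float(np.sqrt(mse))
    mape_val, excl = (None, 0)
    if np.any(a != 0):
        mape_val, excl = mape(a, s, return_excluded=True)
    if mse == 0.0:
        return TheilDecomposition(None, None, None, 0.0, mape_val, excl)
    s_a = float(np.std(a))
    s_s = float(np.std(s))
    bias = (float(np.mean(s)) - float(np.mean(a))) ** 2
    var = (s_s - s_a) ** 2
    # the covariation term 2(1-r)·s_S·s_A equals MSE - bias - var exactly;
    # computing it as the remainder avoids catastrophic cancellation in
    # (1 - r) for near-perfectly correlated series and makes the three
    # components sum to one by construction (it vanishes when either sd is 0)
    covar = max(mse - bias - var, 0.0)
    return TheilDecomposition(
        um=bias / mse,
        us=var / mse,
        uc=covar / mse,
        rmse=root,
        mape=mape_val,
        mape_excluded=excl,
    )


_STATS = ["rmse", "um", "us", "uc", "mape"]


def fit_report(
    panel: list[Trajectory], fitted: list[Trajectory]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-driver and pooled fit diagnostics for events/month and miles/month.

    Parameters
    ----------
    panel, fitted:
        Observed and simulated trajectories with matching driver ids and
        month grids.

    Returns
    -------
    (per_driver, summary):
        ``per_driver`` has one row per driver and variable with columns
        rmse, um, us, uc, mape; ``summary`` reports the cross-driver mean and
        standard deviation of each statistic per variable (undefined
        decompositions are excluded from the averages).
    """
    obs = {t.driver_id: t for t in panel}
    sim = {t.driver_id: t for t in fitted}
    missing = sorted(set(obs) ^ set(sim))
    if missing:
        raise ValueError(f"driver id mismatch between panel and fitted: {missing}")
    rows = []
    for did in sorted(obs):
        o, f = obs[did], sim[did]
        if not np.array_equal(o.months, f.months):
            raise ValueError(f"month grid mismatch for driver {did!r}")
        for var, a, s in (
            ("events/month", o.events, f.events),
            ("driving/month", o.miles, f.miles),
        ):
            d = theil(a, s)
            rows.append(
                {
                    "driver_id": did,
                    "variable": var,
                    "rmse": d.rmse,
                    "um": d.um,
                    "us": d.us,
                    "uc": d.uc,
                    "mape": d.mape,
                }
            )
    per_driver = pd.DataFrame(rows)
    grouped = per_driver.groupby("variable")[_STATS]
    summary = pd.concat(
        {"mean": grouped.mean(), "sd": grouped.std(ddof=1)}, names=["stat"]
    ).swaplevel().sort_index()
    return per_driver, summary
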