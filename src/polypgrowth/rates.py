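"""Per-individual growth/shrinkage rates, scaling laws and survivorship.

Within fixed phase windows each individual's log body area is regressed on
time by OLS, giving one slope per individual per phase.  These slopes feed
the size-dependence test (is the rate independent of starting size?), the
variance decomposition over starting size, phase and feeding condition, and
the allometric and power-law scaling fits.  Kaplan–Meier survivorship uses
the product-limit estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter

__all__ = [
    "IndividualSlope",
    "ScalingFit",
    "SizeDependence",
    "per_individual_slopes",
    "size_dependence",
    "variance_explained",
    "allometry_fit",
    "powerlaw_fit",
    "geometric_prediction",
    "km_survival",
    "death_and_censor_times",
]


@dataclass(frozen=True)
class IndividualSlope:
    individual_id: str
    phase_index: int
    slope: float  # per day, natural-log scale
    n_points: int
    starting_size: float  # mm^2, first observation inside the window
    condition_label: str


@dataclass(frozen=True)
class ScalingFit:
    """A log-log OLS scaling fit (allometry or power law)."""

    exponents: tuple[float, ...]
    exponent_sds: tuple[float, ...]
    exponent_cis: tuple[tuple[float, float], ...]
    intercept: float
    r_squared: float
    aic: float
    n: int
    collinear: bool = False


@dataclass(frozen=True)
class SizeDependence:
    """Regression of individual slopes on (log) starting size in one stratum."""

    phase_index: int
    condition_label: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    independent: bool  # True iff the 95% CI contains 0
    log_size: bool


def per_individual_slopes(traj: pd.DataFrame, phase_windows,
                          min_points: int = 3) -> list[IndividualSlope]:
    """OLS slope of log body area vs day per individual per phase window.

    ``phase_windows`` is an ordered list of ``(start_day, end_day)`` pairs
    (inclusive start, inclusive end) which must not overlap. Individuals
    with fewer than ``min_points`` in-window observations are skipped with
    a warning. ``starting_size`` is the first observed size in the window.
    """
    windows = [(float(a), float(b)) for a, b in phase_windows]
    for (a1, b1), (a2, b2) in zip(windows[:-1], windows[1:]):
        if a2 < b1:
            raise ValueError("phase windows must not overlap")
    alive = traj[traj["alive"].astype(bool)]
    out: list[IndividualSlope] = []
    skipped = 0
    for ind, g in alive.groupby("individual_id", sort=True):
        cond = str(g["condition"].iloc[0])
        for p, (a, b) in enumerate(windows):
            w = g[(g["day"] >= a) & (g["day"] <= b)].sort_values("day")
            if len(w) < min_points:
                skipped += 1
                continue
            t = w["day"].to_numpy(dtype=float)
            y = np.log(w["body_area_mm2"].to_numpy(dtype=float))
            slope = _ols_slope(t, y)
            out.append(IndividualSlope(
                individual_id=str(ind), phase_index=p, slope=float(slope),
                n_points=len(w), starting_size=float(w["body_area_mm2"].iloc[0]),
                condition_label=cond,
            ))
    if skipped:
        warnings.warn(f"excluded {skipped} individual-phase series with "
                      f"< {min_points} observations", stacklevel=2)
    return out


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def slopes_to_frame(slopes: list[IndividualSlope]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in slopes])


def size_dependence(slopes: list[IndividualSlope], log_size: bool = True,
                    alpha: float = 0.05) -> list[SizeDependence]:
    """Test, per (phase, condition) stratum, whether rates depend on starting size.

    Fits slope ~ starting size (log by default) by OLS; the verdict is
    'independent' iff the 95% CI of the regression coefficient contains 0
    (a horizontal line means total independence of rate from polyp size).
    Strata with fewer than 5 slopes are skipped.
    """
    df = slopes_to_frame(slopes)
    out: list[SizeDependence] = []
    for (p, cond), g in df.groupby(["phase_index", "condition_label"], sort=True):
        if len(g) < 5:
            continue
        x = g["starting_size"].to_numpy(dtype=float)
        if log_size:
            x = np.log(x)
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate stratum (phase {p}, {cond}): all starting sizes equal")
        X = sm.add_constant(x)
        res = sm.OLS(g["slope"].to_numpy(dtype=float), X).fit()
        lo, hi = res.conf_int(alpha)[1]
        out.append(SizeDependence(
            phase_index=int(p), condition_label=str(cond),
            beta=float(res.params[1]), ci_low=float(lo), ci_high=float(hi),
            p_value=float(res.pvalues[1]), n=len(g),
            independent=bool(lo <= 0.0 <= hi), log_size=log_size,
        ))
    return out


def variance_explained(slopes: list[IndividualSlope], log_size: bool = True) -> float:
    """R^2 of slope ~ log starting size + phase + condition (categoricals).

    This is the fraction of between-individual rate variance explained by
    starting size, phase and feeding condition together.
    """
    df = slopes_to_frame(slopes)
    if df.empty:
        raise ValueError("no slopes provided")
    x = df["starting_size"].to_numpy(dtype=float)
    if log_size:
        x = np.log(x)
    parts = [x[:, None]]
    for col in ("phase_index", "condition_label"):
        d = pd.get_dummies(df[col].astype("category"), drop_first=True, dtype=float)
        if d.shape[1]:
            parts.append(d.to_numpy())
    X = sm.add_constant(np.hstack(parts))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear/degenerate design for variance decomposition")
    res = sm.OLS(df["slope"].to_numpy(dtype=float), X).fit()
    return float(res.rsquared)


def _loglog_ols(y: np.ndarray, Xcols: list[np.ndarray]) -> ScalingFit:
    X = sm.add_constant(np.column_stack(Xcols))
    collinear = np.linalg.matrix_rank(X) < X.shape[1]
    if collinear:
        warnings.warn("predictors are collinear; exponents are not separately "
                      "identifiable", stacklevel=3)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(0.05)
    return ScalingFit(
        exponents=tuple(float(b) for b in res.params[1:]),
        exponent_sds=tuple(float(s) for s in res.bse[1:]),
        exponent_cis=tuple((float(a), float(b)) for a, b in ci[1:]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        aic=float(res.aic),
        n=int(res.nobs),
        collinear=bool(collinear),
    )


def allometry_fit(lengths, widths) -> ScalingFit:
    """OLS of log body length on log body width; the exponent is the fitted slope.

    An exponent of 2 means length scales with the square of width
    (growth predominantly in length).
    """
    L = np.asarray(lengths, dtype=float)
    W = np.asarray(widths, dtype=float)
    if L.size != W.size or L.size < 3:
        raise ValueError("need >= 3 paired measurements")
    if np.any(L <= 0) or np.any(W <= 0):
        raise ValueError("lengths and widths must be positive")
    return _loglog_ols(np.log(L), [np.log(W)])


def powerlaw_fit(body_sizes, cell_sizes, cell_numbers) -> ScalingFit:
    """OLS of log body size on log cell size and log cell number.

    Returns exponents with standard deviations, R^2 and AIC; exact
    collinearity between the predictors is flagged, not fatal.
    """
    A = np.asarray(body_sizes, dtype=float)
    s = np.asarray(cell_sizes, dtype=float)
    N = np.asarray(cell_numbers, dtype=float)
    if not (A.size == s.size == N.size) or A.size < 4:
        raise ValueError("need >= 4 matched samples")
    if np.any(A <= 0) or np.any(s <= 0) or np.any(N <= 0):
        raise ValueError("all quantities must be positive")
    return _loglog_ols(np.log(A), [np.log(s), np.log(N)])


def geometric_prediction(cell_size_proxy: str = "area_like") -> tuple[float, float]:
    """Predicted (cell-size, cell-number) exponents for projected body area.

    Isometric packing of N cells of volume v gives body volume N*v and a
    projected area ~ (N*v)^(2/3). With an area-like cell-size proxy
    s ~ v^(2/3) this is s^1 * N^(2/3) -> (1, 2/3); with a volume-like proxy
    s = v it is s^(2/3) * N^(2/3) -> (2/3, 2/3).
    """
    if cell_size_proxy == "area_like":
        return (1.0, 2.0 / 3.0)
    if cell_size_proxy == "volume_like":
        return (2.0 / 3.0, 2.0 / 3.0)
    raise ValueError("cell_size_proxy must be 'area_like' or 'volume_like'")


def km_survival(death_days, censor_days=()) -> pd.DataFrame:
    """Kaplan–Meier product-limit survival estimate.

    ``death_days`` are event times; ``censor_days`` are right-censoring
    times (individuals leaving the risk set without an event). Returns a
    step function as a frame with columns ``day`` and ``survival``,
    starting at S(0) = 1.
    """
    deaths = np.asarray(list(death_days), dtype=float)
    cens = np.asarray(list(censor_days), dtype=float)
    times = np.concatenate([deaths, cens])
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    observed = np.concatenate([np.ones(deaths.size), np.zeros(cens.size)])
    km = KaplanMeierFitter()
    km.fit(times, event_observed=observed)
    sf = km.survival_function_
    return pd.DataFrame({"day": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def death_and_censor_times(traj: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract KM inputs from a trajectory table.

    An individual whose record ends with an ``alive=False`` row died at that
    row's day; all others are right-censored at their last observed day.
    """
    deaths, censors = [], []
    for _, g in traj.sort_values("day").groupby("individual_id"):
        last = g.iloc[-1]
        (deaths if not bool(last["alive"]) else censors).append(float(last["day"]))
    return np.asarray(deaths), np.asarray(censors)
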