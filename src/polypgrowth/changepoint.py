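"""Multi-phase piecewise log-linear growth models with AIC selection.

The population model: pooled log body sizes of alive individuals follow a
continuous piecewise-linear mean over time, with Gaussian residuals of a
single variance. Changepoints are restricted to a candidate grid of
observed sampling days, which makes exhaustive maximum-likelihood search
feasible for small phase counts; larger phase counts are seeded by a
free-intercept segment-cost dynamic program plus nesting from the previous
optimum and refined by coordinate descent, which preserves the likelihood
monotonicity in the number of phases.

Slopes on the natural-log-per-day scale convert to doubling times
``T_D = ln 2 / r`` (growth) or halving times ``T_1/2 = ln 2 / |r|``
(shrinkage).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhaseFit",
    "RateSummary",
    "fit_piecewise",
    "select_model",
    "bootstrap_fit",
    "slope_to_time",
    "aic_parameter_count",
]

_MIN_POINTS = 3  # observations per phase below which the segment MLE degenerates
_EXHAUSTIVE_LIMIT = 400_000  # max changepoint placements enumerated exactly


@dataclass(frozen=True)
class PhaseFit:
    """A fitted multi-phase model on pooled log-transformed sizes."""

    n_phases: int
    changepoints: tuple[float, ...]  # days, strictly increasing
    slopes: tuple[float, ...]        # per day, natural-log scale
    intercept: float                 # log size at the first observation day
    sigma: float                     # residual sd, log scale
    log_likelihood: float
    aic: float
    n_obs: int
    continuous: bool = True

    def phase_kind(self, i: int, tol: float = 1e-12) -> str:
        s = self.slopes[i]
        return "growth" if s > tol else ("shrinkage" if s < -tol else "flat")


@dataclass(frozen=True)
class RateSummary:
    """One phase's slope with bootstrap CI, expressed also as T_D / T_1/2."""

    phase_index: int
    slope: float
    slope_ci_low: float
    slope_ci_high: float
    kind: str  # growth | shrinkage | flat
    time_days: float          # doubling or halving time (inf for flat)
    time_ci_low: float
    time_ci_high: float       # inf when the slope CI spans 0
    changepoint_before: float | None = None
    changepoint_ci: tuple[float, float] | None = None


def aic_parameter_count(n_phases: int, continuous: bool = True) -> int:
    """Free parameters: slopes + changepoints + intercept(s) + sigma."""
    k = n_phases + (n_phases - 1) + 1 + 1
    if not continuous:
        k += n_phases - 1  # one free intercept per extra segment
    return k


def _pooled_log_obs(traj: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Days and natural-log sizes of alive observations, pooled over individuals."""
    alive = traj[traj["alive"].astype(bool)]
    area = alive["body_area_mm2"].to_numpy(dtype=float)
    if np.any(~np.isfinite(area)) or np.any(area <= 0):
        raise ValueError("non-positive or missing body sizes among alive records")
    return alive["day"].to_numpy(dtype=float), np.log(area)


def _day_stats(t: np.ndarray, y: np.ndarray):
    """Per-distinct-day sufficient statistics (n, Σy) and prefix sums for OLS."""
    days, inv = np.unique(t, return_inverse=True)
    n_d = np.bincount(inv).astype(float)
    sy_d = np.bincount(inv, weights=y)
    sy2_d = np.bincount(inv, weights=y * y)
    return days, n_d, sy_d, sy2_d


class _SearchSpace:
    """Precomputed Gram matrix over the hinge basis for fast placement scoring.

    Design columns: [1, t, (t-c)+ for every candidate c]. A placement is a
    subset of candidate columns; its OLS solution comes from the
    corresponding Gram submatrix, so each placement costs O(p^3) with p ~ 5.
    """

    def __init__(self, t: np.ndarray, y: np.ndarray, candidates: np.ndarray,
                 min_points: int = _MIN_POINTS):
        self.t, self.y = t, y
        self.candidates = np.asarray(candidates, dtype=float)
        self.n = t.size
        cols = [np.ones_like(t), t] + [np.maximum(t - c, 0.0) for c in self.candidates]
        B = np.column_stack(cols)
        self.G = B.T @ B
        self.bty = B.T @ y
        self.yty = float(y @ y)
        self.min_points = min_points
        # per-day counts for feasibility checks
        self.days, self.n_d, _, _ = _day_stats(t, y)
        self.cum_n = np.concatenate([[0.0], np.cumsum(self.n_d)])
        self.cum_days = np.concatenate([[0], np.arange(1, self.days.size + 1)])

    def _seg_counts(self, combos: np.ndarray):
        """Observation and distinct-day counts per segment for each placement.

        Segment p covers days in (c_{p-1}, c_p]; the first starts at the
        first observed day, the last ends at the last observed day.
        """
        M, p = combos.shape
        cvals = self.candidates[combos]  # (M, p)
        pos = np.searchsorted(self.days, cvals, side="right")  # days <= c
        bounds = np.concatenate([np.zeros((M, 1), int), pos,
                                 np.full((M, 1), self.days.size)], axis=1)
        obs = self.cum_n[bounds[:, 1:]] - self.cum_n[bounds[:, :-1]]
        ndays = bounds[:, 1:] - bounds[:, :-1]
        return obs, ndays

    def feasible(self, combos: np.ndarray) -> np.ndarray:
        obs, ndays = self._seg_counts(combos)
        return (obs >= self.min_points).all(axis=1) & (ndays >= 2).all(axis=1)

    def sse_batch(self, combos: np.ndarray) -> np.ndarray:
        """Residual SSE of the continuous model for each placement (rows of combos)."""
        M, p = combos.shape
        idx = np.concatenate([np.tile([0, 1], (M, 1)), combos + 2], axis=1)
        Gb = self.G[idx[:, :, None], idx[:, None, :]]
        bb = self.bty[idx]
        try:
            beta = np.linalg.solve(Gb, bb[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.stack([np.linalg.lstsq(Gb[i], bb[i], rcond=None)[0] for i in range(M)])
        return self.yty - np.einsum("ij,ij->i", beta, bb)

    def solve(self, combo: np.ndarray):
        """Coefficients and SSE for one placement."""
        idx = np.concatenate([[0, 1], np.asarray(combo) + 2])
        Gb = self.G[np.ix_(idx, idx)]
        bb = self.bty[idx]
        beta = np.linalg.lstsq(Gb, bb, rcond=None)[0]
        sse = self.yty - float(beta @ bb)
        return beta, max(sse, 0.0)


def _gaussian_loglik(sse: float, n: int) -> float:
    sigma2 = max(sse / n, 1e-300)
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def _fit_free_segments(t, y, cut_vals):
    """Free-intercept variant: independent OLS lines per segment, shared sigma."""
    edges = [-np.inf, *cut_vals, np.inf]
    sse = 0.0
    slopes, intercepts = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (t > a) & (t <= b)
        X = np.column_stack([np.ones(m.sum()), t[m]])
        beta, res, *_ = np.linalg.lstsq(X, y[m], rcond=None)
        r = y[m] - X @ beta
        sse += float(r @ r)
        intercepts.append(beta[0])
        slopes.append(beta[1])
    return np.array(slopes), np.array(intercepts), sse


def _dp_changepoints(t, y, candidates, n_phases, min_points):
    """Optimal partition into free-intercept linear segments (exact DP).

    Nodes are [first day] + candidates + [last day]; segment cost is the OLS
    line SSE over observations with day in (node_i, node_j]. Used to propose
    changepoints for the continuous model at larger phase counts.
    """
    days, n_d, sy_d, sy2_d = _day_stats(t, y)
    st_d = n_d * days
    st2_d = n_d * days * days
    sty_d = days * sy_d
    P = lambda v: np.concatenate([[0.0], np.cumsum(v)])
    cn, cy, cy2, ct, ct2, cty = map(P, (n_d, sy_d, sy2_d, st_d, st2_d, sty_d))

    # node k corresponds to boundary value: k=0 -> before first day,
    # k=1..C -> candidates, k=C+1 -> last day
    bounds = np.concatenate([[days[0] - 1.0], candidates, [days[-1]]])
    pos = np.searchsorted(days, bounds, side="right")  # day-index up to each node
    C = len(candidates)
    K = C + 2

    def seg_cost(i, j):
        a, b = pos[i], pos[j]
        n = cn[b] - cn[a]
        if n < min_points or (b - a) < 2:
            return np.inf
        sy = cy[b] - cy[a]; sy2 = cy2[b] - cy2[a]
        st = ct[b] - ct[a]; st2 = ct2[b] - ct2[a]; sty = cty[b] - cty[a]
        stt = st2 - st * st / n
        if stt <= 0:
            return np.inf
        sty_c = sty - st * sy / n
        syy = sy2 - sy * sy / n
        return max(syy - sty_c * sty_c / stt, 0.0)

    cost = np.full((K, K), np.inf)
    for i in range(K - 1):
        for j in range(i + 1, K):
            cost[i, j] = seg_cost(i, j)

    best = np.full((n_phases + 1, K), np.inf)
    arg = np.zeros((n_phases + 1, K), dtype=int)
    best[1, :] = cost[0, :]
    for p in range(2, n_phases + 1):
        for j in range(p, K):
            c = best[p - 1, p - 1:j] + cost[p - 1:j, j]
            if np.all(np.isinf(c)):
                continue
            k = int(np.argmin(c))
            best[p, j] = c[k]
            arg[p, j] = k + p - 1
    if not np.isfinite(best[n_phases, K - 1]):
        return None
    cuts = []
    j = K - 1
    for p in range(n_phases, 1, -1):
        j = arg[p, j]
        cuts.append(j - 1)  # node index -> candidate index
    return np.array(sorted(cuts), dtype=int)


def _refine(space: _SearchSpace, combo: np.ndarray) -> tuple[np.ndarray, float]:
    """Coordinate descent: move each changepoint over the grid, keep improvements."""
    C = space.candidates.size
    combo = np.asarray(combo, dtype=int)
    best_sse = space.sse_batch(combo[None, :])[0] if space.feasible(combo[None, :])[0] else np.inf
    improved = True
    it = 0
    while improved and it < 20:
        improved = False
        it += 1
        for pos in range(combo.size):
            lo = combo[pos - 1] + 1 if pos > 0 else 0
            hi = combo[pos + 1] if pos + 1 < combo.size else C
            if hi <= lo:
                continue
            cands = np.arange(lo, hi)
            trials = np.tile(combo, (cands.size, 1))
            trials[:, pos] = cands
            feas = space.feasible(trials)
            if not feas.any():
                continue
            sse = np.full(cands.size, np.inf)
            sse[feas] = space.sse_batch(trials[feas])
            k = int(np.argmin(sse))
            if sse[k] < best_sse - 1e-12:
                best_sse = sse[k]
                combo = trials[k]
                improved = True
    return combo, best_sse


def _search_combos(space: _SearchSpace, n_phases: int,
                   warm_start: np.ndarray | None = None):
    """Best changepoint placement (candidate indices) and its SSE."""
    C = space.candidates.size
    p = n_phases - 1
    if p == 0:
        beta, sse = space.solve(np.array([], dtype=int))
        return np.array([], dtype=int), sse
    if C < p:
        raise ValueError(f"not enough candidate days ({C}) for {n_phases} phases")

    n_combos = math.comb(C, p)
    if n_phases <= 4 and n_combos <= _EXHAUSTIVE_LIMIT:
        combos = np.array(list(itertools.combinations(range(C), p)), dtype=int)
        feas = space.feasible(combos)
        if not feas.any():
            raise ValueError(f"no feasible {n_phases}-phase placement (need >= "
                             f"{space.min_points} observations per phase)")
        sse = np.full(combos.shape[0], np.inf)
        sse[feas] = space.sse_batch(combos[feas])
        k = int(np.argmin(sse))  # ties: combinations are lexicographic, argmin
        return combos[k], sse[k]  # takes the earliest placement

    # DP proposal + nesting warm start + coordinate descent
    proposals = []
    dp = _dp_changepoints(space.t, space.y, space.candidates, n_phases, space.min_points)
    if dp is not None:
        proposals.append(dp)
    if warm_start is not None and warm_start.size == p - 1:
        taken = set(warm_start.tolist())
        free = [c for c in range(C) if c not in taken]
        if free:
            trials = np.array([sorted([*warm_start, c]) for c in free], dtype=int)
            feas = space.feasible(trials)
            if feas.any():
                sse = np.full(trials.shape[0], np.inf)
                sse[feas] = space.sse_batch(trials[feas])
                proposals.append(trials[int(np.argmin(sse))])
    if not proposals:
        raise ValueError(f"no feasible {n_phases}-phase placement found")
    best_combo, best_sse = None, np.inf
    for prop in proposals:
        combo, sse = _refine(space, np.asarray(prop, dtype=int))
        if sse < best_sse - 1e-12 or (best_combo is None and np.isfinite(sse)):
            best_combo, best_sse = combo, sse
    if best_combo is None:
        raise ValueError(f"no feasible {n_phases}-phase placement found")
    return best_combo, best_sse


def _build_space(t: np.ndarray, y: np.ndarray, candidate_days,
                 min_points: int) -> _SearchSpace:
    obs_days = np.unique(t)
    if candidate_days is None:
        candidates = obs_days[1:-1]
    else:
        candidates = np.asarray(sorted(set(float(c) for c in candidate_days)))
        candidates = candidates[(candidates > obs_days[0]) & (candidates < obs_days[-1])]
    return _SearchSpace(t, y, candidates, min_points)


def _fit_on_space(space: _SearchSpace, n_phases: int, continuous: bool = True,
                  warm_start: np.ndarray | None = None) -> PhaseFit:
    if space.n < n_phases * space.min_points:
        raise ValueError("fewer observations than n_phases * min_points")
    combo, sse = _search_combos(space, n_phases, warm_start=warm_start)
    cut_vals = space.candidates[combo]
    first_day = space.days[0]

    if continuous:
        beta, sse = space.solve(combo)
        slopes = np.cumsum(beta[1:])  # hinge coefficients accumulate
        intercept0 = beta[0] + beta[1] * first_day  # log-size at first obs day
    else:
        slopes, intercepts, sse = _fit_free_segments(space.t, space.y, cut_vals)
        intercept0 = intercepts[0] + slopes[0] * first_day

    n = space.n
    ll = _gaussian_loglik(sse, n)
    k = aic_parameter_count(n_phases, continuous)
    return PhaseFit(
        n_phases=n_phases,
        changepoints=tuple(float(c) for c in cut_vals),
        slopes=tuple(float(s) for s in slopes),
        intercept=float(intercept0),
        sigma=float(math.sqrt(max(sse, 0.0) / n)),
        log_likelihood=float(ll),
        aic=float(2 * k - 2 * ll),
        n_obs=int(n),
        continuous=continuous,
    )


def _fit_from_arrays(t: np.ndarray, y: np.ndarray, n_phases: int,
                     candidate_days=None, min_points: int = _MIN_POINTS,
                     continuous: bool = True,
                     warm_start: np.ndarray | None = None) -> PhaseFit:
    space = _build_space(t, y, candidate_days, min_points)
    return _fit_on_space(space, n_phases, continuous, warm_start)


def fit_piecewise(traj: pd.DataFrame, n_phases: int, candidate_days=None,
                  min_points: int = _MIN_POINTS, continuous: bool = True) -> PhaseFit:
    """Maximum-likelihood multi-phase fit of pooled log body sizes.

    Parameters
    ----------
    traj
        Trajectory table (columns ``individual_id, day, body_area_mm2,
        alive``); only alive records enter the fit.
    n_phases
        Number of linear phases (>= 1).
    candidate_days
        Admissible changepoint days; defaults to every observed day strictly
        inside the observation span. Ties in likelihood resolve toward the
        earliest changepoints.
    continuous
        If True (default) segments join at the changepoints (one continuous
        mean curve); if False each segment has a free intercept.
    """
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    t, y = _pooled_log_obs(traj)
    return _fit_from_arrays(t, y, n_phases, candidate_days, min_points, continuous)


def select_model(traj: pd.DataFrame, max_phases: int = 8, candidate_days=None,
                 min_points: int = _MIN_POINTS, continuous: bool = True):
    """Fit 1..max_phases models, return the minimum-AIC fit and the AIC table.

    The AIC table has one row per attempted phase count with its
    log-likelihood and AIC (NaN where the phase count was infeasible).
    """
    if max_phases < 1:
        raise ValueError("max_phases must be >= 1")
    t, y = _pooled_log_obs(traj)
    space = _build_space(t, y, candidate_days, min_points)
    fits: dict[int, PhaseFit] = {}
    rows = []
    warm = None
    for p in range(1, max_phases + 1):
        try:
            fit = _fit_on_space(space, p, continuous, warm_start=warm)
        except ValueError:
            rows.append({"n_phases": p, "log_likelihood": np.nan, "aic": np.nan})
            continue
        fits[p] = fit
        warm = np.searchsorted(space.candidates, np.asarray(fit.changepoints))
        rows.append({"n_phases": p, "log_likelihood": fit.log_likelihood, "aic": fit.aic})
    if not fits:
        raise ValueError("no phase count could be fitted")
    table = pd.DataFrame(rows)
    best = min(fits.values(), key=lambda f: (f.aic, f.n_phases))
    return best, table


def bootstrap_fit(traj: pd.DataFrame, fit: PhaseFit, n_boot: int = 1000,
                  seed: int = 0, candidate_days=None,
                  min_points: int = _MIN_POINTS) -> list[RateSummary]:
    """Percentile-bootstrap CIs for slopes and changepoints.

    Individuals (whole trajectories) are resampled with replacement and the
    model refitted with the phase count fixed; 95% percentile intervals are
    reported per phase and converted to doubling/halving times.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    alive = traj[traj["alive"].astype(bool)]
    groups = {
        i: (g["day"].to_numpy(dtype=float),
            np.log(g["body_area_mm2"].to_numpy(dtype=float)))
        for i, g in alive.groupby("individual_id")
    }
    ids = np.array(list(groups))

    slopes = np.empty((n_boot, fit.n_phases))
    cps = np.empty((n_boot, max(fit.n_phases - 1, 1)))
    for b in range(n_boot):
        pick = rng.choice(ids, size=ids.size, replace=True)
        t = np.concatenate([groups[i][0] for i in pick])
        y = np.concatenate([groups[i][1] for i in pick])
        bf = _fit_from_arrays(t, y, fit.n_phases, candidate_days, min_points,
                              fit.continuous)
        slopes[b] = bf.slopes
        if fit.n_phases > 1:
            cps[b] = bf.changepoints

    out: list[RateSummary] = []
    for p in range(fit.n_phases):
        lo, hi = np.percentile(slopes[:, p], [2.5, 97.5])
        s = fit.slopes[p]
        kind, t_days = slope_to_time(s)
        t_lo, t_hi = _time_ci(lo, hi)
        cp_before = fit.changepoints[p - 1] if p > 0 else None
        cp_ci = tuple(np.percentile(cps[:, p - 1], [2.5, 97.5])) if p > 0 else None
        out.append(RateSummary(
            phase_index=p, slope=float(s),
            slope_ci_low=float(lo), slope_ci_high=float(hi),
            kind=kind, time_days=t_days, time_ci_low=t_lo, time_ci_high=t_hi,
            changepoint_before=cp_before, changepoint_ci=cp_ci,
        ))
    return out


def slope_to_time(slope: float) -> tuple[str, float]:
    """Convert a per-day log-scale rate to a doubling or halving time.

    Returns ``(kind, days)``: ``('growth', ln2/slope)`` for positive slopes,
    ``('shrinkage', ln2/|slope|)`` for negative, ``('flat', inf)`` at zero.
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if slope > 0:
        return "growth", math.log(2.0) / slope
    if slope < 0:
        return "shrinkage", math.log(2.0) / abs(slope)
    return "flat", math.inf


def _time_ci(slope_lo: float, slope_hi: float) -> tuple[float, float]:
    """Monotone transform of a slope CI to a time CI.

    When the slope CI spans zero the slower bound is infinite (the printed
    extreme ranges for near-flat phases arise exactly this way).
    """
    if slope_lo > 0:  # both growth: faster slope -> shorter doubling time
        return math.log(2.0) / slope_hi, math.log(2.0) / slope_lo
    if slope_hi < 0:  # both shrinkage: more negative slope -> shorter halving time
        return math.log(2.0) / abs(slope_lo), math.log(2.0) / abs(slope_hi)
    finite = min(math.log(2.0) / abs(s) for s in (slope_lo, slope_hi) if s != 0)
    return finite, math.inf
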