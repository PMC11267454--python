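"""Per-individual rates, size-(in)dependence, scaling laws and survivorship:
hand-computable oracles, calibration of the independence test, and geometric
predictions checked against a numerical packing model."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import polypgrowth as pg
from polypgrowth.rates import (IndividualSlope, _ols_slope, allometry_fit,
                               death_and_censor_times, geometric_prediction,
                               km_survival, per_individual_slopes, powerlaw_fit,
                               size_dependence, variance_explained)


def _traj(rows):
    df = pd.DataFrame(rows, columns=["individual_id", "day", "body_area_mm2"])
    df["condition"] = "X"
    df["body_length_mm"] = 1.0
    df["body_width_mm"] = 1.0
    df["alive"] = True
    return df


def _make_slopes(rng, n, beta, phase=0, cond="X", noise=0.01):
    """Directly construct IndividualSlope lists with slope = beta*log(size)+e."""
    sizes = np.exp(rng.normal(0.0, 0.5, n))
    return [IndividualSlope(f"i{k}", phase, float(beta * math.log(s)
                                                  + rng.normal(0, noise)),
                            5, float(s), cond)
            for k, s in enumerate(sizes)]


# ---------------------------------------------------------------- slopes


def test_exact_exponential_slope():
    rows = [("a", d, math.exp(0.5 + 0.25 * d)) for d in range(0, 10, 2)]
    s = per_individual_slopes(_traj(rows), [(0, 10)])
    assert len(s) == 1
    assert s[0].slope == pytest.approx(0.25, abs=1e-12)
    assert s[0].starting_size == pytest.approx(math.exp(0.5))
    assert s[0].n_points == 5


def test_ols_slope_matches_normal_equations():
    rng = np.random.default_rng(0)
    t = np.array([0.0, 2.0, 3.0, 7.0, 11.0])
    y = rng.normal(0, 1, 5)
    X = np.column_stack([np.ones(5), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert _ols_slope(t, y) == pytest.approx(beta[1], rel=1e-12)


def test_windows_partition_observations():
    rows = [("a", d, math.exp(0.3 * min(d, 5) - 0.1 * max(d - 5, 0)))
            for d in range(0, 11)]
    s = per_individual_slopes(_traj(rows), [(0, 5), (6, 10)])
    assert [x.phase_index for x in s] == [0, 1]
    assert s[0].slope == pytest.approx(0.3, abs=1e-12)
    assert s[1].slope == pytest.approx(-0.1, abs=1e-12)


def test_short_series_skipped_with_warning():
    rows = [("a", 0, 1.0), ("a", 2, 2.0),                 # 2 points -> skipped
            ("b", 0, 1.0), ("b", 2, 2.0), ("b", 4, 4.0)]
    with pytest.warns(UserWarning, match="excluded 1"):
        s = per_individual_slopes(_traj(rows), [(0, 5)])
    assert [x.individual_id for x in s] == ["b"]


def test_dead_rows_excluded():
    rows = [("a", d, math.exp(0.2 * d)) for d in range(0, 8, 2)]
    df = _traj(rows)
    extra = df.iloc[[-1]].assign(day=10.0, body_area_mm2=np.nan, alive=False)
    df = pd.concat([df, extra], ignore_index=True)
    s = per_individual_slopes(df, [(0, 10)])
    assert s[0].n_points == 4 and s[0].slope == pytest.approx(0.2, abs=1e-12)


def test_overlapping_windows_rejected():
    with pytest.raises(ValueError):
        per_individual_slopes(_traj([("a", 0, 1.0)]), [(0, 5), (4, 9)])


# ---------------------------------------------------- size (in)dependence


def test_size_dependence_type_one_error_rate():
    """Under true independence the test concedes dependence <= ~5% of runs."""
    rng = np.random.default_rng(10)
    verdicts = [size_dependence(_make_slopes(rng, 96, beta=0.0))[0].independent
                for _ in range(200)]
    assert sum(verdicts) >= 186  # 93% of 200; expected 95%


def test_size_dependence_detects_real_effect():
    rng = np.random.default_rng(11)
    hits = [not size_dependence(_make_slopes(rng, 96, beta=-0.05))[0].independent
            for _ in range(50)]
    assert sum(hits) >= 48


def test_size_dependence_strata_are_separate():
    rng = np.random.default_rng(12)
    s = (_make_slopes(rng, 40, 0.0, phase=0, cond="AL")
         + _make_slopes(rng, 40, -0.2, phase=1, cond="AL"))
    res = size_dependence(s)
    assert [(r.phase_index, r.condition_label) for r in res] == [(0, "AL"), (1, "AL")]
    assert res[0].independent and not res[1].independent


def test_size_dependence_degenerate_sizes_rejected():
    s = [IndividualSlope(f"i{k}", 0, 0.1, 5, 2.0, "X") for k in range(8)]
    with pytest.raises(ValueError):
        size_dependence(s)


def test_variance_explained_exact_linear_relation():
    rng = np.random.default_rng(13)
    s = _make_slopes(rng, 30, beta=0.1, noise=0.0)
    assert variance_explained(s) == pytest.approx(1.0, abs=1e-10)


def test_variance_explained_matches_brute_force():
    """R^2 equals 1 - SSE/SST from an explicit dummy-coded lstsq fit."""
    rng = np.random.default_rng(14)
    s = (_make_slopes(rng, 4, 0.05, phase=0, cond="AL", noise=0.05)
         + _make_slopes(rng, 4, 0.05, phase=1, cond="AL", noise=0.05)
         + _make_slopes(rng, 4, 0.05, phase=1, cond="RES", noise=0.05))
    r2 = variance_explained(s)
    y = np.array([x.slope for x in s])
    X = np.column_stack([
        np.ones(len(s)),
        np.log([x.starting_size for x in s]),
        [float(x.phase_index == 1) for x in s],
        [float(x.condition_label == "RES") for x in s],
    ])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ beta) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    assert r2 == pytest.approx(1.0 - sse / sst, rel=1e-9)


# ----------------------------------------------------------- scaling fits


def test_allometry_exact_square_law():
    w = np.linspace(0.5, 3.0, 12)
    fit = allometry_fit(0.8 * w**2, w)
    assert fit.exponents[0] == pytest.approx(2.0, abs=1e-10)
    assert fit.intercept == pytest.approx(math.log(0.8), abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0)


def test_allometry_matches_normal_equations():
    rng = np.random.default_rng(15)
    w = np.exp(rng.normal(0, 0.3, 6))
    L = np.exp(rng.normal(0, 0.3, 6))
    fit = allometry_fit(L, w)
    X = np.column_stack([np.ones(6), np.log(w)])
    beta = np.linalg.solve(X.T @ X, X.T @ np.log(L))
    assert fit.exponents[0] == pytest.approx(beta[1], rel=1e-10)
    assert fit.intercept == pytest.approx(beta[0], rel=1e-10)


def test_powerlaw_exact_geometric_surface():
    """Bodies built as s^1 * N^(2/3) recover exponents (1, 2/3) exactly."""
    rng = np.random.default_rng(16)
    s = np.exp(rng.normal(3.0, 0.2, 20))
    N = np.exp(rng.normal(10.0, 0.8, 20))
    A = s * N ** (2.0 / 3.0)
    fit = powerlaw_fit(A, s, N)
    assert fit.exponents == pytest.approx((1.0, 2.0 / 3.0), abs=1e-9)
    assert not fit.collinear


def test_powerlaw_matches_normal_equations():
    rng = np.random.default_rng(17)
    s = np.exp(rng.normal(0, 0.3, 8))
    N = np.exp(rng.normal(0, 0.5, 8))
    A = np.exp(rng.normal(0, 0.4, 8))
    fit = powerlaw_fit(A, s, N)
    X = np.column_stack([np.ones(8), np.log(s), np.log(N)])
    beta = np.linalg.solve(X.T @ X, X.T @ np.log(A))
    assert fit.exponents == pytest.approx(tuple(beta[1:]), rel=1e-9)
    # residual-based sd of each coefficient
    resid = np.log(A) - X @ beta
    cov = float(resid @ resid) / (8 - 3) * np.linalg.inv(X.T @ X)
    assert fit.exponent_sds == pytest.approx(tuple(np.sqrt(np.diag(cov))[1:]), rel=1e-9)


def test_powerlaw_collinear_flagged_not_fatal():
    N = np.exp(np.linspace(0, 2, 10))
    s = N**0.5  # exactly collinear in logs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = powerlaw_fit(s * N, s, N)
    assert fit.collinear


def test_geometric_prediction_values():
    assert geometric_prediction("area_like") == (1.0, 2.0 / 3.0)
    assert geometric_prediction("volume_like") == (2.0 / 3.0, 2.0 / 3.0)
    with pytest.raises(ValueError):
        geometric_prediction("nonsense")


def test_geometric_prediction_matches_numerical_packing():
    """Simulated isometric bodies (area = (N v)^(2/3)) reproduce the analytic
    exponents to high precision under a log-log fit."""
    rng = np.random.default_rng(18)
    v = np.exp(rng.normal(0.0, 0.3, 40))       # cell volume
    N = np.exp(rng.normal(8.0, 0.9, 40))       # cell number
    body_area = (N * v) ** (2.0 / 3.0)
    for proxy, cell_size in (("area_like", v ** (2.0 / 3.0)), ("volume_like", v)):
        fit = powerlaw_fit(body_area, cell_size, N)
        assert fit.exponents == pytest.approx(geometric_prediction(proxy), abs=1e-6)


# ----------------------------------------------------------- survivorship


def test_km_no_deaths_is_flat():
    sf = km_survival([], censor_days=[5, 10, 15])
    assert np.allclose(sf["survival"], 1.0)


def test_km_hand_computed_product_limit():
    # n = 4 at risk; deaths at day 2 (S -> 3/4) and day 5 (S -> 1/2),
    # censored at 7 and 9 (no further drops).
    sf = km_survival([2, 5], censor_days=[7, 9]).set_index("day")["survival"]
    assert sf.loc[0.0] == pytest.approx(1.0)
    assert sf.loc[2.0] == pytest.approx(0.75)
    assert sf.loc[5.0] == pytest.approx(0.5)
    assert sf.iloc[-1] == pytest.approx(0.5)


def test_km_monotone_and_starts_at_one():
    rng = np.random.default_rng(19)
    sf = km_survival(rng.integers(1, 30, 40), censor_days=rng.integers(1, 30, 10))
    assert sf["survival"].iloc[0] == pytest.approx(1.0)
    assert (np.diff(sf["survival"]) <= 1e-12).all()
    with pytest.raises(ValueError):
        km_survival([])
    with pytest.raises(ValueError):
        km_survival([-1.0])


def test_death_and_censor_extraction():
    rows = [("a", 0, 1.0), ("a", 3, 2.0), ("b", 0, 1.0), ("b", 3, 1.5)]
    df = _traj(rows)
    dead = df.iloc[[1]].assign(day=6.0, body_area_mm2=np.nan, alive=False)
    df = pd.concat([df, dead], ignore_index=True)
    deaths, censors = death_and_censor_times(df)
    assert deaths.tolist() == [6.0]
    assert censors.tolist() == [3.0]


# ----------------------------------------------- end-to-end on a cohort


def test_initial_rates_independent_of_starting_size():
    """At the start of the experiment individual rate draws are independent of
    the starting-size draw, and the stratum verdict agrees.

    Only the first phase carries this guarantee: each individual keeps its
    rate offset across phases, so by a later phase boundary its accumulated
    size is genuinely informative about its subsequent rate.
    """
    cfg = pg.SimCohortConfig(n_individuals=96, phase_schedule=[(0, 14, 0.2)],
                             noise_sd=0.1, rate_heterogeneity_sd=0.02,
                             start_size_logsd=0.4,
                             sampling_days=list(range(0, 15, 2)), seed=30)
    sim = pg.simulate_cohort(cfg)
    slopes = per_individual_slopes(sim.trajectories, [(0, 14)])
    res = size_dependence(slopes)
    assert len(res) == 1 and res[0].independent and res[0].n == 96


def test_persistent_heterogeneity_creates_late_phase_dependence(al_cohort):
    """Because rate offsets persist, size entering a later phase predicts the
    rate within it; the test should detect that in at least one late stratum."""
    windows = [(p.start_day, p.end_day) for p in pg.nematostella_al().phase_schedule]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        slopes = per_individual_slopes(al_cohort.trajectories, windows)
    res = size_dependence(slopes)
    assert len(res) == 4
    assert any(not r.independent for r in res[1:])


def test_cohort_phase_means_match_generator(al_cohort):
    cfg = pg.nematostella_al()
    windows = [(p.start_day, p.end_day) for p in cfg.phase_schedule]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        slopes = per_individual_slopes(al_cohort.trajectories, windows)
    df = pd.DataFrame([s.__dict__ for s in slopes])
    means = df.groupby("phase_index")["slope"].mean()
    for p, phase in enumerate(cfg.phase_schedule):
        assert means[p] == pytest.approx(phase.rate, abs=0.02)
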