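"""Per-individual growth rates, their size-(in)dependence, scaling laws
and survivorship.

Uses the fitted changepoints from step 02 to window each cohort, regresses
each individual's log body area on time within each window, and asks
whether those rates depend on the size the individual entered the window
with.  Also fits the length-width allometry on the simulated morphometrics,
compares a body-size power law in cell size and cell number against the
geometric prediction, and computes Kaplan-Meier survivorship.  Writes
results under results/03_individual_rates_scaling/.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import polypgrowth as pg
from polypgrowth.pipeline import phase_windows_from_fit, stage_seed
from polypgrowth.rates import slopes_to_frame, variance_explained

SEED = 20240603
ROOT = Path(__file__).resolve().parent.parent
IN = ROOT / "results" / "01_simulate"
FITS = ROOT / "results" / "02_fit_growth_phases"
OUT = ROOT / "results" / "03_individual_rates_scaling"

COHORTS = ["nematostella_al", "nematostella_res",
           "aiptasia_symbiotic", "aiptasia_aposymbiotic"]


def windows_for(name: str, traj: pd.DataFrame):
    cps = pd.read_csv(FITS / f"{name}.changepoint_table.csv")
    edges = [traj["day"].min(), *cps["day"].tolist(), traj["day"].max()]
    return list(zip(edges[:-1], edges[1:]))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    all_slopes = []
    for name in COHORTS:
        traj = pg.read_trajectories(IN / f"{name}.csv")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            slopes = pg.per_individual_slopes(traj, windows_for(name, traj))
        df = slopes_to_frame(slopes)
        df.insert(0, "cohort", name)
        all_slopes.append(df)
        verdicts = pg.size_dependence(slopes)
        pd.DataFrame([v.__dict__ for v in verdicts]).to_csv(
            OUT / f"{name}.size_dependence.csv", index=False)
        n_indep = sum(v.independent for v in verdicts)
        print(f"{name}: {len(slopes)} individual-phase slopes; "
              f"{n_indep}/{len(verdicts)} strata size-independent")

        deaths, censors = pg.death_and_censor_times(traj)
        pg.km_survival(deaths, censors).to_csv(OUT / f"{name}.survival.csv",
                                               index=False)
    pd.concat(all_slopes, ignore_index=True).to_csv(
        OUT / "individual_slopes.csv", index=False)

    # variance in individual rates explained by size, phase and condition
    al = pg.read_trajectories(IN / "nematostella_al.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        slopes = pg.per_individual_slopes(al, windows_for("nematostella_al", al))
    r2 = variance_explained(slopes)
    print(f"variance explained (size + phase + condition): R^2 = {r2:.2f}")

    # allometry: log body length on log body width, pooled over the cohort
    fit = pg.allometry_fit(al.loc[al["alive"], "body_length_mm"],
                           al.loc[al["alive"], "body_width_mm"])
    print(f"allometry: length ~ width^{fit.exponents[0]:.2f} "
          f"(R^2 = {fit.r_squared:.2f}, n = {fit.n})")

    # power law of body size in cell size and cell number, vs the geometric
    # prediction for an area-like body measure and an area-like cell proxy
    rng = np.random.default_rng(stage_seed(SEED, "powerlaw"))
    n = 60
    cell_size = np.exp(rng.normal(3.0, 0.15, n))        # area-like proxy, a.u.
    cell_number = np.exp(rng.normal(11.0, 0.9, n))
    body = cell_size * cell_number ** (2 / 3) * np.exp(rng.normal(0, 0.25, n))
    pl = pg.powerlaw_fit(body, cell_size, cell_number)
    pred = pg.geometric_prediction("area_like")
    print(f"power law: size exponent {pl.exponents[0]:.3f} "
          f"(sd {pl.exponent_sds[0]:.3f}), number exponent {pl.exponents[1]:.3f} "
          f"(sd {pl.exponent_sds[1]:.3f}); geometric prediction {pred}")
    pd.DataFrame({
        "quantity": ["allometry_exponent", "allometry_r2",
                     "powerlaw_cell_size_exponent", "powerlaw_cell_number_exponent",
                     "powerlaw_r2", "variance_explained_r2",
                     "geometric_cell_size_exponent", "geometric_cell_number_exponent"],
        "value": [fit.exponents[0], fit.r_squared,
                  pl.exponents[0], pl.exponents[1], pl.r_squared, r2,
                  pred[0], pred[1]],
    }).to_csv(OUT / "scaling_summary.csv", index=False)


if __name__ == "__main__":
    main()
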