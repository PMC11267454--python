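"""Generate the synthetic datasets every downstream analysis step consumes.

Writes, under results/01_simulate/:
  - one trajectory table + truth table per cohort preset (two Nematostella
    feeding regimes over two feed/starve cycles, two Aiptasia variants over
    a single cycle), and
  - one truth-labelled cytometry event table per sampling-day preset
    (fed day 1, day 5, starved day 21, re-fed), each with a matching
    EdU-negative control.
"""

import dataclasses
from pathlib import Path

import polypgrowth as pg
from polypgrowth.pipeline import stage_seed

SEED = 20240601
OUT = Path(__file__).resolve().parent.parent / "results" / "01_simulate"

COHORTS = {
    "nematostella_al": pg.nematostella_al,
    "nematostella_res": pg.nematostella_res,
    "aiptasia_symbiotic": pg.aiptasia_symbiotic,
    "aiptasia_aposymbiotic": pg.aiptasia_aposymbiotic,
}
EVENTS = {
    "events_day1": pg.events_day1,
    "events_day5": pg.events_day5,
    "events_day21": pg.events_day21,
    "events_refed": pg.events_refed,
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, preset in COHORTS.items():
        cfg = preset(seed=stage_seed(SEED, name))
        sim = pg.simulate_cohort(cfg)
        pg.write_trajectories(sim.trajectories, OUT / f"{name}.csv")
        sim.truth.to_csv(OUT / f"{name}.truth.csv", index=False)
        pg.dump_config(cfg, OUT / f"{name}.config.yaml")
        n = sim.trajectories["individual_id"].nunique()
        print(f"{name}: {n} individuals, {len(sim.trajectories)} records")
    for name, preset in EVENTS.items():
        cfg = preset(seed=stage_seed(SEED, name))
        pg.write_events(pg.simulate_events(cfg), OUT / f"{name}.csv")
        ctrl = dataclasses.replace(cfg, edu_fraction=0.0,
                                   seed=stage_seed(SEED, name + "-control"))
        pg.write_events(pg.simulate_events(ctrl), OUT / f"{name}.control.csv")
        pg.dump_config(cfg, OUT / f"{name}.config.yaml")
        print(f"{name}: {cfg.n_cells} cells simulated (+ negative control)")


if __name__ == "__main__":
    main()
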