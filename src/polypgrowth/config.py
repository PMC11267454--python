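"""Configuration objects for cohort and cytometry-event simulation and gating.

All rates are per day on the natural-log scale; sizes are mm^2 (body area),
mm (length/width) and arbitrary cytometer intensity units. One master seed
drives every stream; child streams are spawned per individual or event block
via :class:`numpy.random.SeedSequence`, so identical configs give identical
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

__all__ = [
    "Phase",
    "SimCohortConfig",
    "SimEventsConfig",
    "GateConfig",
    "BeadSizeStandard",
    "nematostella_al",
    "nematostella_res",
    "aiptasia_symbiotic",
    "aiptasia_aposymbiotic",
    "events_day1",
    "events_day5",
    "events_day21",
    "events_refed",
    "load_config",
]


@dataclass(frozen=True)
class Phase:
    """One dynamic phase: [start_day, end_day) with a constant log-scale rate."""

    start_day: float
    end_day: float
    rate: float  # per day, natural-log scale; >0 growth, <0 shrinkage

    @property
    def duration(self) -> float:
        return self.end_day - self.start_day


def _doubling(td: float) -> float:
    return math.log(2.0) / td


def _halving(th: float) -> float:
    return -math.log(2.0) / th


@dataclass
class SimCohortConfig:
    """Conditions for a simulated longitudinal body-size cohort.

    Each individual i follows a continuous piecewise-linear log body area
    with per-phase slope ``rate + eps_i`` where ``eps_i ~ N(0,
    rate_heterogeneity_sd)`` is a constant individual offset.  Observations
    carry additive Gaussian noise on the log scale (multiplicative lognormal
    on the raw scale).  Deaths are per-day Bernoulli draws with a
    phase-specific hazard.
    """

    n_individuals: int = 96
    phase_schedule: Sequence[Phase] = ()
    rate_heterogeneity_sd: float = 0.02
    noise_sd: float = 0.1
    start_size_logmean: float = math.log(0.5)  # mm^2
    start_size_logsd: float = 0.4
    hazard_per_phase: Sequence[float] = ()
    allometry_exponent: float = 2.0  # length ~ width^b
    shape_noise_sd: float = 0.79  # lognormal scatter of length about the allometry
    sampling_days: Sequence[float] = ()
    condition_label: str = "AL"
    seed: int = 0

    def __post_init__(self) -> None:
        self.phase_schedule = tuple(
            p if isinstance(p, Phase) else Phase(*p) for p in self.phase_schedule
        )
        if not self.phase_schedule:
            raise ValueError("phase_schedule must contain at least one phase")
        for a, b in zip(self.phase_schedule[:-1], self.phase_schedule[1:]):
            if not math.isclose(a.end_day, b.start_day):
                raise ValueError("phase intervals must be contiguous and non-overlapping")
        for sd_name in ("rate_heterogeneity_sd", "noise_sd", "start_size_logsd", "shape_noise_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        if not self.hazard_per_phase:
            self.hazard_per_phase = tuple(0.0 for _ in self.phase_schedule)
        self.hazard_per_phase = tuple(float(h) for h in self.hazard_per_phase)
        if len(self.hazard_per_phase) != len(self.phase_schedule):
            raise ValueError("hazard_per_phase must match phase_schedule length")
        if any(h < 0 or h > 1 for h in self.hazard_per_phase):
            raise ValueError("hazards must lie in [0, 1]")
        if not self.sampling_days:
            t0 = self.phase_schedule[0].start_day
            t1 = self.phase_schedule[-1].end_day
            self.sampling_days = tuple(float(d) for d in _arange_inclusive(t0, t1, 4.0))
        self.sampling_days = tuple(float(d) for d in self.sampling_days)
        if any(b <= a for a, b in zip(self.sampling_days[:-1], self.sampling_days[1:])):
            raise ValueError("sampling_days must be strictly increasing")
        lo = self.phase_schedule[0].start_day
        hi = self.phase_schedule[-1].end_day
        if self.sampling_days[0] < lo or self.sampling_days[-1] > hi:
            raise ValueError("sampling day outside the phase schedule span")


def _arange_inclusive(a: float, b: float, step: float) -> list[float]:
    out = []
    x = a
    while x < b - 1e-9:
        out.append(x)
        x += step
    out.append(b)
    return out


@dataclass
class SimEventsConfig:
    """Conditions for one simulated cytometry sample (event cloud).

    DNA-dye intensity: the 2N (G1/G0) peak is Gaussian with mean
    ``dna_2n_mean`` and CV ``dna_cv``; the 4N (G2/M) peak sits at exactly
    twice the 2N mean; S-phase events bridge the two peaks uniformly.
    Forward scatter area is proportional to cell diameter squared.
    """

    n_cells: int = 50_000
    cycle_fractions: tuple[float, float, float] = (0.838, 0.050, 0.112)  # G1/G0, S, G2/M
    dna_2n_mean: float = 50.0
    dna_cv: float = 0.04
    edu_fraction: float = 0.0
    edu_separation: float = math.log(100.0)  # natural-log gap between +/- peaks
    size_classes: Sequence[tuple[float, float]] = ((3.0, 0.45), (5.0, 0.35), (8.0, 0.15), (12.0, 0.05))
    beads_added_count: int = 50_000
    bead_recovery: float = 1.0
    loss_beads_spiked: int = 0  # set to the spiked count (2e5 in the protocol) to emulate dissociation loss
    loss_bead_recovery: float = 1.0
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.03
    seed: int = 0

    # intensity-scale constants shared with the default GateConfig
    fsc_per_um2: float = 100.0  # fsc_a = fsc_per_um2 * diameter^2
    size_class_logsd: float = 0.08

    def __post_init__(self) -> None:
        self.cycle_fractions = tuple(float(f) for f in self.cycle_fractions)
        if abs(sum(self.cycle_fractions) - 1.0) > 1e-9:
            raise ValueError("cycle_fractions must sum to 1")
        for name in ("edu_fraction", "bead_recovery", "loss_bead_recovery",
                     "debris_fraction", "doublet_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(f < 0 or f > 1 for f in self.cycle_fractions):
            raise ValueError("cycle_fractions must lie in [0, 1]")
        if self.beads_added_count <= 0:
            raise ValueError("beads_added_count must be > 0")
        self.size_classes = tuple((float(d), float(w)) for d, w in self.size_classes)


@dataclass
class GateConfig:
    """Thresholds for the sequential gating cascade.

    Defaults match the intensity scales of :class:`SimEventsConfig`; with
    real instrument data every threshold must be set from the controls.
    """

    fsc_a_min: float = 380.0  # scatter debris gate (≈ 2 µm equivalent)
    ssc_a_min: float = 20.0
    singlet_ratio_tol: float = 0.15  # |fsc_a/fsc_h − 1| tolerance
    ssc_w_max: float = 130.0
    dna_w_min: float = 80.0
    dna_w_max: float = 125.0
    dna_a_min: float = 30.0  # 2N–4N envelope (admissible DNA-dye range)
    dna_a_max: float = 125.0
    edu_quantile: float = 0.999  # negative-control quantile for the EdU threshold
    bead_channel_threshold: float = 100.0
    counting_bead_min: float = 1500.0  # splits counting vs loss beads
    chlorophyll_max: float | None = None  # symbiont exclusion preset (off by default)

    def __post_init__(self) -> None:
        if not 0.0 < self.edu_quantile < 1.0:
            raise ValueError("edu_quantile must lie in (0, 1)")


@dataclass(frozen=True)
class BeadSizeStandard:
    """Known-diameter polystyrene bead ladder mapping FSC-A to micrometres."""

    diameters_um: tuple[float, ...] = (2.0, 4.0, 6.0, 10.0, 15.0)
    median_fsc_a: tuple[float, ...] = (400.0, 1600.0, 3600.0, 10000.0, 22500.0)

    def __post_init__(self) -> None:
        d, f = self.diameters_um, self.median_fsc_a
        if len(d) < 2 or len(d) != len(f):
            raise ValueError("standard needs >= 2 (diameter, fsc) pairs")
        if any(b <= a for a, b in zip(d[:-1], d[1:])) or any(b <= a for a, b in zip(f[:-1], f[1:])):
            raise ValueError("diameters and fsc values must be strictly increasing")
        if d[0] < 2.0 - 1e-9 or d[-1] > 15.0 + 1e-9:
            raise ValueError("bead diameters must lie within [2, 15] µm")


# ---------------------------------------------------------------------------
# Presets: one configuration per feeding regime, with phase rates specified
# as doubling/halving times and converted via r = ln 2 / T.
# ---------------------------------------------------------------------------

def nematostella_al(**kw) -> SimCohortConfig:
    """Ad-libitum-fed Nematostella, two feed/starve cycles over 198 days.

    Growth phases run ~9 days (feeding plus a short overhang into
    starvation), which at T_D 2.4 d yields a ~13-fold first-phase size
    increase, followed by slow shrinkage over 90-day starvation phases.
    """
    schedule = (
        Phase(0, 9, _doubling(2.4)),      # growth, T_D 2.4 d, ~13-fold
        Phase(9, 99, _halving(29.0)),     # shrinkage, T_1/2 29 d
        Phase(99, 108, _doubling(4.5)),   # re-growth, T_D 4.5 d
        Phase(108, 198, _halving(37.0)),  # shrinkage, T_1/2 37 d
    )
    kw.setdefault("hazard_per_phase", (0.0005, 0.0015, 0.003, 0.0005))
    kw.setdefault("sampling_days", tuple(float(d) for d in range(0, 199, 3)))
    return SimCohortConfig(phase_schedule=schedule, condition_label="AL", **kw)


def nematostella_res(**kw) -> SimCohortConfig:
    """Restricted-fed (every 3rd day) Nematostella, same cycle layout (~9-fold)."""
    schedule = (
        Phase(0, 9, _doubling(3.0)),
        Phase(9, 99, _halving(21.9)),
        Phase(99, 108, _doubling(3.1)),
        Phase(108, 198, _halving(34.2)),
    )
    kw.setdefault("hazard_per_phase", (0.0005, 0.004, 0.006, 0.0005))
    kw.setdefault("sampling_days", tuple(float(d) for d in range(0, 199, 3)))
    return SimCohortConfig(phase_schedule=schedule, condition_label="RES", **kw)


def aiptasia_symbiotic(**kw) -> SimCohortConfig:
    """Symbiotic Aiptasia: 14 d feeding then 56 d starvation, near-flat shrinkage."""
    schedule = (Phase(0, 14, _doubling(3.0)), Phase(14, 70, _halving(100.0)))
    kw.setdefault("n_individuals", 36)
    kw.setdefault("sampling_days", tuple(float(d) for d in range(0, 71, 2)))
    return SimCohortConfig(phase_schedule=schedule, condition_label="SYM", **kw)


def aiptasia_aposymbiotic(**kw) -> SimCohortConfig:
    """Aposymbiotic Aiptasia: immediate post-feeding shrinkage, T_1/2 ≈ 28 d."""
    schedule = (Phase(0, 14, _doubling(3.6)), Phase(14, 70, _halving(27.9)))
    kw.setdefault("n_individuals", 36)
    kw.setdefault("sampling_days", tuple(float(d) for d in range(0, 71, 2)))
    return SimCohortConfig(phase_schedule=schedule, condition_label="APO", **kw)


def events_day1(**kw) -> SimEventsConfig:
    """One day post-feeding: 16.2% of cells in S or G2/M, EdU index 8.3%."""
    kw.setdefault("cycle_fractions", (0.838, 0.050, 0.112))
    kw.setdefault("edu_fraction", 0.083)
    return SimEventsConfig(**kw)


def events_day5(**kw) -> SimEventsConfig:
    """Five days starved: proliferation collapsed, EdU index 2.4%."""
    kw.setdefault("cycle_fractions", (0.878, 0.032, 0.090))
    kw.setdefault("edu_fraction", 0.024)
    return SimEventsConfig(**kw)


def events_day21(**kw) -> SimEventsConfig:
    """21 days starved: S/G2/M down to 8.5%, mostly quiescent G1/G0."""
    kw.setdefault("cycle_fractions", (0.915, 0.022, 0.063))
    kw.setdefault("edu_fraction", 0.010)
    kw.setdefault("size_classes", ((3.0, 0.65), (5.0, 0.25), (8.0, 0.08), (12.0, 0.02)))
    return SimEventsConfig(**kw)


def events_refed(**kw) -> SimEventsConfig:
    """24 h after re-feeding 20-day-starved polyps: S/G2/M back to 12.1%."""
    kw.setdefault("cycle_fractions", (0.879, 0.045, 0.076))
    kw.setdefault("edu_fraction", 0.071)
    return SimEventsConfig(**kw)


_PRESETS = {
    "nematostella_al": nematostella_al,
    "nematostella_res": nematostella_res,
    "aiptasia_symbiotic": aiptasia_symbiotic,
    "aiptasia_aposymbiotic": aiptasia_aposymbiotic,
    "events_day1": events_day1,
    "events_day5": events_day5,
    "events_day21": events_day21,
    "events_refed": events_refed,
}


def load_config(path, kind: str | None = None):
    """Load a flat YAML config file into a simulation config.

    The document may name a ``preset`` (overridable field by field) or give
    the full field set of :class:`SimCohortConfig` / :class:`SimEventsConfig`
    (selected via ``kind: cohort|events`` in the file or the argument).
    ``phase_schedule`` is a list of ``[start_day, end_day, rate]`` triples.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config file {path} must be a mapping")
    preset = doc.pop("preset", None)
    kind = doc.pop("kind", kind)
    if preset is not None:
        if preset not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
        return _PRESETS[preset](**doc)
    if kind == "cohort":
        return SimCohortConfig(**doc)
    if kind == "events":
        return SimEventsConfig(**doc)
    raise ValueError("config needs either a 'preset' or kind: cohort|events")


def dump_config(cfg, path) -> None:
    """Write a config back out as flat YAML (inverse of load_config)."""
    doc = asdict(cfg)
    doc["kind"] = "cohort" if isinstance(cfg, SimCohortConfig) else "events"
    if "phase_schedule" in doc:
        doc["phase_schedule"] = [[p.start_day, p.end_day, p.rate] for p in cfg.phase_schedule]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
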