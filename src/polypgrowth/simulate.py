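"""Synthetic longitudinal cohorts and cytometry event clouds with ground truth.

These generators define the study conditions against which every downstream
stage (changepoint fitting, rate analytics, gating) is tested: multi-phase
exponential body-size trajectories with individual rate heterogeneity,
lognormal measurement noise and phase-specific mortality; and event clouds
with 2N/4N DNA peaks, an S-phase bridge, EdU-positive subpopulations,
debris, doublets and bead spike-ins.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import Phase, SimCohortConfig, SimEventsConfig

__all__ = [
    "CohortSim",
    "simulate_cohort",
    "simulate_events",
    "expected_log_size",
    "TRAJECTORY_COLUMNS",
    "EVENT_COLUMNS",
]

TRAJECTORY_COLUMNS = [
    "individual_id", "condition", "day",
    "body_area_mm2", "body_length_mm", "body_width_mm", "alive",
]
EVENT_COLUMNS = [
    "fsc_a", "fsc_h", "ssc_a", "ssc_w",
    "dna_a", "dna_w", "edu_fluor", "bead_channel", "truth_label",
]


class CohortSim(NamedTuple):
    """Trajectory table plus per-individual ground truth."""

    trajectories: pd.DataFrame
    truth: pd.DataFrame  # individual_id, rate_offset, death_day (NaN = survived)


def expected_log_size(config: SimCohortConfig, days) -> np.ndarray:
    """Noise-free population-mean log body area at each requested day.

    The mean trajectory is continuous piecewise linear: the integral of the
    phase-schedule rates from the first phase's start, anchored at
    ``start_size_logmean``.
    """
    days = np.asarray(days, dtype=float)
    out = np.full(days.shape, config.start_size_logmean, dtype=float)
    for ph in config.phase_schedule:
        dt = np.clip(days, ph.start_day, ph.end_day) - ph.start_day
        out += ph.rate * np.clip(dt, 0.0, ph.duration)
    return out


def _phase_index(schedule: tuple[Phase, ...], day: float) -> int:
    for i, ph in enumerate(schedule):
        if day < ph.end_day or i == len(schedule) - 1:
            if day >= ph.start_day:
                return i
    raise ValueError(f"day {day} outside the phase schedule")


def simulate_cohort(config: SimCohortConfig) -> CohortSim:
    """Simulate a longitudinal cohort of exponentially growing/shrinking polyps.

    Each individual's log body area follows the phase schedule with a
    constant per-individual slope offset; observations carry additive
    Gaussian noise on the log scale. Deaths are drawn daily with the hazard
    of the current phase; a dead individual contributes one terminal
    ``alive=False`` row (no size) at the first sampling day on/after death
    and nothing after.

    Returns a :class:`CohortSim` with the trajectory table and a truth table
    holding each individual's rate offset, start size and death day.
    """
    schedule = tuple(config.phase_schedule)
    if not schedule:
        raise ValueError("phase_schedule must not be empty")
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_individuals)
    t0, t1 = schedule[0].start_day, schedule[-1].end_day
    days = np.asarray(config.sampling_days, dtype=float)

    # per-day hazards on integer-day steps across the schedule span
    step_days = np.arange(np.floor(t0), np.ceil(t1))
    step_hazard = np.array([config.hazard_per_phase[_phase_index(schedule, d)] for d in step_days])

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        ind = f"{config.condition_label}-{i:03d}"
        eps = rng.normal(0.0, config.rate_heterogeneity_sd) if config.rate_heterogeneity_sd > 0 else 0.0
        log_a0 = rng.normal(config.start_size_logmean, config.start_size_logsd) \
            if config.start_size_logsd > 0 else config.start_size_logmean

        # death day: first Bernoulli success over daily steps, else survives
        u = rng.random(step_days.size)
        hits = np.nonzero(u < step_hazard)[0]
        death_day = float(step_days[hits[0]] + 1.0) if hits.size else np.nan

        # continuous piecewise-linear latent log size with slope rate + eps
        latent = np.full(days.shape, log_a0)
        for ph in schedule:
            dt = np.clip(np.clip(days, ph.start_day, ph.end_day) - ph.start_day, 0.0, ph.duration)
            latent += (ph.rate + eps) * dt
        obs = latent + (rng.normal(0.0, config.noise_sd, days.size) if config.noise_sd > 0 else 0.0)

        # allometric shape: width tracks area isometrically (area ~ W^(b+1)),
        # length scatters lognormally about L = W^b, so the fitted log-log
        # exponent is unbiased and shape_noise_sd sets the allometry R^2
        b = config.allometry_exponent
        log_w = obs / (b + 1.0)
        log_l = b * log_w
        if config.shape_noise_sd > 0:
            log_l = log_l + rng.normal(0.0, config.shape_noise_sd, days.size)

        alive_mask = days < death_day if np.isfinite(death_day) else np.ones(days.size, bool)
        for j, d in enumerate(days):
            if alive_mask[j]:
                rows.append({
                    "individual_id": ind, "condition": config.condition_label, "day": float(d),
                    "body_area_mm2": float(np.exp(obs[j])),
                    "body_length_mm": float(np.exp(log_l[j])),
                    "body_width_mm": float(np.exp(log_w[j])),
                    "alive": True,
                })
            else:
                rows.append({
                    "individual_id": ind, "condition": config.condition_label, "day": float(d),
                    "body_area_mm2": np.nan, "body_length_mm": np.nan,
                    "body_width_mm": np.nan, "alive": False,
                })
                break  # one terminal dead row, nothing after
        truth_rows.append({
            "individual_id": ind, "rate_offset": float(eps),
            "start_log_size": float(log_a0), "death_day": death_day,
        })

    traj = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return CohortSim(traj, truth)


def simulate_events(config: SimEventsConfig) -> pd.DataFrame:
    """Simulate one cytometry sample as a truth-labelled event table.

    Cells receive a cycle label per ``cycle_fractions`` (counts rounded to
    the exact configured proportions): G1/G0 DNA at the 2N peak, G2/M at
    exactly twice the 2N mean, S uniformly bridging the peaks.  FSC-A is
    proportional to diameter squared over a lognormal mixture of size
    classes.  EdU labelling fills its quota from S cells first, then G2/M,
    then G1/G0, and shifts the labelled log intensity by ``edu_separation``.
    Debris, DNA-doublets and two bead spike-ins (counting + loss) are
    appended with distinct truth labels.
    """
    if abs(sum(config.cycle_fractions) - 1.0) > 1e-9:
        raise ValueError("cycle_fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = int(config.n_cells)
    f_g1, f_s, f_g2 = config.cycle_fractions

    n_g1 = int(round(n * f_g1))
    n_s = int(round(n * f_s))
    n_g2 = n - n_g1 - n_s
    labels = np.array(["cell_G1G0"] * n_g1 + ["cell_S"] * n_s + ["cell_G2M"] * n_g2)
    rng.shuffle(labels)

    two_n = config.dna_2n_mean
    dna = np.empty(n)
    m_g1 = labels == "cell_G1G0"
    m_s = labels == "cell_S"
    m_g2 = labels == "cell_G2M"
    if config.dna_cv > 0:
        dna[m_g1] = rng.normal(two_n, config.dna_cv * two_n, m_g1.sum())
        dna[m_g2] = rng.normal(2 * two_n, config.dna_cv * 2 * two_n, m_g2.sum())
    else:
        dna[m_g1] = two_n
        dna[m_g2] = 2 * two_n
    dna[m_s] = rng.uniform(two_n, 2 * two_n, m_s.sum())
    dna = np.abs(dna)

    # size: lognormal mixture over classes, fsc_a = k * diameter^2
    diam_means = np.array([d for d, _ in config.size_classes])
    weights = np.array([w for _, w in config.size_classes], dtype=float)
    weights = weights / weights.sum()
    cls = rng.choice(diam_means.size, size=n, p=weights)
    diam = np.exp(np.log(diam_means[cls]) + rng.normal(0.0, config.size_class_logsd, n))
    fsc_a = config.fsc_per_um2 * diam**2
    fsc_h = fsc_a * rng.normal(1.0, 0.02, n)
    ssc_a = np.exp(rng.normal(np.log(200.0), 0.4, n))
    ssc_w = rng.normal(100.0, 5.0, n)
    dna_w = rng.normal(100.0, 5.0, n)

    # EdU: quota filled S -> G2M -> G1/G0 (a short pulse marks S-phase cells)
    n_edu = int(round(n * config.edu_fraction))
    order = np.concatenate([
        rng.permutation(np.nonzero(m_s)[0]),
        rng.permutation(np.nonzero(m_g2)[0]),
        rng.permutation(np.nonzero(m_g1)[0]),
    ])
    edu_pos = np.zeros(n, dtype=bool)
    edu_pos[order[:n_edu]] = True
    edu = np.exp(rng.normal(np.log(10.0), 0.5, n))
    edu[edu_pos] *= np.exp(config.edu_separation)
    bead_ch = np.exp(rng.normal(np.log(10.0), 0.5, n))

    frames = [pd.DataFrame({
        "fsc_a": fsc_a, "fsc_h": fsc_h, "ssc_a": ssc_a, "ssc_w": ssc_w,
        "dna_a": dna, "dna_w": dna_w, "edu_fluor": edu, "bead_channel": bead_ch,
        "truth_label": labels,
    })]

    other = config.debris_fraction + config.doublet_fraction
    n_total = n / (1.0 - other) if other > 0 else n
    n_debris = int(round(n_total * config.debris_fraction))
    n_doublet = int(round(n_total * config.doublet_fraction))

    if n_debris:
        d_diam = np.exp(rng.normal(np.log(1.2), 0.3, n_debris))
        d_fsc = config.fsc_per_um2 * d_diam**2
        frames.append(pd.DataFrame({
            "fsc_a": d_fsc, "fsc_h": d_fsc * rng.normal(1.0, 0.05, n_debris),
            "ssc_a": np.exp(rng.normal(np.log(8.0), 0.4, n_debris)),
            "ssc_w": rng.normal(100.0, 5.0, n_debris),
            "dna_a": rng.uniform(0.0, 0.5 * two_n, n_debris),
            "dna_w": rng.normal(100.0, 5.0, n_debris),
            "edu_fluor": np.exp(rng.normal(np.log(10.0), 0.5, n_debris)),
            "bead_channel": np.exp(rng.normal(np.log(10.0), 0.5, n_debris)),
            "truth_label": "debris",
        }))
    if n_doublet:
        # two aggregated G1-like cells: summed DNA/FSC, stretched pulse width
        db_diam = np.exp(np.log(rng.choice(diam_means, n_doublet, p=weights))
                         + rng.normal(0.0, config.size_class_logsd, n_doublet))
        db_fsc = 2 * config.fsc_per_um2 * db_diam**2
        frames.append(pd.DataFrame({
            "fsc_a": db_fsc, "fsc_h": db_fsc * rng.normal(0.6, 0.03, n_doublet),
            "ssc_a": np.exp(rng.normal(np.log(400.0), 0.4, n_doublet)),
            "ssc_w": rng.normal(150.0, 8.0, n_doublet),
            "dna_a": np.abs(rng.normal(2 * two_n, max(config.dna_cv, 1e-6) * 2 * two_n, n_doublet)),
            "dna_w": rng.normal(160.0, 8.0, n_doublet),
            "edu_fluor": np.exp(rng.normal(np.log(10.0), 0.5, n_doublet)),
            "bead_channel": np.exp(rng.normal(np.log(10.0), 0.5, n_doublet)),
            "truth_label": "doublet",
        }))

    def _bead_frame(count: int, label: str, channel_mean: float) -> pd.DataFrame:
        b_fsc = config.fsc_per_um2 * rng.normal(10.0, 0.15, count) ** 2  # 10 µm spheres
        return pd.DataFrame({
            "fsc_a": b_fsc, "fsc_h": b_fsc * rng.normal(1.0, 0.02, count),
            "ssc_a": np.exp(rng.normal(np.log(300.0), 0.1, count)),
            "ssc_w": rng.normal(100.0, 5.0, count),
            "dna_a": rng.uniform(0.0, 0.2 * two_n, count),
            "dna_w": rng.normal(100.0, 5.0, count),
            "edu_fluor": np.exp(rng.normal(np.log(10.0), 0.5, count)),
            "bead_channel": np.exp(rng.normal(np.log(channel_mean), 0.05, count)),
            "truth_label": label,
        })

    n_count_beads = int(round(config.beads_added_count * config.bead_recovery))
    if n_count_beads:
        frames.append(_bead_frame(n_count_beads, "bead_count", 5000.0))
    n_loss_beads = int(round(config.loss_beads_spiked * config.loss_bead_recovery))
    if n_loss_beads:
        frames.append(_bead_frame(n_loss_beads, "bead_loss", 500.0))

    events = pd.concat(frames, ignore_index=True)
    events = events.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1))).reset_index(drop=True)
    for col in EVENT_COLUMNS[:-1]:
        events[col] = np.abs(events[col].to_numpy(dtype=float))
    return events[EVENT_COLUMNS]
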