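"""Flow-cytometry-style quantification: gating, cell cycle, EdU, counting, sizes.

The analysis chain mirrors manual cytometry practice but with deterministic
rules: a sequential gate cascade (scatter debris, two singlet gates, DNA
pulse-width window, 2N–4N DNA envelope), cell-cycle fractions from the DNA
histogram (2N peak located by kernel smoothing, 4N fixed at twice 2N,
Gaussian windows of ±z sd around each peak, S in between), an EdU index
thresholded at a quantile of a negative control, bead-spike-in absolute
counting, dissociation-loss correction, and bead-ladder-calibrated cell
size bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .config import BeadSizeStandard, GateConfig

__all__ = [
    "GatingResult",
    "gate_cells",
    "split_beads",
    "cell_cycle_fractions",
    "cycle_windows",
    "edu_index",
    "count_cells",
    "loss_correction",
    "size_bins",
    "analyze_sample",
]

_REQUIRED = ["fsc_a", "fsc_h", "ssc_a", "ssc_w", "dna_a", "dna_w"]
_GATE_ORDER = ["scatter_debris", "fsc_a_fsc_h_singlets", "fsc_a_ssc_w",
               "dna_w_window", "dna_a_envelope"]


@dataclass
class GatingResult:
    """Per-sample quantification summary."""

    n_events_in: int
    n_cells_gated: int
    gate_log: dict[str, int]
    fractions: tuple[float, float, float] | None = None  # G1/G0, S, G2/M
    edu_index: float | None = None
    edu_s_g2m_fraction: float | None = None
    cells_per_sample: float | None = None
    recovery_factor: float | None = None
    size_bin_fractions: dict[str, float] = field(default_factory=dict)


def _require_channels(events: pd.DataFrame, channels) -> None:
    missing = [c for c in channels if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing channels: {missing}")


def split_beads(events: pd.DataFrame, cfg: GateConfig):
    """Separate bead events from the rest on the dedicated bead channel.

    Returns ``(non_beads, counting_beads, loss_beads)``; the two spike-in
    types are split by intensity band at ``cfg.counting_bead_min``.
    """
    _require_channels(events, ["bead_channel"])
    bead_mask = events["bead_channel"] > cfg.bead_channel_threshold
    beads = events[bead_mask]
    counting = beads[beads["bead_channel"] >= cfg.counting_bead_min]
    loss = beads[beads["bead_channel"] < cfg.counting_bead_min]
    return events[~bead_mask], counting, loss


def gate_cells(events: pd.DataFrame, cfg: GateConfig | None = None):
    """Sequential gating cascade; returns (gated events, provenance counts).

    Gates apply in order: scatter debris (FSC-A/SSC-A minima), FSC-A/FSC-H
    singlets (area/height ratio), FSC-A/SSC-W (pulse-width ceiling), DNA
    pulse-width window (doublet removal) and the 2N–4N DNA-intensity
    envelope. Bead events (and, when configured, chlorophyll-positive
    symbiont events) are excluded up front. The provenance log records the
    event count surviving each gate.
    """
    cfg = cfg or GateConfig()
    _require_channels(events, _REQUIRED)
    log: dict[str, int] = {"input": len(events)}
    if "bead_channel" in events.columns:
        events, _, _ = split_beads(events, cfg)
    log["non_bead"] = len(events)
    if cfg.chlorophyll_max is not None and "chlorophyll" in events.columns:
        events = events[events["chlorophyll"] <= cfg.chlorophyll_max]
        log["chlorophyll_negative"] = len(events)

    m = (events["fsc_a"] >= cfg.fsc_a_min) & (events["ssc_a"] >= cfg.ssc_a_min)
    events = events[m]
    log["scatter_debris"] = len(events)

    ratio = events["fsc_a"] / events["fsc_h"].replace(0, np.nan)
    events = events[(ratio - 1.0).abs() <= cfg.singlet_ratio_tol]
    log["fsc_a_fsc_h_singlets"] = len(events)

    events = events[events["ssc_w"] <= cfg.ssc_w_max]
    log["fsc_a_ssc_w"] = len(events)

    events = events[(events["dna_w"] >= cfg.dna_w_min) & (events["dna_w"] <= cfg.dna_w_max)]
    log["dna_w_window"] = len(events)

    events = events[(events["dna_a"] >= cfg.dna_a_min) & (events["dna_a"] <= cfg.dna_a_max)]
    log["dna_a_envelope"] = len(events)
    return events.reset_index(drop=True), log


def _locate_2n_peak(dna: np.ndarray) -> float:
    """Mode of the kernel-smoothed DNA histogram, restricted to the lower half.

    The 2N peak is the dominant mode below the midpoint of the intensity
    range (G1/G0 is always the largest population in these samples).
    """
    lo, hi = np.percentile(dna, [0.5, 99.5])
    if hi <= lo:
        return float(np.median(dna))
    kde = gaussian_kde(dna)
    grid = np.linspace(lo, hi, 512)
    dens = kde(grid)
    half = grid <= lo + 0.6 * (hi - lo)
    return float(grid[half][np.argmax(dens[half])])


def cycle_windows(dna: np.ndarray, z: float = 2.0):
    """2N/4N peak means and ±z·sd window edges from a DNA-intensity sample."""
    two_n = _locate_2n_peak(dna)
    four_n = 2.0 * two_n
    # robust per-peak sd from events near each peak (±10% of the peak mean);
    # MAD-based so the uniform S bridge does not inflate the width
    near2 = dna[np.abs(dna - two_n) <= 0.10 * two_n]
    near4 = dna[np.abs(dna - four_n) <= 0.10 * four_n]
    sd2 = 1.4826 * float(np.median(np.abs(near2 - two_n))) if near2.size >= 10 else 0.04 * two_n
    sd4 = 1.4826 * float(np.median(np.abs(near4 - four_n))) if near4.size >= 10 else 2 * sd2
    sd2 = max(sd2, 1e-9)
    sd4 = max(sd4, 1e-9)
    g1_hi = two_n + z * sd2
    g2_lo = four_n - z * sd4
    if g2_lo <= g1_hi:  # peaks merge: split midway
        mid = 0.5 * (two_n + four_n)
        g1_hi = g2_lo = mid
    return {"two_n": two_n, "four_n": four_n, "sd2": sd2, "sd4": sd4, "z": z,
            "g1_lo": two_n - z * sd2, "g1_hi": g1_hi,
            "g2_lo": g2_lo, "g2_hi": four_n + z * sd4}


def cell_cycle_fractions(dna_a, z: float = 2.0, tail_correct: bool = True):
    """(G1/G0, S, G2/M) fractions from gated DNA-dye intensities.

    G1/G0 is the 2N window (2N ± z·sd), G2/M the 4N window, S everything
    strictly between; fractions are over the union of the three windows.
    With ``tail_correct`` (default) the raw window counts are deconvolved
    for the Gaussian peak tails that spill into the S bridge and for the
    bridge portion hidden under the peak windows, by solving the expected-
    count linear system under the Gaussian-peaks + uniform-bridge model;
    without it the raw window proportions are returned. Raises if no 2N
    peak is detectable; an absent 4N population simply yields G2/M = 0.
    """
    dna = np.asarray(dna_a, dtype=float)
    dna = dna[np.isfinite(dna)]
    if dna.size == 0:
        raise ValueError("no DNA intensities supplied")
    if dna.size < 500:
        warnings.warn("fewer than 500 gated events; cycle fractions will be noisy",
                      stacklevel=2)
    if np.ptp(dna) == 0:  # degenerate: a single intensity = pure 2N peak
        return (1.0, 0.0, 0.0)
    w = cycle_windows(dna, z)
    g1 = (dna >= w["g1_lo"]) & (dna <= w["g1_hi"])
    g2 = (dna >= w["g2_lo"]) & (dna <= w["g2_hi"]) & ~g1
    s = (dna > w["g1_hi"]) & (dna < w["g2_lo"])
    counts = np.array([g1.sum(), s.sum(), g2.sum()], dtype=float)
    if counts.sum() == 0:
        raise ValueError("no events inside the 2N-4N envelope; no detectable 2N peak")
    if not tail_correct:
        frac = counts / counts.sum()
        return (float(frac[0]), float(frac[1]), float(frac[2]))

    # Expected share of each population landing in each window:
    # G1 ~ N(2N, sd2), G2M ~ N(4N, sd4), S ~ Uniform(2N, 4N).
    cov = math.erf(z / math.sqrt(2.0))  # Gaussian mass within ±z sd
    tail = 0.5 * (1.0 - cov)            # one-sided spill into the bridge
    L = w["four_n"] - w["two_n"]
    b1 = min(z * w["sd2"] / L, 1.0)     # bridge share under the 2N window
    b2 = min(z * w["sd4"] / L, 1.0)     # bridge share under the 4N window
    bm = max(1.0 - b1 - b2, 0.0)
    A = np.array([
        [cov,  b1, 0.0],   # counts in the 2N window
        [tail, bm, tail],  # counts strictly between the windows
        [0.0,  b2, cov],   # counts in the 4N window
    ])
    est = np.linalg.solve(A, counts)
    est = np.clip(est, 0.0, None)
    if est.sum() == 0:
        est = counts
    frac = est / est.sum()
    return (float(frac[0]), float(frac[1]), float(frac[2]))


def edu_index(gated: pd.DataFrame, negative_control: pd.DataFrame,
              quantile: float = 0.999, z: float = 2.0):
    """Fraction of gated cells above the control EdU threshold.

    The threshold is the configured quantile of the negative control's EdU
    fluorescence. Also reports the S/G2M proportion among EdU+ cells
    (pulse-chase bookkeeping), using the same DNA windows as
    :func:`cell_cycle_fractions`.
    """
    if len(negative_control) == 0:
        raise ValueError("negative control is empty")
    _require_channels(gated, ["edu_fluor", "dna_a"])
    _require_channels(negative_control, ["edu_fluor"])
    thr = float(np.quantile(negative_control["edu_fluor"].to_numpy(dtype=float), quantile))
    edu = gated["edu_fluor"].to_numpy(dtype=float)
    pos = edu > thr
    index = float(pos.mean()) if edu.size else 0.0
    s_g2m = math.nan
    if pos.any():
        dna = gated["dna_a"].to_numpy(dtype=float)
        w = cycle_windows(dna, z)
        dpos = dna[pos]
        in_g1 = (dpos >= w["g1_lo"]) & (dpos <= w["g1_hi"])
        in_env = (dpos >= w["g1_lo"]) & (dpos <= w["g2_hi"])
        denom = int(in_env.sum())
        s_g2m = float((in_env & ~in_g1).sum() / denom) if denom else math.nan
    return index, s_g2m


def count_cells(n_cell_events: int, n_bead_events: int, beads_added: int) -> float:
    """Absolute cells per sample from the counting-bead spike-in.

    cells = (cell events / bead events) × beads added. Exactly linear in
    the cell events and the spike-in size, inverse in the bead events.
    """
    if beads_added <= 0:
        raise ValueError("beads_added must be > 0")
    if n_bead_events <= 0:
        raise ValueError("zero bead events: spike-in failed")
    if n_cell_events < 0:
        raise ValueError("n_cell_events must be >= 0")
    return (n_cell_events / n_bead_events) * beads_added


def loss_correction(beads_recovered: int, beads_spiked: int = 200_000):
    """Dissociation-loss recovery factor and the corrected-count transform.

    Returns ``(recovery, correct)`` where ``recovery = recovered/spiked``
    and ``correct(raw_count) = raw_count / recovery``. Recovery above 1 is
    flagged as anomalous (more beads out than in) with a warning.
    """
    if beads_spiked <= 0:
        raise ValueError("beads_spiked must be > 0")
    if beads_recovered < 0:
        raise ValueError("beads_recovered must be >= 0")
    recovery = beads_recovered / beads_spiked
    if recovery == 0:
        raise ValueError("zero beads recovered: loss correction undefined")
    if recovery > 1:
        warnings.warn(f"recovery factor {recovery:.3f} > 1 is anomalous", stacklevel=2)
    return recovery, (lambda raw: raw / recovery)


def size_bins(gated: pd.DataFrame, standard: BeadSizeStandard | None = None,
              bin_edges_um=(2.0, 4.0, 6.0, 10.0, 15.0),
              extrapolate: bool = False) -> dict[str, float]:
    """Fraction of gated cells per diameter bin, via the bead size ladder.

    The ladder's (diameter, median FSC-A) pairs are interpolated
    monotonically in log-log space to map bin edges (µm) onto FSC-A
    cutoffs. Edges outside the ladder's hull raise unless ``extrapolate``.
    """
    standard = standard or BeadSizeStandard()
    edges = np.asarray(bin_edges_um, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing, >= 2 of them")
    d = np.asarray(standard.diameters_um)
    f = np.asarray(standard.median_fsc_a)
    if not extrapolate and (edges[0] < d[0] - 1e-9 or edges[-1] > d[-1] + 1e-9):
        raise ValueError("bin edge outside the bead standard's hull "
                         "(pass extrapolate=True to allow)")
    log_cut = np.interp(np.log(edges), np.log(d), np.log(f))
    if extrapolate:  # linear continuation in log-log space
        sl_lo = (np.log(f[1]) - np.log(f[0])) / (np.log(d[1]) - np.log(d[0]))
        sl_hi = (np.log(f[-1]) - np.log(f[-2])) / (np.log(d[-1]) - np.log(d[-2]))
        below = np.log(edges) < np.log(d[0])
        above = np.log(edges) > np.log(d[-1])
        log_cut[below] = np.log(f[0]) + sl_lo * (np.log(edges[below]) - np.log(d[0]))
        log_cut[above] = np.log(f[-1]) + sl_hi * (np.log(edges[above]) - np.log(d[-1]))
    cuts = np.exp(log_cut)
    fsc = gated["fsc_a"].to_numpy(dtype=float)
    counts, _ = np.histogram(fsc, bins=cuts)
    total = counts.sum()
    labels = [f"{a:g}-{b:g}um" for a, b in zip(edges[:-1], edges[1:])]
    if total == 0:
        return {lab: math.nan for lab in labels}
    return {lab: float(c) / total for lab, c in zip(labels, counts)}


def analyze_sample(events: pd.DataFrame, cfg: GateConfig | None = None,
                   negative_control: pd.DataFrame | None = None,
                   beads_added: int | None = None,
                   loss_beads_spiked: int | None = None,
                   standard: BeadSizeStandard | None = None,
                   bin_edges_um=(2.0, 4.0, 6.0, 10.0, 15.0)) -> GatingResult:
    """Full per-sample pipeline: gate, cycle fractions, EdU, counting, size bins."""
    cfg = cfg or GateConfig()
    n_in = len(events)
    _, counting_beads, loss_beads = split_beads(events, cfg) \
        if "bead_channel" in events.columns else (events, events.iloc[0:0], events.iloc[0:0])
    gated, log = gate_cells(events, cfg)
    result = GatingResult(n_events_in=n_in, n_cells_gated=len(gated), gate_log=log)
    if len(gated):
        result.fractions = cell_cycle_fractions(gated["dna_a"].to_numpy(dtype=float))
        result.size_bin_fractions = size_bins(gated, standard, bin_edges_um)
    if negative_control is not None and len(gated):
        ctrl_gated, _ = gate_cells(negative_control, cfg)
        result.edu_index, result.edu_s_g2m_fraction = edu_index(
            gated, ctrl_gated if len(ctrl_gated) else negative_control, cfg.edu_quantile)
    if beads_added is not None and len(counting_beads):
        raw = count_cells(len(gated), len(counting_beads), beads_added)
        if loss_beads_spiked:
            recovery, correct = loss_correction(len(loss_beads), loss_beads_spiked)
            result.recovery_factor = recovery
            raw = correct(raw)
        result.cells_per_sample = raw
    return result
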