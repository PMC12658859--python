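"""Synthetic SC-ICP-MS traces, mass-cytometry streams and nanoparticle runs.

The generator inverts the per-cell mass equation m_c = eta * F * t * I / b:
a lognormal per-cell mass draw is converted to an expected event intensity
I = m * b / (eta * F * t) and realised as Poisson shot noise, on top of a
Poisson count background.  Quadrupole traces carry one-dwell events (5 ms
dwell); mass-cytometry streams carry 10–150-dwell pulses with a discretised
Gaussian shape across the channels of interest, plus six-metal calibration
beads and overlapping-pulse doublets.  Cell arrival can decay exponentially
in time to emulate sedimentation of the suspension.  Every simulation
returns the ground truth alongside the instrument-shaped output so each
downstream stage can be scored against known labels and masses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import CalibrationModel
from .config import AcquisitionConfig, SimConfig
from .constants import BEAD_CHANNELS
from .cytofevents import CytofEvent, EventStream
from .scevents import TimeTrace


def default_sc_calibration(element: str = "Lu175", slope: float = 2000.0) -> CalibrationModel:
    """Reference quadrupole calibration (counts per µg/L per 5 ms dwell).

    The default slope puts a 0.18 fg Lu cell at ~900 counts in one dwell at
    eta = 0.48 and F = 10 µL/min, comfortably above a Poisson(5) background.
    """
    return CalibrationModel(element=element, slope=slope, intercept=0.0,
                            intercept_sd=0.0, r_squared=1.0,
                            abundance_factor=0.974 if element.startswith("Lu") else 1.0)


#: mass-cytometry sensitivities, DC per µg/L per 13 µs dwell.  Lu at 2.5
#: puts a 0.17 fg cell near 430 integrated DC (eta = 0.15, F = 30 µL/min),
#: matching the DC scale of antibody-label positives; Ir is set brighter, as
#: for a DNA intercalator, so the trigger rides on a strong channel.
_CYTOF_SLOPES = {"Lu175": 2.5, "Ir191": 25.0, "Ir193": 25.0}


def default_cytof_calibrations(
    channels: Sequence[str] = ("Ir191", "Ir193", "Lu175"),
) -> dict[str, CalibrationModel]:
    """Reference per-channel mass-cytometry calibrations."""
    out = {}
    for ch in channels:
        out[ch] = CalibrationModel(
            element=ch, slope=_CYTOF_SLOPES.get(ch, 2.5), intercept=0.0,
            intercept_sd=0.0, r_squared=1.0,
            abundance_factor=0.974 if ch.startswith("Lu") else 1.0,
        )
    return out


def expected_event_intensity(
    mass_fg: float | np.ndarray,
    calib: CalibrationModel,
    acq: AcquisitionConfig,
) -> float | np.ndarray:
    """Expected intensity I (counts) for a cell of the given mass.

    Inverse of the mass equation: I = m * b / (eta * F * t), with t the
    dwell time (for multi-point pulses this is the *total* expected counts
    summed over the pulse, since the equation applies to the summed
    intensity at the per-point dwell).
    """
    if acq.transport_efficiency is None:
        raise ValueError("acquisition config has no transport efficiency set")
    mass_g = np.asarray(mass_fg, dtype=float) * 1e-15
    denom = acq.transport_efficiency * acq.flow_l_per_s * acq.dwell_time_s
    out = mass_g * calib.slope_counts_per_g_per_l / denom
    return float(out) if np.isscalar(mass_fg) else out


def _lognormal_masses(rng: np.random.Generator, median_fg: float, gsd: float,
                      size: int) -> np.ndarray:
    sigma = math.log(gsd) if gsd > 1 else 0.0
    return rng.lognormal(mean=math.log(median_fg), sigma=sigma, size=size)


def _sedimentation_weights(times_s: np.ndarray, halflife_s: float) -> np.ndarray:
    if math.isinf(halflife_s):
        return np.ones_like(times_s)
    # exponential thinning with the given half-life
    return np.exp2(-times_s / halflife_s)


@dataclass
class SimulatedTrace:
    """A synthetic single-element trace plus its ground truth."""

    trace: TimeTrace
    truth: pd.DataFrame  # one row per event: dwell_index, mass_fg, n_cells
    config: dict

    def write(self, prefix: str | Path) -> None:
        """Write trace CSV, ground-truth sidecar CSV and config JSON."""
        prefix = Path(prefix)
        self.trace.to_csv(prefix.with_suffix(".trace.csv"))
        self.truth.to_csv(prefix.with_suffix(".truth.csv"), index=False)
        prefix.with_suffix(".config.json").write_text(json.dumps(self.config, indent=2))


def simulate_sc_trace(
    sim: SimConfig,
    acq: AcquisitionConfig,
    calib: CalibrationModel,
    split_events: bool = False,
) -> SimulatedTrace:
    """Simulate a sequential-quadrupole single-cell run for one element.

    Background dwells are Poisson(background_lambda); each cell deposits its
    Poisson-realised expected intensity into exactly one dwell (two adjacent
    dwells with ``split_events``, for robustness studies).  Cell arrivals
    are a Poisson process optionally thinned by sedimentation; a
    ``doublet_fraction`` of events carries the mass of two cells.
    """
    if acq.duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(sim.seed)
    n = acq.n_dwells
    trace_counts = rng.poisson(sim.background_lambda, size=n).astype(float)

    times = np.arange(n) * acq.dwell_time_s
    weights = _sedimentation_weights(times, sim.sedimentation_halflife_s)
    expected_events = sim.event_rate * acq.dwell_time_s * weights.sum()
    n_events = min(rng.poisson(expected_events), n) if expected_events > 0 else 0

    if n_events:
        p = weights / weights.sum()
        idx = np.sort(rng.choice(n, size=n_events, replace=False, p=p))
        masses = _lognormal_masses(rng, sim.cell_mass_median_fg, sim.cell_mass_gsd,
                                   n_events)
        n_cells = np.ones(n_events, dtype=int)
        if sim.doublet_fraction > 0:
            is_doublet = rng.random(n_events) < sim.doublet_fraction
            masses = masses + np.where(
                is_doublet,
                _lognormal_masses(rng, sim.cell_mass_median_fg, sim.cell_mass_gsd,
                                  n_events),
                0.0,
            )
            n_cells += is_doublet.astype(int)
        lam = expected_event_intensity(masses, calib, acq)
        if split_events:
            frac = rng.uniform(0.3, 0.7, size=n_events)
            first = rng.poisson(lam * frac)
            second = rng.poisson(lam * (1 - frac))
            trace_counts[idx] += first
            nxt = np.minimum(idx + 1, n - 1)
            np.add.at(trace_counts, nxt, second)
        else:
            trace_counts[idx] += rng.poisson(lam)
        truth = pd.DataFrame(
            {"dwell_index": idx, "mass_fg": masses, "n_cells": n_cells}
        )
    else:
        truth = pd.DataFrame(columns=["dwell_index", "mass_fg", "n_cells"])

    trace = TimeTrace(
        element=calib.element,
        dwell_time_s=acq.dwell_time_s,
        intensities=trace_counts,
        run_id=f"sim-seed{sim.seed}",
    )
    cfg = {"seed": sim.seed, "background_lambda": sim.background_lambda,
           "event_rate": sim.event_rate, "median_fg": sim.cell_mass_median_fg,
           "gsd": sim.cell_mass_gsd, "halflife_s": sim.sedimentation_halflife_s,
           "doublet_fraction": sim.doublet_fraction, "split_events": split_events}
    return SimulatedTrace(trace=trace, truth=truth, config=cfg)


#: default median Ir masses (fg/cell) for the DNA intercalator, split across
#: the two monitored isotopes by natural abundance (0.5 fg total Ir).
_DEFAULT_IR_MEDIANS_FG = {"Ir191": 0.5 * 0.373, "Ir193": 0.5 * 0.627}

#: expected integrated DC per bead in each bead metal channel (EQ-style
#: beads are bright and present in all six metals).
_DEFAULT_BEAD_DC = {c: 3000.0 for c in BEAD_CHANNELS}


@dataclass
class CytofSimulation:
    """A synthetic multichannel stream plus per-event ground truth."""

    stream: EventStream
    truth: pd.DataFrame  # label, start_index, duration_points, mass_fg_<ch>...
    config: dict

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        times = np.arange(self.stream.n_dwells) * self.stream.dwell_time_s
        df = pd.DataFrame(self.stream.counts, columns=self.stream.channels)
        df.insert(0, "time_s", times)
        df.to_csv(prefix.with_suffix(".stream.csv"), index=False)
        self.truth.to_csv(prefix.with_suffix(".truth.csv"), index=False)
        prefix.with_suffix(".config.json").write_text(json.dumps(self.config, indent=2))


def _gaussian_pulse_weights(duration: int) -> np.ndarray:
    x = np.arange(duration) - (duration - 1) / 2.0
    sigma = max(duration / 6.0, 0.5)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def simulate_cytof_stream(
    sim: SimConfig,
    acq: AcquisitionConfig,
    calibrations: Sequence[CalibrationModel] | Mapping[str, CalibrationModel],
    min_gap_dwells: int = 20,
    bead_dc: Mapping[str, float] | None = None,
) -> CytofSimulation:
    """Simulate a mass-cytometry per-dwell multichannel count stream.

    Cell events are contiguous pulses of 10–150 dwells with a discretised
    Gaussian envelope; the summed expected counts per channel follow from
    the cell's mass in that channel through the mass equation.  Beads carry
    bright signal in all six bead metals; doublets are two overlapping
    pulses recorded as a single ground-truth row.  Events are laid down
    sequentially with a guaranteed inter-event gap so that ground-truth
    labels stay unambiguous (accidental pile-up would be indistinguishable
    from a deliberate doublet).
    """
    if isinstance(calibrations, Mapping):
        calib_map = dict(calibrations)
    else:
        calib_map = {c.element: c for c in calibrations}
    if not calib_map:
        raise ValueError("need at least one channel calibration")
    channels = list(calib_map)
    rng = np.random.default_rng(sim.seed)
    n = acq.n_dwells
    nch = len(channels)

    if sim.background_lambda > 0:
        counts = rng.poisson(sim.background_lambda, size=(n, nch)).astype(np.int32)
    else:
        counts = np.zeros((n, nch), dtype=np.int32)

    medians = dict(_DEFAULT_IR_MEDIANS_FG)
    medians["Lu175"] = sim.cell_mass_median_fg
    if sim.channel_mass_median_fg is not None:
        medians.update(sim.channel_mass_median_fg)
    cell_channels = [c for c in channels if c in medians]
    bead_expected = dict(_DEFAULT_BEAD_DC if bead_dc is None else bead_dc)

    mean_dur = (10 + 150) / 2.0
    target_events = sim.event_rate * acq.duration_s
    if target_events <= 0:
        truth = pd.DataFrame(columns=["label", "start_index", "duration_points"]
                             + [f"mass_fg_{c}" for c in cell_channels])
        stream = EventStream(acq.dwell_time_s, channels, counts)
        return CytofSimulation(stream, truth, {"seed": sim.seed})

    mean_gap = max(n / target_events - mean_dur - min_gap_dwells, float(min_gap_dwells))

    def add_pulse(start: int, duration: int, totals: dict[str, float]) -> None:
        w = _gaussian_pulse_weights(duration)
        for ch, total in totals.items():
            k = channels.index(ch)
            counts[start:start + duration, k] += rng.poisson(total * w).astype(np.int32)

    def cell_totals() -> tuple[dict[str, float], dict[str, float]]:
        masses = {c: float(_lognormal_masses(rng, medians[c], sim.cell_mass_gsd, 1)[0])
                  for c in cell_channels}
        totals = {c: expected_event_intensity(masses[c], calib_map[c], acq)
                  for c in cell_channels}
        return masses, totals

    rows: list[dict] = []
    pos = 0
    while True:
        gap = min_gap_dwells + rng.exponential(mean_gap)
        start = pos + int(round(gap))
        if start >= n - 160:
            break
        t_s = start * acq.dwell_time_s
        if not math.isinf(sim.sedimentation_halflife_s):
            if rng.random() > 2.0 ** (-t_s / sim.sedimentation_halflife_s):
                pos = start  # cell sedimented out; advance without an event
                continue
        is_bead = rng.random() < sim.bead_fraction
        if is_bead:
            duration = int(rng.integers(10, 41))
            totals = {c: float(rng.lognormal(math.log(bead_expected[c]), math.log(1.15)))
                      for c in bead_expected if c in channels}
            add_pulse(start, duration, totals)
            row = {"label": "bead", "start_index": start, "duration_points": duration}
            row.update({f"mass_fg_{c}": np.nan for c in cell_channels})
            end = start + duration
        else:
            d1 = int(rng.integers(10, 151))
            masses, totals = cell_totals()
            add_pulse(start, d1, totals)
            label, span = "cell", d1
            if rng.random() < sim.doublet_fraction:
                # near-coincident second cell: strong pulse overlap (the two
                # envelopes merge into one trigger run) with comparable width,
                # so the composite shows the two-peaks-and-valley shape that
                # multiplet gating keys on
                offset = int(round(rng.uniform(0.6, 0.8) * d1))
                d2 = int(np.clip(round(d1 * rng.uniform(0.8, 1.25)), 10, 150))
                masses2, totals2 = cell_totals()
                add_pulse(start + offset, d2, totals2)
                masses = {c: masses[c] + masses2[c] for c in masses}
                label, span = "doublet", max(d1, offset + d2)
            row = {"label": label, "start_index": start, "duration_points": span}
            row.update({f"mass_fg_{c}": masses[c] for c in cell_channels})
            end = start + span
        rows.append(row)
        pos = end

    truth = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["label", "start_index", "duration_points"]
        + [f"mass_fg_{c}" for c in cell_channels]
    )
    stream = EventStream(acq.dwell_time_s, channels, counts)
    cfg = {"seed": sim.seed, "event_rate": sim.event_rate,
           "bead_fraction": sim.bead_fraction, "doublet_fraction": sim.doublet_fraction,
           "median_fg": sim.cell_mass_median_fg, "gsd": sim.cell_mass_gsd,
           "halflife_s": sim.sedimentation_halflife_s}
    return CytofSimulation(stream=stream, truth=truth, config=cfg)


def _match_truth_rows(events: Sequence[CytofEvent], truth: pd.DataFrame) -> np.ndarray:
    """Index of the overlapping ground-truth row per event (-1 = background)."""
    out = np.full(len(events), -1, dtype=int)
    if truth.empty:
        return out
    starts = truth["start_index"].to_numpy()
    ends = starts + truth["duration_points"].to_numpy()
    for i, ev in enumerate(events):
        s, e = ev.start_index, ev.start_index + ev.duration_points
        j = int(np.searchsorted(starts, e)) - 1
        if j >= 0 and ends[j] > s:
            out[i] = j
    return out


def match_events_to_truth(events: Sequence[CytofEvent], truth: pd.DataFrame) -> list[str]:
    """Assign each detected event the overlapping ground-truth label.

    Truth intervals are non-overlapping by construction; an event with no
    overlap is labelled ``background``.
    """
    rows = _match_truth_rows(events, truth)
    labels = truth["label"].to_numpy() if not truth.empty else np.array([])
    return [str(labels[j]) if j >= 0 else "background" for j in rows]


def score_gating(
    events: Sequence[CytofEvent],
    gated_table: pd.DataFrame,
    truth: pd.DataFrame,
) -> dict[str, float]:
    """Score gating decisions against generator ground truth.

    A ground-truth bead or doublet counts as *removed* when no detected
    event overlapping it survives as a retained cell (flagged, or excluded
    by the duration gates); recall is the removed fraction.  Bead precision
    is 1 minus the fraction of true cells whose events carry a bead flag.
    Ground-truth cells count as retained when at least one overlapping
    event is kept.
    """
    rows = _match_truth_rows(events, truth)
    retained = gated_table["cell"].to_numpy(dtype=bool)
    bead_flags = gated_table["bead"].to_numpy(dtype=bool)
    n_truth = len(truth)
    kept_by_truth = np.zeros(n_truth, dtype=bool)
    bead_flag_by_truth = np.zeros(n_truth, dtype=bool)
    for i, j in enumerate(rows):
        if j >= 0:
            kept_by_truth[j] |= retained[i]
            bead_flag_by_truth[j] |= bead_flags[i]
    labels = truth["label"].to_numpy()

    def _frac(mask_num: np.ndarray, mask_den: np.ndarray) -> float:
        den = int(mask_den.sum())
        return float(mask_num.sum() / den) if den else float("nan")

    is_cell, is_bead, is_doublet = (labels == "cell"), (labels == "bead"), (labels == "doublet")
    return {
        "bead_recall": _frac(is_bead & ~kept_by_truth, is_bead),
        "doublet_recall": _frac(is_doublet & ~kept_by_truth, is_doublet),
        "cell_retention": _frac(is_cell & kept_by_truth, is_cell),
        "bead_precision": 1.0 - _frac(is_cell & bead_flag_by_truth, is_cell),
        "n_beads": float(is_bead.sum()),
        "n_doublets": float(is_doublet.sum()),
        "n_cells": float(is_cell.sum()),
    }


def simulate_np_counting_run(
    particle_conc_per_ml: float,
    acq: AcquisitionConfig,
    completeness: float,
    seed: int = 0,
    background_lambda: float = 5.0,
    spike_mean_counts: float = 1000.0,
) -> SimulatedTrace:
    """Simulate a nanoparticle-counting run for transport-efficiency work.

    ``completeness`` is the ground-truth transport efficiency: the number of
    detected spikes is Poisson(conc * F * duration * completeness), each a
    bright one-dwell transient on a Poisson background.
    """
    if particle_conc_per_ml < 0:
        raise ValueError("particle concentration must be >= 0")
    if not (0 <= completeness <= 1):
        raise ValueError("completeness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = acq.n_dwells
    trace_counts = rng.poisson(background_lambda, size=n).astype(float)
    introduced = particle_conc_per_ml * acq.flow_ml_per_s * acq.duration_s
    n_spikes = min(rng.poisson(introduced * completeness), n)
    if n_spikes:
        idx = np.sort(rng.choice(n, size=n_spikes, replace=False))
        trace_counts[idx] += rng.poisson(spike_mean_counts, size=n_spikes)
        truth = pd.DataFrame({"dwell_index": idx})
    else:
        truth = pd.DataFrame(columns=["dwell_index"])
    trace = TimeTrace(element="AuNP", dwell_time_s=acq.dwell_time_s,
                      intensities=trace_counts, run_id=f"np-seed{seed}")
    cfg = {"seed": seed, "particle_conc_per_ml": particle_conc_per_ml,
           "completeness": completeness, "introduced": introduced}
    return SimulatedTrace(trace=trace, truth=truth, config=cfg)
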