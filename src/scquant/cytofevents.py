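"""Mass-cytometry event building and gating.

A mass-cytometer records per-dwell (13 µs) Dual Counts in many metal
channels; a cell passing the plasma produces a contiguous pulse of 10–150
dwells.  ``build_events`` segments the stream into candidate events by
thresholding the summed trigger-channel signal at 10 DC and sums the ion
counts of every event per channel.  ``gate_events`` then reproduces the
standard clean-up sequence: calibration beads are recognised by their
content of bead-exclusive metals (Y/In/Ce/Tb/Bi — Lu is shared with the
antibody label and is never used for the bead call), and cell multiplets by
a bimodal intra-event pulse shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .constants import BEAD_CHANNELS, CELL_CHANNELS, fcs_channel_name
from . import fcsio


@dataclass
class EventStream:
    """Rectangular per-dwell, per-channel Dual Count matrix."""

    dwell_time_s: float
    channels: list[str]
    counts: np.ndarray  # shape (n_dwells, n_channels)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not self.dwell_time_s > 0:
            raise ValueError("dwell_time_s must be positive")
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.channels):
            raise ValueError("counts must be (n_dwells, n_channels)")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")

    @property
    def n_dwells(self) -> int:
        return self.counts.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise ValueError(f"unknown channel {name!r}; have {self.channels}") from None


@dataclass
class CytofEvent:
    """One integrated candidate event.

    ``integrated_dc`` holds the per-channel summed Dual Counts over the
    event's dwells — the intensity I entering the mass equation in
    mass-cytometry mode.  ``profile`` keeps the per-dwell trigger-channel
    sum for shape-based multiplet gating.
    """

    start_index: int
    duration_points: int
    integrated_dc: np.ndarray
    channels: list[str]
    profile: np.ndarray
    flags: dict = field(default_factory=dict)

    def dc(self, channel: str) -> float:
        return float(self.integrated_dc[self.channels.index(channel)])

    @property
    def valid(self) -> bool:
        return bool(self.flags.get("valid", False))


def build_events(
    stream: EventStream,
    trigger_channels: Sequence[str],
    trigger_threshold: float = 10.0,
    min_points: int = 10,
    max_points: int = 150,
    per_channel_trigger: bool = False,
) -> list[CytofEvent]:
    """Segment the stream into integrated events.

    An event is a maximal run of contiguous dwells whose summed
    trigger-channel DC reaches ``trigger_threshold`` (with
    ``per_channel_trigger`` any single trigger channel suffices instead).
    Per-channel DC are summed over the run; runs shorter than
    ``min_points`` or longer than ``max_points`` are flagged too_short /
    too_long and excluded from the valid set.
    """
    trig_idx = [stream.channel_index(c) for c in trigger_channels]
    trig_counts = stream.counts[:, trig_idx]
    if per_channel_trigger:
        above = (trig_counts >= trigger_threshold).any(axis=1)
    else:
        above = trig_counts.sum(axis=1) >= trigger_threshold
    trig_sum = trig_counts.sum(axis=1)

    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(np.int8), [0]))))
    starts, ends = edges[0::2], edges[1::2]

    events: list[CytofEvent] = []
    for s, e in zip(starts, ends):
        duration = int(e - s)
        integrated = stream.counts[s:e].sum(axis=0).astype(float)
        flags = {
            "too_short": duration < min_points,
            "too_long": duration > max_points,
            "bead": False,
            "doublet": False,
        }
        flags["valid"] = not (flags["too_short"] or flags["too_long"])
        events.append(
            CytofEvent(
                start_index=int(s),
                duration_points=duration,
                integrated_dc=integrated,
                channels=list(stream.channels),
                profile=trig_sum[s:e].astype(float),
                flags=flags,
            )
        )
    return events


def _is_bimodal(profile: np.ndarray, valley_frac: float, smooth_window: int,
                peak_frac: float) -> bool:
    """Two local maxima separated by a valley below valley_frac of the smaller.

    ``smooth_window = 0`` selects an adaptive boxcar of ~1/12 of the event
    duration (odd, between 3 and 9): enough to suppress shot noise without
    washing out the valley of short two-cell pulses.
    """
    if profile.size < 3:
        return False
    if smooth_window == 0:
        smooth_window = int(np.clip(profile.size // 12 * 2 + 1, 3, 9))
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        p = np.convolve(profile, kernel, mode="same")
    else:
        p = profile.astype(float)
    top = p.max()
    if top <= 0:
        return False
    peaks, _ = find_peaks(p, height=peak_frac * top, prominence=peak_frac * top)
    if peaks.size < 2:
        return False
    order = np.argsort(p[peaks])[::-1]
    i, j = sorted(peaks[order[:2]])
    valley = p[i:j + 1].min()
    return valley < valley_frac * min(p[i], p[j])


@dataclass
class GatingReport:
    n_input: int
    n_too_short: int
    n_too_long: int
    n_bead: int
    n_doublet: int
    n_cells: int
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n_input", "n_too_short", "n_too_long", "n_bead", "n_doublet", "n_cells")}


def gate_events(
    events: list[CytofEvent],
    bead_channels: Sequence[str] = BEAD_CHANNELS,
    cell_channels: Sequence[str] = CELL_CHANNELS,
    bead_threshold_dc: float = 100.0,
    min_bead_channels: int = 3,
    valley_frac: float = 0.75,
    smooth_window: int = 0,
    peak_frac: float = 0.1,
) -> tuple[pd.DataFrame, GatingReport]:
    """Flag beads and multiplets; return the gated table and a report.

    Beads show integrated DC above ``bead_threshold_dc`` in at least
    ``min_bead_channels`` of the bead-exclusive metals (bead channels minus
    cell channels, i.e. Y/In/Ce/Tb/Bi by default).  Remaining valid events
    with a bimodal trigger profile (valley below ``valley_frac`` of the
    smaller of two peaks) are flagged doublet.  The table contains all
    events with their flags; retained cells are rows with cell == True.
    """
    warnings: list[str] = []
    if not events:
        warnings.append("empty event list")
        empty = pd.DataFrame(columns=["start_index", "duration_points", "cell"])
        return empty, GatingReport(0, 0, 0, 0, 0, 0, warnings)

    bead_exclusive = [c for c in bead_channels if c not in cell_channels]
    channels = events[0].channels
    rows = []
    for ev in events:
        if ev.valid:
            n_hot = sum(ev.dc(c) > bead_threshold_dc for c in bead_exclusive if c in channels)
            ev.flags["bead"] = n_hot >= min_bead_channels
            if not ev.flags["bead"]:
                ev.flags["doublet"] = _is_bimodal(
                    ev.profile, valley_frac, smooth_window, peak_frac
                )
        row = {
            "start_index": ev.start_index,
            "duration_points": ev.duration_points,
            **{c: ev.integrated_dc[k] for k, c in enumerate(channels)},
            **{f: ev.flags[f] for f in ("valid", "too_short", "too_long", "bead", "doublet")},
        }
        row["cell"] = ev.valid and not ev.flags["bead"] and not ev.flags["doublet"]
        rows.append(row)
    table = pd.DataFrame(rows)
    report = GatingReport(
        n_input=len(events),
        n_too_short=int(table["too_short"].sum()),
        n_too_long=int(table["too_long"].sum()),
        n_bead=int(table["bead"].sum()),
        n_doublet=int(table["doublet"].sum()),
        n_cells=int(table["cell"].sum()),
        warnings=warnings,
    )
    return table, report


def events_to_fcs(path: str | Path, table: pd.DataFrame, channels: Sequence[str],
                  cells_only: bool = True) -> None:
    """Export integrated intensities of gated events as an FCS 3.0 file."""
    sel = table[table["cell"]] if (cells_only and "cell" in table) else table
    out = sel[list(channels)].rename(columns={c: fcs_channel_name(c) for c in channels})
    fcsio.write_fcs(path, out)
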