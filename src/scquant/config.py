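"""Acquisition and simulation configuration objects.

``AcquisitionConfig`` carries the instrument-side quantities entering the
per-cell mass equation m_c = eta * F * t * I / b: the sample flow F, the
dwell (integration) time t and the transport efficiency eta.  ``SimConfig``
carries the statistical structure of a synthetic run (background, event
rate, per-cell mass distribution, sedimentation, doublets, beads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from . import units


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument acquisition settings for one run.

    Parameters
    ----------
    flow_rate_ul_min : sample uptake flow, µL/min (10 for the quadrupole
        syringe pump, 30 for the mass-cytometer loop in the reference setups).
    dwell_time_s : integration time of one data point, s (5e-3 quadrupole,
        13e-6 mass cytometer).
    duration_s : total acquisition length, s.
    transport_efficiency : fraction eta of nebulised sample reaching the
        plasma, in (0, 1]; ``None`` until measured.
    """

    flow_rate_ul_min: float
    dwell_time_s: float
    duration_s: float
    transport_efficiency: float | None = None

    def __post_init__(self) -> None:
        for name in ("flow_rate_ul_min", "dwell_time_s", "duration_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        eta = self.transport_efficiency
        if eta is not None and not (0 < eta <= 1):
            raise ValueError("transport_efficiency must lie in (0, 1]")

    @property
    def flow_l_per_s(self) -> float:
        return units.flow_to_l_per_s(self.flow_rate_ul_min, "uL/min")

    @property
    def flow_ml_per_s(self) -> float:
        return self.flow_l_per_s * 1e3

    @property
    def n_dwells(self) -> int:
        return int(round(self.duration_s / self.dwell_time_s))

    def with_eta(self, eta: float) -> "AcquisitionConfig":
        return replace(self, transport_efficiency=eta)


@dataclass(frozen=True)
class SimConfig:
    """Statistical description of a synthetic single-cell run.

    Defaults describe the sequential-quadrupole Lu measurement of the
    antibody-labelled leukemia cell line: a clean heavy-metal channel
    (Poisson background of 1e-3 counts per 5 ms dwell, i.e. ~0.2 cps dark
    counts at m/z 175 — washed cells contribute no dissolved Lu; a
    phosphorus-like channel warrants a far higher value), ~1.7 cells/s
    (≈300 events in a 3 min run), lognormal per-cell Lu mass with median
    0.18 fg, stable suspension (infinite sedimentation half-life), no
    doublets or beads unless requested.
    """

    seed: int = 0
    background_lambda: float = 1e-3
    event_rate: float = 1.7
    cell_mass_median_fg: float = 0.18
    cell_mass_gsd: float = 1.6
    sedimentation_halflife_s: float = math.inf
    doublet_fraction: float = 0.0
    bead_fraction: float = 0.0
    #: per-channel median masses (fg) for multichannel streams; ``None`` means
    #: {Lu175: cell_mass_median_fg} plus Ir split by natural isotope abundance.
    channel_mass_median_fg: Mapping[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.background_lambda < 0:
            raise ValueError("background_lambda must be >= 0")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.cell_mass_gsd < 1:
            raise ValueError("cell_mass_gsd must be >= 1")
        for name in ("doublet_fraction", "bead_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sedimentation_halflife_s <= 0:
            raise ValueError("sedimentation_halflife_s must be positive (inf = stable)")


#: Reference acquisition settings for the two instrument modes.
SC_ACQUISITION = AcquisitionConfig(
    flow_rate_ul_min=10.0, dwell_time_s=5e-3, duration_s=180.0, transport_efficiency=0.48
)
CYTOF_ACQUISITION = AcquisitionConfig(
    flow_rate_ul_min=30.0, dwell_time_s=13e-6, duration_s=180.0, transport_efficiency=0.15
)
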