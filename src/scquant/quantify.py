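"""Per-cell mass and receptor-number quantification.

The central relation is m_c = eta * F * t * I / b: transport efficiency
times flow times integration time gives the effective sample volume behind
one data point, I / b converts the event intensity to a concentration
through the calibration slope, and their product is the element mass in
the cell.  In sequential-quadrupole mode I is the single-point event
intensity and t the 5 ms dwell; in mass-cytometry mode I is the summed
per-point intensity of the 10–150-point event and t the 13 µs per-point
dwell, which makes the two branches dimensionally identical.

Downstream conversions: label-metal mass -> bound antibodies (via the
metal:antibody stoichiometry) -> receptors per cell; and the proportional
Dual-Count -> molecules mapping anchored at a known (DC, molecules) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import units
from .calibrate import CalibrationModel
from .config import AcquisitionConfig
from .constants import AVOGADRO, MOLAR_MASS_G_PER_MOL


@dataclass
class CellQuantResult:
    """Per-cell masses for one element in one run/replicate."""

    masses_fg: np.ndarray
    element: str
    mode: str  # "sc_icpms" | "cytof"
    replicate: int = 0

    def __post_init__(self) -> None:
        self.masses_fg = np.asarray(self.masses_fg, dtype=float)
        if np.any(self.masses_fg < 0):
            raise ValueError("per-cell masses must be non-negative")
        if self.mode not in ("sc_icpms", "cytof"):
            raise ValueError("mode must be 'sc_icpms' or 'cytof'")

    @property
    def median_fg(self) -> float:
        return float(np.median(self.masses_fg)) if self.masses_fg.size else float("nan")

    @property
    def n_events(self) -> int:
        return int(self.masses_fg.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mass_fg": self.masses_fg,
                             "element": self.element,
                             "mode": self.mode,
                             "replicate": self.replicate})


@dataclass(frozen=True)
class AntibodyStoichiometry:
    """Average label-metal atoms per antibody molecule (e.g. Lu:Ab = 76 ± 2)."""

    metal_atoms_per_antibody: float
    uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if not self.metal_atoms_per_antibody > 0:
            raise ValueError("stoichiometric ratio must be positive")


@dataclass(frozen=True)
class DcToMoleculeAnchor:
    """Proportional Dual-Count -> molecules-per-cell conversion through origin."""

    anchor_dc: float
    anchor_molecules: float

    def __post_init__(self) -> None:
        if not (self.anchor_dc > 0 and self.anchor_molecules > 0):
            raise ValueError("anchor DC and molecules must both be positive")


def mass_per_event(
    intensity: float | np.ndarray,
    model: CalibrationModel,
    acq: AcquisitionConfig,
) -> float | np.ndarray:
    """m_c = eta * F * t * I / b, returned in fg.

    ``intensity`` is the event intensity I in counts (single point for the
    quadrupole, per-point sum for mass cytometry); accepts scalars or
    arrays.
    """
    I = np.asarray(intensity, dtype=float)
    if np.any(I < 0):
        raise ValueError("event intensity must be non-negative")
    if acq.transport_efficiency is None:
        raise ValueError("acquisition config has no transport efficiency set")
    volume_l = acq.transport_efficiency * acq.flow_l_per_s * acq.dwell_time_s
    mass_g = volume_l * I / model.slope_counts_per_g_per_l
    out = units.g_to_fg(mass_g)
    return float(out) if np.isscalar(intensity) else out


def quantify_events(
    intensities: Sequence[float] | np.ndarray,
    model: CalibrationModel,
    acq: AcquisitionConfig,
    mode: str,
    replicate: int = 0,
) -> CellQuantResult:
    """Convert a set of event intensities to a per-cell mass result."""
    masses = mass_per_event(np.asarray(intensities, dtype=float), model, acq)
    return CellQuantResult(masses_fg=masses, element=model.element, mode=mode,
                           replicate=replicate)


def clean_artifacts(result: CellQuantResult, k: float = 1.5) -> CellQuantResult:
    """Remove non-cell artifacts from a quadrupole event set.

    Quadrupole event sets are curated by hand in routine practice: detector
    dark counts crossing the converged threshold appear as events of a few
    counts, orders of magnitude below real cells.  This automates that
    curation with Tukey fences of width ``k``*IQR applied on the log-mass
    scale — the natural scale for lognormal per-cell masses, where such
    artifacts are extreme low outliers while genuine dim cells and cell
    doublets stay inside the fences.  Zero-mass entries are always
    artifacts.
    """
    masses = result.masses_fg
    positive = masses > 0
    if not positive.any():
        return CellQuantResult(masses_fg=masses[:0], element=result.element,
                               mode=result.mode, replicate=result.replicate)
    logs = np.log(masses[positive])
    q1, q3 = np.percentile(logs, [25, 75])
    iqr = q3 - q1
    keep = (logs >= q1 - k * iqr) & (logs <= q3 + k * iqr)
    return CellQuantResult(masses_fg=masses[positive][keep], element=result.element,
                           mode=result.mode, replicate=result.replicate)


def receptors_per_cell(
    mass_fg: float | np.ndarray,
    stoich: AntibodyStoichiometry,
    molar_mass_g_per_mol: float = MOLAR_MASS_G_PER_MOL["Lu"],
) -> float | np.ndarray:
    """Label-metal mass per cell -> receptor (bound antibody) number.

    receptors = (m / M) * N_A / ratio, assuming one antibody per receptor
    and ``ratio`` metal atoms per antibody.
    """
    mass_g = np.asarray(mass_fg, dtype=float) * 1e-15
    atoms = mass_g / molar_mass_g_per_mol * AVOGADRO
    out = atoms / stoich.metal_atoms_per_antibody
    return float(out) if np.isscalar(mass_fg) else out


def stoichiometry_from_concentrations(
    metal_conc: float,
    ab_conc: float,
    metal_unit: str = "mol/L",
    ab_unit: str = "mol/L",
    metal_molar_mass: float = MOLAR_MASS_G_PER_MOL["Lu"],
    ab_molar_mass: float | None = None,
    uncertainty: float = 0.0,
) -> AntibodyStoichiometry:
    """Metal:antibody ratio from co-measured concentrations of one solution.

    Both concentrations refer to the same (chromatographic) antibody
    fraction; mass-per-volume units are converted to molar through the
    respective molar masses before ratioing.
    """
    n_metal = units.conc_to_mol_per_l(metal_conc, metal_unit, metal_molar_mass)
    n_ab = units.conc_to_mol_per_l(ab_conc, ab_unit, ab_molar_mass)
    if n_ab <= 0:
        raise ValueError("antibody concentration must be positive")
    return AntibodyStoichiometry(metal_atoms_per_antibody=n_metal / n_ab,
                                 uncertainty=uncertainty)


def dc_to_molecules(
    dc: float | np.ndarray,
    anchor: DcToMoleculeAnchor,
) -> float | np.ndarray:
    """Proportional Dual-Count -> molecules conversion through the origin."""
    out = np.asarray(dc, dtype=float) * anchor.anchor_molecules / anchor.anchor_dc
    return float(out) if np.isscalar(dc) else out


def classify_positive(
    molecules: float | np.ndarray,
    threshold: float = 360.0,
) -> bool | np.ndarray:
    """Marker-positive call: strictly more than ``threshold`` molecules."""
    out = np.asarray(molecules, dtype=float) > threshold
    return bool(out) if np.isscalar(molecules) else out


def mean_of_medians(results: Sequence[CellQuantResult]) -> float:
    """Cross-replicate central tendency robust to skewed per-cell spreads."""
    if not results:
        raise ValueError("need at least one replicate")
    return float(np.mean([r.median_fg for r in results]))


def round_sig(value: float, sig: int = 2) -> float:
    """Display rounding to ``sig`` significant figures."""
    if value == 0:
        return 0.0
    from math import floor, log10
    return round(value, -int(floor(log10(abs(value)))) + (sig - 1))
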