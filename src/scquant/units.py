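"""Centralised unit conversions.

Canonical internal units are SI-leaning: flow in L/s, time in s, mass
concentration in g/L, molar concentration in mol/L, per-cell mass in grams
(reported as fg).  All user-facing entry points accept the instrument-native
units (µL/min flow, µg/L standards, fg masses) and convert through here, so
that the quantification arithmetic is unit-safe by construction.
"""

from __future__ import annotations

_FLOW_TO_L_PER_S = {
    "L/s": 1.0,
    "mL/s": 1e-3,
    "uL/s": 1e-6,
    "L/min": 1.0 / 60.0,
    "mL/min": 1e-3 / 60.0,
    "uL/min": 1e-6 / 60.0,
}

_CONC_TO_G_PER_L = {
    "g/L": 1.0,
    "mg/L": 1e-3,
    "ug/L": 1e-6,
    "ng/L": 1e-9,
    "pg/L": 1e-12,
    "g/mL": 1e3,
    "mg/mL": 1.0,
    "ug/mL": 1e-3,
    "ng/mL": 1e-6,
}

_MOLAR_TO_MOL_PER_L = {
    "mol/L": 1.0,
    "M": 1.0,
    "mmol/L": 1e-3,
    "mM": 1e-3,
    "umol/L": 1e-6,
    "uM": 1e-6,
    "nmol/L": 1e-9,
    "nM": 1e-9,
}


def _normalise(unit: str) -> str:
    return unit.replace("µ", "u").replace(" ", "")


def flow_to_l_per_s(value: float, unit: str = "uL/min") -> float:
    """Convert a volumetric flow rate to L/s."""
    key = _normalise(unit)
    try:
        return value * _FLOW_TO_L_PER_S[key]
    except KeyError:
        raise ValueError(f"unknown flow unit {unit!r}; known: {sorted(_FLOW_TO_L_PER_S)}") from None


def conc_to_g_per_l(value: float, unit: str = "ug/L") -> float:
    """Convert a mass concentration to g/L."""
    key = _normalise(unit)
    try:
        return value * _CONC_TO_G_PER_L[key]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}; known: {sorted(_CONC_TO_G_PER_L)}") from None


def conc_to_mol_per_l(value: float, unit: str, molar_mass_g_per_mol: float | None = None) -> float:
    """Convert a concentration to mol/L.

    Molar units convert directly; mass-per-volume units require
    ``molar_mass_g_per_mol``.
    """
    key = _normalise(unit)
    if key in _MOLAR_TO_MOL_PER_L:
        return value * _MOLAR_TO_MOL_PER_L[key]
    if key in _CONC_TO_G_PER_L:
        if molar_mass_g_per_mol is None or molar_mass_g_per_mol <= 0:
            raise ValueError(f"mass-based unit {unit!r} needs a positive molar mass")
        return value * _CONC_TO_G_PER_L[key] / molar_mass_g_per_mol
    raise ValueError(f"unknown concentration unit {unit!r}")


def g_to_fg(value_g: float) -> float:
    return value_g * 1e15


def fg_to_g(value_fg: float) -> float:
    return value_fg * 1e-15
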