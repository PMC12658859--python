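"""Physical constants and element reference data used across the package."""

#: Avogadro constant (2019 SI exact value), mol^-1.
AVOGADRO = 6.02214076e23

#: Grams per femtogram scale factor.
G_TO_FG = 1e15
FG_TO_G = 1e-15

#: Molar masses, g/mol (standard atomic weights; Lu is the quantification label).
MOLAR_MASS_G_PER_MOL = {
    "Lu": 174.97,
    "Ir": 192.22,
    "Fe": 55.845,
    "P": 30.974,
    "Y": 88.906,
    "In": 114.82,
    "Ce": 140.12,
    "Tb": 158.93,
    "Bi": 208.98,
    "Au": 196.97,
}

#: Natural isotopic abundance of the monitored isotope, as a fraction.
#: Lu-175 at 0.974 is the value used when calibrating with natural-Lu standards
#: against an isotopically pure 175Lu antibody label.  The remaining entries are
#: IUPAC natural abundances supplied as convenience defaults.
NATURAL_ABUNDANCE = {
    "Lu175": 0.974,
    "Ir191": 0.373,
    "Ir193": 0.627,
    "Y89": 1.0,
    "In115": 0.9571,
    "Ce140": 0.8845,
    "Tb159": 1.0,
    "Bi209": 1.0,
    "Fe56": 0.9175,
    "P31": 1.0,
}

#: Channels carried by EQ-style polystyrene calibration beads.
BEAD_CHANNELS = ("Y89", "In115", "Ce140", "Tb159", "Lu175", "Bi209")

#: Channels expected in labelled cells (Ir DNA intercalator + Lu antibody label).
CELL_CHANNELS = ("Ir191", "Ir193", "Lu175")

#: Bead metals that never appear in cells; used for bead calls since Lu is shared.
BEAD_EXCLUSIVE_CHANNELS = ("Y89", "In115", "Ce140", "Tb159", "Bi209")


def element_of(channel: str) -> str:
    """Strip the mass number from a channel label: ``'Lu175' -> 'Lu'``."""
    return channel.rstrip("0123456789").rstrip()


def fcs_channel_name(channel: str) -> str:
    """Community-style FCS short name for a metal channel: ``'Lu175' -> 'Lu175Di'``."""
    return channel if channel.endswith("Di") else channel + "Di"
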