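"""Per-residue hydrophobicity scales.

``KYTE_DOOLITTLE``: the classic hydropathy index (dimensionless; positive =
hydrophobic). ``WIMLEY_WHITE_INTERFACE``: experimental free energies of
transfer from water to the POPC bilayer interface, kcal/mol, for Ac-WL-X-LL
pentapeptides; *negative* values mean partitioning into the lipid/water
interface is favourable (Trp, Phe, Tyr are the strongest interface seekers).
Charged residues use their dominant protonation state at neutral pH; His is
the neutral form.
"""

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

WIMLEY_WHITE_INTERFACE = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}

SCALES = {
    "kd": KYTE_DOOLITTLE,
    "ww_interface": WIMLEY_WHITE_INTERFACE,
}

SCALE_UNITS = {
    "kd": "hydropathy index (positive = hydrophobic)",
    "ww_interface": "kcal/mol water->POPC interface (negative = favourable)",
}
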