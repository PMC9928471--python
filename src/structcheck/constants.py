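"""Embedded reference tables and ideal-geometry constants.

All tables are snapshot-pinned in this file so that results do not drift
with external package versions.
"""

from __future__ import annotations

#: Van der Waals radii in Angstrom.  Bondi (1964) values except oxygen,
#: which uses the reduced protein-contact radius 1.40 A (the
#: MolProbity/Probe convention): with the full Bondi 1.52 A, canonical
#: native geometry — e.g. the CB(i)..O(i+2) contact of a polyproline-I
#: helix at 2.71 A — would register as clashing.  Deuterium shares the H
#: radius.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.40,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
    "ZN": 1.39,
    "FE": 1.40,
    "MG": 1.73,
    "CA": 1.74,
    "NA": 2.27,
    "K": 2.75,
}

#: Radius used for elements absent from :data:`VDW_RADII` (carbon-like).
FALLBACK_VDW_RADIUS: float = 1.70

VDW_PROVENANCE: str = "Bondi (1964) radii; O reduced to 1.40 A (protein contact convention)"

#: Wimley-White interface scale: free energy of transfer (kcal/mol) from
#: water to the POPC bilayer interface, whole-residue values.  Negative
#: values mean favorable partitioning into the interface, i.e. hydrophobic.
#: Asp/Glu are the charged (physiological pH) values; His the neutral form.
WIMLEY_WHITE_INTERFACE: dict[str, float] = {
    "ALA": 0.17,
    "ARG": 0.81,
    "ASN": 0.42,
    "ASP": 1.23,
    "CYS": -0.24,
    "GLN": 0.58,
    "GLU": 2.02,
    "GLY": 0.01,
    "HIS": 0.17,
    "ILE": -0.31,
    "LEU": -0.56,
    "LYS": 0.99,
    "MET": -0.23,
    "PHE": -1.13,
    "PRO": 0.45,
    "SER": 0.13,
    "THR": 0.14,
    "TRP": -1.85,
    "TYR": -0.94,
    "VAL": 0.07,
}

WIMLEY_WHITE_NAME: str = "Wimley-White interface"

#: Theoretical maximum solvent-accessible surface area per residue type
#: (Angstrom^2), Tien et al. 2013, used to normalize per-residue SASA into
#: a relative exposure in [0, ~1.2].
MAX_SASA: dict[str, float] = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}

#: The twenty standard amino-acid three-letter codes.
STANDARD_AA: frozenset[str] = frozenset(WIMLEY_WHITE_INTERFACE)

#: Ideal backbone geometry (Engh-Huber-style standard values) used by the
#: synthetic peptide builder.  Lengths in Angstrom, angles in degrees.
IDEAL_GEOMETRY: dict[str, float] = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "C_O": 1.231,
    "CA_CB": 1.530,
    "N_H": 1.010,
    "CA_HA": 1.090,
    # Proline ring
    "CB_CG": 1.492,
    "CG_CD": 1.503,
    "N_CD": 1.473,
    # bond angles
    "N_CA_C": 111.2,
    "CA_C_N": 116.2,
    "C_N_CA": 121.7,
    "CA_C_O": 120.8,
    "C_CA_CB": 110.1,
    "N_CA_CB": 110.4,
    "CA_N_H": 119.0,
    "C_CA_HA": 108.0,
    "CA_N_CD": 112.0,
    "CA_CB_CG": 104.0,
    "CB_CG_CD": 105.0,
}

#: Torsion N-C-CA-CB (deg) that places CB on the L side of the backbone.
#: Calibrated once against ideal L-amino-acid geometry; guarded by a test.
CB_TORSION_L: float = 122.6

#: Viewer color per finding class (Figure-legend convention of the tool's
#: report: D-amino acids purple, cis-amide red, cis-proline green,
#: non-planar cyan, clashing atoms yellow).
FINDING_COLORS: dict[str, str] = {
    "D": "purple",
    "CIS": "red",
    "CIS_PRO": "green",
    "NON_PLANAR": "cyan",
    "CLASH": "yellow",
}
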