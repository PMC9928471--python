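"""Peptide-bond omega dihedral computation and cis/trans classification.

The omega torsion of the bond between residues i and i+1 is
CA(i)-C(i)-N(i+1)-CA(i+1): ~180 deg trans, ~0 deg cis.  Bonds near neither
value are non-planar.  Cis bonds preceding a proline are labeled
separately (cis-Pro) because they occur naturally at an appreciable rate,
unlike cis bonds to other residues.

Classification thresholds default to |omega| <= 30 deg for cis and
|omega| >= 150 deg for trans — the common cis-peptide criterion in the
validation literature; both are configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ConfigurationError, DegenerateGeometryError
from .geometry import dihedral
from .structure_io import Residue, StructureModel, peptide_bonds

DEFAULT_CIS_THRESHOLD = 30.0
DEFAULT_TRANS_THRESHOLD = 150.0


class AmideLabel(str, enum.Enum):
    TRANS = "TRANS"
    CIS = "CIS"
    CIS_PRO = "CIS_PRO"
    NON_PLANAR = "NON_PLANAR"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class AmideBond:
    """One peptide bond: the two residues, its omega angle and its class.

    Findings are attributed to the *following* residue ``res_j`` (the one
    whose N participates) in viewer output, since that is the residue whose
    conformation is unusual.
    """

    res_i: tuple[str, int, str, str]
    res_j: tuple[str, int, str, str]
    omega: float | None
    label: AmideLabel

    @property
    def id_str(self) -> str:
        ci, si, ii, ni = self.res_i
        cj, sj, ij, nj = self.res_j
        return f"{ci}:{ni}{si}{ii}-{nj}{sj}{ij}".strip()


def omega_angle(res_i: Residue, res_j: Residue) -> float:
    """Omega torsion CA(i)-C(i)-N(i+1)-CA(i+1) in degrees, (-180, 180]."""
    atoms = [res_i.get_atom("CA"), res_i.get_atom("C"),
             res_j.get_atom("N"), res_j.get_atom("CA")]
    if any(a is None for a in atoms):
        missing = [n for n, a in zip(("CA_i", "C_i", "N_j", "CA_j"), atoms) if a is None]
        raise ValueError(f"omega undefined, missing {', '.join(missing)}")
    return dihedral(*(a.position for a in atoms))


def classify_amide(omega: float, next_is_proline: bool,
                   cis_threshold: float = DEFAULT_CIS_THRESHOLD,
                   trans_threshold: float = DEFAULT_TRANS_THRESHOLD) -> AmideLabel:
    """Map an omega angle to TRANS / CIS / CIS_PRO / NON_PLANAR."""
    if not (0.0 < cis_threshold < trans_threshold <= 180.0):
        raise ConfigurationError(
            f"thresholds must satisfy 0 < cis < trans <= 180, "
            f"got cis={cis_threshold}, trans={trans_threshold}")
    # tiny tolerance so an angle sitting numerically on a threshold is
    # classified as if it were exactly there
    eps = 1e-9
    if abs(omega) <= cis_threshold + eps:
        return AmideLabel.CIS_PRO if next_is_proline else AmideLabel.CIS
    if abs(omega) >= trans_threshold - eps:
        return AmideLabel.TRANS
    return AmideLabel.NON_PLANAR


def scan_amides(model: StructureModel,
                cis_threshold: float = DEFAULT_CIS_THRESHOLD,
                trans_threshold: float = DEFAULT_TRANS_THRESHOLD,
                max_cn_distance: float = 2.0) -> list[AmideBond]:
    """Classify every peptide bond of the model, in chain order.

    Bonds across chain breaks are absent (see
    :func:`structcheck.structure_io.peptide_bonds`); bonds whose omega
    cannot be computed (missing CA, degenerate geometry) are reported
    UNDETERMINED rather than raising.
    """
    out: list[AmideBond] = []
    for res_i, res_j in peptide_bonds(model, max_cn_distance=max_cn_distance):
        try:
            omega = omega_angle(res_i, res_j)
        except (ValueError, DegenerateGeometryError):
            out.append(AmideBond(res_i.ref, res_j.ref, None, AmideLabel.UNDETERMINED))
            continue
        label = classify_amide(omega, res_j.resname == "PRO",
                               cis_threshold, trans_threshold)
        out.append(AmideBond(res_i.ref, res_j.ref, omega, label))
    return out
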