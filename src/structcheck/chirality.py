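"""L/D chirality assignment at the Calpha stereocenter.

The stereocenter is classified from heavy atoms only, so the verdict is
identical whether or not the model contains hydrogens.  The three
substituents N, C (carbonyl) and CB are taken in fixed priority order
(N > C > CB; the implicit hydrogen ranks lowest and is omitted).  They
span a triangle; the cross product of two triangle edges gives its normal,
and the dot product of that normal with the vector from the stereocenter
to the triangle centroid is a signed scalar whose sign decides L vs D.

Note on nomenclature: cysteine is CIP-(R) as an L-amino acid because the
sulfur raises the side-chain priority, but the geometric L/D verdict here
uses the same three heavy atoms for every residue type, so L-Cys is
reported L like every other L-residue.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .structure_io import Residue, StructureModel

#: Scalar sign meaning L.  Calibrated once against ideal L-amino-acid
#: geometry (positive for L with the N > C > CB priority order) and frozen;
#: a unit test guards the calibration.
L_SIGN: int = +1

#: |scalar| below this (A^3 scale) is treated as degenerate (near-planar).
PLANARITY_TOL: float = 1e-6


class Chirality(str, enum.Enum):
    L = "L"
    D = "D"
    ACHIRAL = "ACHIRAL"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class ChiralityAssignment:
    """Per-residue chirality verdict and the scalar that produced it."""

    residue_ref: tuple[str, int, str, str]
    label: Chirality
    scalar: float | None = None
    center_atom: str = "CA"
    reason: str = ""

    @property
    def id_str(self) -> str:
        chain, seq, icode, resname = self.residue_ref
        return f"{chain}:{resname}{seq}{icode}".strip()


def chirality_scalar(center, a1, a2, a3) -> float:
    """Signed orientation scalar of three prioritized substituents.

    Returns ``dot((a2 - a1) x (a3 - a1), centroid(a1, a2, a3) - center)``,
    which equals the signed volume ``det[a1 - c, a2 - c, a3 - c]``.  The
    sign flips under mirror reflection; the magnitude carries no meaning
    for classification.

    Raises
    ------
    DegenerateGeometryError
        If a1, a2, a3 are collinear.
    """
    center, a1, a2, a3 = (np.asarray(p, dtype=float) for p in (center, a1, a2, a3))
    normal = np.cross(a2 - a1, a3 - a1)
    if np.linalg.norm(normal) < 1e-10:
        raise DegenerateGeometryError("degenerate center: substituents collinear")
    centroid = (a1 + a2 + a3) / 3.0
    return float(np.dot(normal, centroid - center))


def assign_chirality(residue: Residue) -> ChiralityAssignment:
    """Assign L/D/ACHIRAL/UNDETERMINED at the Calpha of one residue.

    Glycine (no CB) is achiral.  A residue missing any of N, CA, C, CB, or
    with degenerate (near-planar) geometry, is UNDETERMINED — never an
    error.
    """
    if residue.resname == "GLY":
        return ChiralityAssignment(residue.ref, Chirality.ACHIRAL)
    atoms = {name: residue.get_atom(name) for name in ("N", "CA", "C", "CB")}
    missing = [name for name, a in atoms.items() if a is None]
    if missing:
        return ChiralityAssignment(
            residue.ref, Chirality.UNDETERMINED,
            reason=f"missing atoms: {', '.join(missing)}")
    try:
        scalar = chirality_scalar(
            atoms["CA"].position, atoms["N"].position,
            atoms["C"].position, atoms["CB"].position)
    except DegenerateGeometryError:
        return ChiralityAssignment(
            residue.ref, Chirality.UNDETERMINED, reason="degenerate geometry")
    if abs(scalar) < PLANARITY_TOL:
        return ChiralityAssignment(
            residue.ref, Chirality.UNDETERMINED, scalar=scalar,
            reason="near-planar center")
    label = Chirality.L if scalar * L_SIGN > 0 else Chirality.D
    return ChiralityAssignment(residue.ref, label, scalar=scalar)


def scan_chirality(model: StructureModel) -> list[ChiralityAssignment]:
    """One :class:`ChiralityAssignment` per polymer residue, in chain order."""
    return [assign_chirality(res) for res in model.residues()]
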