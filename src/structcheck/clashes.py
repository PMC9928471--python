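"""Van der Waals clash detection with a k-d tree neighbor search.

Two atoms clash when their distance is below the sum of their van der
Waals radii minus a tolerance (default 0.4 A, the widely used
steric-overlap cutoff).  Pairs that are covalently close are excluded:
all pairs within one residue, and inter-residue pairs separated by three
covalent bonds or fewer through the peptide bond C(i)-N(i+1) or through a
disulfide SG-SG bond.  The three-bond rule is required for zero false
positives: the canonical trans peptide itself places O(i) and CA(i+1)
(a 1-4 pair) at ~2.77 A, inside the Bondi-radius criterion.  Connectivity
comes from residue templates by atom name, not from distance-based bond
perception.  The spatial index only accelerates the search — the reported
pair set is identical to a brute-force all-pairs scan with the same rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import FALLBACK_VDW_RADIUS, VDW_PROVENANCE, VDW_RADII
from .errors import UnknownElementError
from .structure_io import StructureModel, peptide_bonds

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 0.4
DISULFIDE_SG_CUTOFF = 2.5

# Covalent-bond distance of backbone-template atoms from the carbonyl C of
# residue i, and from the amide N of residue i+1.  An inter-residue pair is
# excluded when the sum of the two counts is <= 2, i.e. the atoms are at
# most three bonds apart through the peptide bond.
_BONDS_FROM_C = {"C": 0, "CA": 1, "O": 1, "OXT": 1, "N": 2, "CB": 2,
                 "HA": 2, "HA2": 2, "HA3": 2}
_BONDS_FROM_N = {"N": 0, "CA": 1, "H": 1, "HN": 1, "H1": 1, "H2": 1, "H3": 1,
                 "C": 2, "CB": 2, "HA": 2, "HA2": 2, "HA3": 2}
# proline's CD is bonded to N; CG and the CD hydrogens are two bonds away
_BONDS_FROM_N_PRO = {**_BONDS_FROM_N, "CD": 1, "CG": 2, "HD2": 2, "HD3": 2}
# cystine bridge: distances from the SG of either partner
_BONDS_FROM_SG = {"SG": 0, "CB": 1, "CA": 2, "HB2": 2, "HB3": 2}


@dataclass
class VdwTable:
    """Element symbol -> van der Waals radius (Angstrom)."""

    radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    provenance: str = VDW_PROVENANCE
    fallback: float = FALLBACK_VDW_RADIUS

    def radius(self, element: str, strict: bool = False) -> float:
        el = element.upper()
        try:
            return self.radii[el]
        except KeyError:
            if strict:
                raise UnknownElementError(
                    f"no van der Waals radius for element {element!r}") from None
            warnings.warn(
                f"element {element!r} not in radius table "
                f"({self.provenance}); using fallback {self.fallback} A",
                stacklevel=2)
            return self.fallback


AtomRef = tuple[str, int, str, str, str]  # chain, seq_id, icode, resname, atom name


@dataclass
class ClashPair:
    """One clashing atom pair; ``atom_a`` precedes ``atom_b`` in file order."""

    atom_a: AtomRef
    atom_b: AtomRef
    distance: float
    vdw_sum: float
    overlap: float  # vdw_sum - tolerance - distance, > 0


@dataclass
class ClashReport:
    pairs: list[ClashPair]
    n_residues: int
    score: float | None = None

    @property
    def n_clashes(self) -> int:
        return len(self.pairs)


def _collect_atoms(model: StructureModel, include_hydrogens: bool):
    """Flat atom list (skipping waters and optionally hydrogens), with
    per-atom residue index and the residue list itself."""
    atoms, res_index, residues = [], [], []
    for res in model.all_residues():
        if res.resname in ("HOH", "WAT", "DOD"):
            continue
        ridx = len(residues)
        residues.append(res)
        for atom in res.atoms:
            if atom.is_hydrogen and not include_hydrogens:
                continue
            atoms.append(atom)
            res_index.append(ridx)
    return atoms, res_index, residues


def _excluded_pairs(model: StructureModel, residues, atoms, res_index):
    """Set of frozensets of atom list-indices within three covalent bonds
    of each other through a peptide or disulfide bond."""
    # atom lookup: residue idx -> {atom name: atom list index}
    by_res: dict[int, dict[str, int]] = {}
    for idx, (atom, ridx) in enumerate(zip(atoms, res_index)):
        by_res.setdefault(ridx, {})[atom.name] = idx
    res_pos = {id(res): i for i, res in enumerate(residues)}

    excluded: set[frozenset[int]] = set()

    def exclude_through_bond(ri, rj, dist_i, dist_j):
        for name_i, di in dist_i.items():
            a = by_res.get(ri, {}).get(name_i)
            if a is None:
                continue
            for name_j, dj in dist_j.items():
                if di + dj > 2:
                    continue
                b = by_res.get(rj, {}).get(name_j)
                if b is not None and a != b:
                    excluded.add(frozenset((a, b)))

    for res_i, res_j in peptide_bonds(model):
        ri = res_pos.get(id(res_i))
        rj = res_pos.get(id(res_j))
        if ri is None or rj is None:
            continue
        from_n = _BONDS_FROM_N_PRO if res_j.resname == "PRO" else _BONDS_FROM_N
        exclude_through_bond(ri, rj, _BONDS_FROM_C, from_n)

    # disulfides: SG pairs within bonding distance bridge two residues
    sg = [(i, atoms[i].position) for i in range(len(atoms))
          if atoms[i].name == "SG"]
    for k, (i, pi) in enumerate(sg):
        for j, pj in sg[k + 1:]:
            if (res_index[i] != res_index[j]
                    and np.linalg.norm(pi - pj) <= DISULFIDE_SG_CUTOFF):
                exclude_through_bond(res_index[i], res_index[j],
                                     _BONDS_FROM_SG, _BONDS_FROM_SG)
    return excluded


def find_clashes(model: StructureModel, vdw: VdwTable | None = None,
                 tolerance: float = DEFAULT_TOLERANCE,
                 include_hydrogens: bool = False,
                 strict_elements: bool = False) -> list[ClashPair]:
    """Every non-excluded atom pair with distance < r_a + r_b - tolerance.

    Hydrogens are ignored by default (models frequently lack them, and
    mixed-protonation comparisons would be inconsistent).  With
    ``strict_elements`` an element missing from the radius table raises
    :class:`UnknownElementError` instead of using the fallback radius.
    """
    if vdw is None:
        vdw = VdwTable()
    atoms, res_index, residues = _collect_atoms(model, include_hydrogens)
    if len(atoms) < 2:
        return []
    coords = np.array([a.position for a in atoms])
    radii = np.array([vdw.radius(a.element, strict=strict_elements) for a in atoms])

    excluded = _excluded_pairs(model, residues, atoms, res_index)

    tree = cKDTree(coords)
    search_r = 2.0 * float(radii.max()) - tolerance
    pairs: list[ClashPair] = []
    for i, j in tree.query_pairs(r=search_r):
        if res_index[i] == res_index[j]:
            continue
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        vdw_sum = float(radii[i] + radii[j])
        if dist >= vdw_sum - tolerance:
            continue
        if frozenset((i, j)) in excluded:
            continue
        a, b = (i, j) if i < j else (j, i)
        ra, rb = residues[res_index[a]], residues[res_index[b]]
        pairs.append(ClashPair(
            atom_a=(*ra.ref, atoms[a].name),
            atom_b=(*rb.ref, atoms[b].name),
            distance=dist, vdw_sum=vdw_sum,
            overlap=vdw_sum - tolerance - dist))
    pairs.sort(key=lambda p: (p.atom_a, p.atom_b))
    return pairs


def clash_score(n_clashes: int, n_residues: int, per: float = 100.0) -> float:
    """Length-normalized clash severity: clashes per ``per`` (100) residues.

    Only clash counts enter the score; chirality and amide findings are
    deliberately not part of it.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if n_clashes < 0:
        raise ValueError("n_clashes must be >= 0")
    return per * n_clashes / n_residues


def clash_report(model: StructureModel, vdw: VdwTable | None = None,
                 tolerance: float = DEFAULT_TOLERANCE,
                 include_hydrogens: bool = False,
                 with_score: bool = True) -> ClashReport:
    """Run clash detection on a model and bundle the result."""
    pairs = find_clashes(model, vdw=vdw, tolerance=tolerance,
                         include_hydrogens=include_hydrogens)
    n_res = model.n_residues
    score = clash_score(len(pairs), n_res) if (with_score and n_res) else None
    return ClashReport(pairs=pairs, n_residues=n_res, score=score)
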