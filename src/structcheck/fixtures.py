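"""Synthetic ideal-geometry peptides with controlled defects.

This module is the test substrate for the whole validator: it builds
peptides by sequential internal-to-Cartesian placement from standard bond
lengths and angles, with every omega torsion, every residue's handedness
(L or D) and injected steric clashes under exact caller control.  The
closure property — the validator recovers exactly the planted findings —
is what most of the test suite exercises.

Omega angles and chirality are reproduced exactly as specified.  Phi/psi
are free parameters: the requested values are used where they work, but
the builder resamples them (deterministically, from the spec seed) when a
growing chain would otherwise fold back onto itself, so that the only
steric clashes in a built model are the ones injected on purpose.

Side chains are stubbed at CB (enough for chirality and clash checks),
except proline which gets its full CB/CG/CD ring because the CD atom
participates in peptide-bond exclusion rules and cis-Pro realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clashes import (DEFAULT_TOLERANCE, VdwTable, _BONDS_FROM_C,
                      _BONDS_FROM_N, _BONDS_FROM_N_PRO)
from .constants import CB_TORSION_L, IDEAL_GEOMETRY as G, STANDARD_AA
from .errors import StructCheckError
from .geometry import place_atom
from .hydrophobicity import sphere_lattice
from .structure_io import Atom3D, Residue, StructureModel

DEFAULT_PHI = -120.0
DEFAULT_PSI = 130.0

# extra clearance (A) beyond the clash criterion during chain growth, so a
# built model is never borderline
_GROWTH_MARGIN = 0.01
# free-torsion search grids (deg) and the evaluation budget of one growth
_PSI_GRID_STEP = 2.0
_PHI_GRID_STEP = 3.0
# per-step psi candidate caps, escalated over successive growth passes,
# and the phi cap within one psi choice
_PSI_PICKS_SCHEDULE = (40 * (12,)) + (60 * (30,)) + (100 * (60,))
_PHI_PICKS = 40
# in-pass dead-end recoveries before the pass is abandoned
_MAX_BACKTRACKS = 40


@dataclass
class PeptideSpec:
    """Recipe for a synthetic peptide.

    ``omega[k]`` is the torsion of the bond between residues k and k+1
    (n-1 values, default all 180 = trans).  ``chirality`` holds "L" or "D"
    per residue (ignored for glycine).  Scalar phi/psi describe the L
    conformation and are mirrored for D residues; per-residue lists are
    used verbatim.
    """

    sequence: list[str]
    omega: list[float] | None = None
    chirality: list[str] | None = None
    phi: float | list[float] = DEFAULT_PHI
    psi: float | list[float] = DEFAULT_PSI
    include_hydrogens: bool = False
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self):
        n = len(self.sequence)
        if n == 0:
            raise StructCheckError("empty sequence")
        for code in self.sequence:
            if code not in STANDARD_AA:
                raise StructCheckError(f"unknown residue code {code!r}")
        if self.omega is None:
            self.omega = [180.0] * (n - 1)
        if len(self.omega) != n - 1:
            raise StructCheckError("omega must have n-1 entries")
        for w in self.omega:
            if not (-180.0 < w <= 180.0):
                raise StructCheckError(f"omega {w} outside (-180, 180]")
        if self.chirality is None:
            self.chirality = ["L"] * n
        if len(self.chirality) != n:
            raise StructCheckError("chirality must have n entries")
        for c in self.chirality:
            if c not in ("L", "D"):
                raise StructCheckError(f"chirality must be 'L' or 'D', got {c!r}")

    def angle_list(self, value, mirror_d: bool) -> list[float]:
        n = len(self.sequence)
        if isinstance(value, (int, float)):
            out = [float(value)] * n
            if mirror_d:
                out = [-a if c == "D" else a
                       for a, c in zip(out, self.chirality)]
            return out
        if len(value) != n:
            raise StructCheckError("phi/psi list length mismatch")
        return [float(v) for v in value]


def _sidechain(code: str, handed: float, n_pos, ca_pos, c_pos):
    """Heavy side-chain atoms (name, element, position) stubbed at CB."""
    out = []
    if code == "GLY":
        return out
    cb = place_atom(n_pos, c_pos, ca_pos, G["CA_CB"], G["C_CA_CB"],
                    handed * CB_TORSION_L)
    out.append(("CB", "C", cb))
    if code == "PRO":
        cg = place_atom(n_pos, ca_pos, cb, G["CB_CG"], G["CA_CB_CG"], 0.0)
        cd = place_atom(cb, ca_pos, n_pos, G["N_CD"], G["CA_N_CD"], 0.0)
        out.append(("CG", "C", cg))
        out.append(("CD", "C", cd))
    return out


class _GrowthState:
    """Vectorized store of committed atoms for fast clearance checks."""

    def __init__(self, sequence, vdw, margin):
        self.sequence = sequence
        self.vdw = vdw
        self.margin = margin
        self.pos = np.zeros((0, 3))
        self.rad = np.zeros(0)
        self.res = np.zeros(0, dtype=int)
        self.names: list[str] = []
        self.elements: list[str] = []
        # per-atom covalent distance from the C role (as bond residue i)
        # and from the N role (as bond residue i+1); 9 = not on a template
        self.fc = np.zeros(0, dtype=int)
        self.fn = np.zeros(0, dtype=int)

    def _roles(self, names, res_idx):
        fc = np.array([_BONDS_FROM_C.get(nm, 9) for nm in names])
        fn = np.array([(_BONDS_FROM_N_PRO if self.sequence[r] == "PRO"
                        else _BONDS_FROM_N).get(nm, 9)
                       for nm, r in zip(names, res_idx)])
        return fc, fn

    def commit(self, new_atoms, new_res_idx):
        if not new_atoms:
            return
        self.pos = np.vstack([self.pos,
                              np.array([p for _, _, p in new_atoms])])
        self.rad = np.concatenate([self.rad,
                                   [self.vdw.radius(el) for _, el, _ in new_atoms]])
        self.res = np.concatenate([self.res, new_res_idx])
        names = [name for name, _, _ in new_atoms]
        fc, fn = self._roles(names, new_res_idx)
        self.fc = np.concatenate([self.fc, fc])
        self.fn = np.concatenate([self.fn, fn])
        self.names.extend(names)
        self.elements.extend(el for _, el, _ in new_atoms)

    def snapshot(self) -> int:
        return len(self.names)

    def rollback(self, mark: int):
        self.pos = self.pos[:mark]
        self.rad = self.rad[:mark]
        self.res = self.res[:mark]
        self.fc = self.fc[:mark]
        self.fn = self.fn[:mark]
        del self.names[mark:]
        del self.elements[mark:]

    def limits(self, names, elements, res_idx) -> np.ndarray:
        """(k, m) matrix of minimum allowed distances between k new atoms
        and the m committed atoms; -1 where a pair is exempt (same residue,
        or within three covalent bonds through the peptide bond)."""
        nrad = np.array([self.vdw.radius(el) for el in elements])
        lim = nrad[:, None] + self.rad[None, :] - DEFAULT_TOLERANCE + self.margin
        nres = np.asarray(res_idx)
        fc_new, fn_new = self._roles(names, res_idx)
        same = nres[:, None] == self.res[None, :]
        # new atom is on the C side of the bond to the committed atom
        lo = ((self.res[None, :] == nres[:, None] + 1)
              & (fc_new[:, None] + self.fn[None, :] <= 2))
        # new atom is on the N side
        hi = ((self.res[None, :] == nres[:, None] - 1)
              & (self.fc[None, :] + fn_new[:, None] <= 2))
        lim[same | lo | hi] = -1.0
        return lim

    def clearance_ok(self, new_atoms, new_res_idx) -> bool:
        """True when no non-excluded pair violates the clash criterion."""
        if len(self.names) == 0:
            return True
        npos = np.array([p for _, _, p in new_atoms])
        lim = self.limits([a[0] for a in new_atoms],
                          [a[1] for a in new_atoms], new_res_idx)
        d = np.linalg.norm(npos[:, None, :] - self.pos[None, :, :], axis=2)
        return bool(np.all(d >= lim))


def _rotated(points, center, axis_unit, thetas):
    """Rodrigues rotation of ``points`` (k, 3) about the axis through
    ``center`` for every angle in ``thetas`` (radians) -> (len(thetas), k, 3)."""
    p = points - center
    c = np.cos(thetas)[:, None, None]
    s = np.sin(thetas)[:, None, None]
    u = axis_unit
    cross = np.cross(np.broadcast_to(u, p.shape), p) * -1.0  # u x p = -(p x u)
    cross = np.cross(u[None, :], p)
    dot = p @ u
    rot = p[None] * c + cross[None] * s + (u[None, None, :] * dot[None, :, None]) * (1 - c)
    return rot + center


def build_peptide(spec: PeptideSpec, vdw: VdwTable | None = None) -> StructureModel:
    """Build a :class:`StructureModel` realizing the spec exactly.

    Backbone omega torsions are reproduced to well under 0.1 degrees and
    the requested handedness at every Calpha; the result contains no
    steric clash.  D residues are built by reflecting the side-chain
    placement through the backbone plane at CA, which flips the
    stereocenter without touching the backbone.  Deterministic for a
    given spec (including its seed).
    """
    if vdw is None:
        vdw = VdwTable()
    handed = [1.0 if c == "L" else -1.0 for c in spec.chirality]
    rng = np.random.default_rng(spec.seed)
    for attempt, psi_picks in enumerate(_PSI_PICKS_SCHEDULE):
        model = _grow_chain(spec, handed, rng, vdw,
                            prefer_spec=(attempt == 0), psi_picks=psi_picks)
        if model is not None:
            return model
    raise StructCheckError(
        "chain growth failed: no clash-free conformation found for the "
        "requested omega/chirality pattern")


def _torsion_grid(step_deg: float) -> np.ndarray:
    return np.arange(-180.0 + step_deg, 180.0 + step_deg / 2, step_deg)


def _grow_chain(spec, handed, rng, vdw, prefer_spec: bool, psi_picks: int):
    """One stochastic growth pass; returns None when it dead-ends.

    Each step screens the whole psi grid in a single vectorized pass (the
    O(i)/N(i+1)/CA(i+1) unit rotates rigidly about the CA(i)-C(i) axis),
    then draws among the clash-free candidates with a bias toward
    conformations that grow away from the already-placed atoms.  The
    requested phi/psi are used whenever they are feasible on the first
    pass, so defaults build exactly the requested conformation.  Omega
    angles and side-chain handedness are never searched.
    """
    n = len(spec.sequence)
    phi = spec.angle_list(spec.phi, mirror_d=isinstance(spec.phi, (int, float)))
    psi = spec.angle_list(spec.psi, mirror_d=isinstance(spec.psi, (int, float)))
    # around a cis bond the extended default digs into the chain; prefer a
    # polyproline-I-like turn there (phi -81, psi 155; mirrored for D)
    # unless the caller asked for specific angles
    if isinstance(spec.psi, (int, float)) and float(spec.psi) == DEFAULT_PSI:
        for i in range(n - 1):
            if abs(spec.omega[i]) <= 30.0:
                psi[i] = 155.0 * handed[i]
    if isinstance(spec.phi, (int, float)) and float(spec.phi) == DEFAULT_PHI:
        for i in range(1, n):
            if abs(spec.omega[i - 1]) <= 30.0:
                phi[i] = -81.0 * handed[i]
    state = _GrowthState(spec.sequence, vdw, _GROWTH_MARGIN)
    backbone: list[dict] = []

    # residue 0 backbone (its O depends on psi[0], so it is placed later)
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([G["N_CA"], 0.0, 0.0])
    theta = np.radians(G["N_CA_C"])
    c0 = ca0 + G["CA_C"] * np.array([-np.cos(theta), np.sin(theta), 0.0])
    backbone.append({"N": n0, "CA": ca0, "C": c0})
    first = ([("N", "N", n0), ("CA", "C", ca0), ("C", "C", c0)]
             + _sidechain(spec.sequence[0], handed[0], n0, ca0, c0))
    state.commit(first, [0] * len(first))

    def feasible_psis(i, names, elements, res_idx):
        """(psi value, unit coordinates) for every clash-free grid psi,
        the spec-preferred value (when feasible) listed first."""
        bb = backbone[i]
        base = {"O": place_atom(bb["N"], bb["CA"], bb["C"],
                                G["C_O"], G["CA_C_O"], -180.0)}
        if "N" in names:
            n_b = place_atom(bb["N"], bb["CA"], bb["C"],
                             G["C_N"], G["CA_C_N"], 0.0)
            base["N"] = n_b
            base["CA"] = place_atom(bb["CA"], bb["C"], n_b,
                                    G["N_CA"], G["C_N_CA"], spec.omega[i])
        pts = np.array([base[nm] for nm in names])
        axis = bb["C"] - bb["CA"]
        axis = axis / np.linalg.norm(axis)
        # calibrate rotation sign against the torsion convention once
        probe = place_atom(bb["N"], bb["CA"], bb["C"],
                           G["C_O"], G["CA_C_O"], -140.0)
        plus = _rotated(base["O"][None, :], bb["C"], axis,
                        np.array([np.radians(40.0)]))[0, 0]
        sign = 1.0 if np.linalg.norm(plus - probe) < 1e-6 else -1.0

        psis = np.concatenate([[psi[i]], _torsion_grid(_PSI_GRID_STEP)])
        coords = _rotated(pts, bb["C"], axis, sign * np.radians(psis))
        lim = state.limits(names, elements, res_idx)
        d = np.linalg.norm(coords[:, :, None, :] - state.pos[None, None, :, :],
                           axis=3)
        ok = np.all(d >= lim[None, :, :], axis=(1, 2))
        return psis, coords, ok

    def pick_order(psis, coords, ok, prefer_first):
        """Indices of feasible candidates in visit order: the preferred
        value first when wanted, then a random draw biased outward."""
        idx = np.nonzero(ok)[0]
        rest = idx[idx != 0]
        if len(rest) > 1:
            centroid = state.pos.mean(axis=0)
            away = np.linalg.norm(coords[rest, -1, :] - centroid, axis=1)
            # sample without replacement, weighted by distance
            w = (away - away.min() + 0.5) ** 2
            rest = rng.choice(rest, size=len(rest), replace=False,
                              p=w / w.sum())
        order = list(rest)
        if ok[0] and prefer_first:
            order.insert(0, 0)
        elif ok[0]:
            order.append(0)
        return order

    step_marks = [0] * max(n - 1, 1)
    backtracks = 0
    i = 0
    while i < n - 1:
        step_marks[i] = state.snapshot()
        names = ["O", "N", "CA"]
        elements = ["O", "N", "C"]
        res_idx = [i, i + 1, i + 1]
        psis, coords, ok = feasible_psis(i, names, elements, res_idx)
        placed = False
        next_code = spec.sequence[i + 1]
        phi_names = ["C"] + (["CB", "CG", "CD"] if next_code == "PRO"
                             else [] if next_code == "GLY" else ["CB"])
        phi_elements = ["C"] * len(phi_names)
        for k in pick_order(psis, coords, ok, prefer_spec)[:psi_picks]:
            o_i, n_next, ca_next = coords[k]
            mark = state.snapshot()
            state.commit([("O", "O", o_i), ("N", "N", n_next),
                          ("CA", "C", ca_next)], res_idx)
            # the phi-stage atom names are fixed, so the pair-limit matrix
            # can be computed once per psi choice and reused
            phi_lim = state.limits(phi_names, phi_elements,
                                   [i + 1] * len(phi_names))
            phis = np.concatenate([[phi[i + 1]], _torsion_grid(_PHI_GRID_STEP)])
            order = list(range(1, len(phis)))
            rng.shuffle(order)
            if prefer_spec:
                order.insert(0, 0)
            else:
                order.append(0)
            for j in order[:_PHI_PICKS]:
                c_next = place_atom(backbone[i]["C"], n_next, ca_next,
                                    G["CA_C"], G["N_CA_C"], phis[j])
                phi_atoms = [("C", "C", c_next)]
                for entry in _sidechain(next_code, handed[i + 1],
                                        n_next, ca_next, c_next):
                    phi_atoms.append(entry)
                npos = np.array([p for _, _, p in phi_atoms])
                d = np.linalg.norm(npos[:, None, :] - state.pos[None, :, :],
                                   axis=2)
                if np.all(d >= phi_lim):
                    state.commit(phi_atoms, [i + 1] * len(phi_atoms))
                    backbone.append({"N": n_next, "CA": ca_next, "C": c_next})
                    psi[i], phi[i + 1] = float(psis[k]), float(phis[j])
                    placed = True
                    break
            if placed:
                break
            state.rollback(mark)
        if placed:
            i += 1
            continue
        # dead end: unwind a few residues and re-place them with fresh
        # draws, rather than abandoning the whole pass
        if i == 0 or backtracks >= _MAX_BACKTRACKS:
            return None
        backtracks += 1
        unwind = min(3, i)
        for _ in range(unwind):
            backbone.pop()
        i -= unwind
        state.rollback(step_marks[i])

    # carbonyl O of the last residue
    psis, coords, ok = feasible_psis(n - 1, ["O"], ["O"], [n - 1])
    order = pick_order(psis, coords, ok, prefer_spec)
    if not order:
        return None
    k = order[0]
    state.commit([("O", "O", coords[k][0])], [n - 1])
    psi[n - 1] = float(psis[k])

    # assemble residues in atom order N, CA, C, O, side chain
    order_key = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4, "CG": 5, "CD": 6}
    residues: list[Residue] = []
    for k, code in enumerate(spec.sequence):
        res = Residue(resname=code, seq_id=k + 1, icode="",
                      chain_id=spec.chain_id)
        entries = [(state.names[j], state.elements[j], state.pos[j])
                   for j in range(len(state.names)) if state.res[j] == k]
        for name, el, pos in sorted(entries, key=lambda a: order_key.get(a[0], 9)):
            res.atoms.append(Atom3D(name=name, element=el,
                                    position=np.asarray(pos, float).copy()))
        residues.append(res)

    if spec.include_hydrogens:
        _add_hydrogens(residues, backbone, handed)

    return StructureModel(chains=[(spec.chain_id, residues)],
                          source_path="<synthetic>")



def _add_hydrogens(residues, backbone, handed):
    """Alpha and amide hydrogens.  Hydrogens never affect the default
    clash check, so they are placed without collision search."""
    for i, res in enumerate(residues):
        bb = backbone[i]
        if res.resname == "GLY":
            for suffix, sign in (("HA2", 1.0), ("HA3", -1.0)):
                pos = place_atom(bb["N"], bb["C"], bb["CA"],
                                 G["CA_HA"], G["C_CA_HA"], sign * CB_TORSION_L)
                res.atoms.append(Atom3D(name=suffix, element="H",
                                        position=pos, is_hydrogen=True))
        else:
            pos = place_atom(bb["N"], bb["C"], bb["CA"], G["CA_HA"],
                             G["C_CA_HA"], -handed[i] * CB_TORSION_L)
            res.atoms.append(Atom3D(name="HA", element="H",
                                    position=pos, is_hydrogen=True))
        if i > 0 and res.resname != "PRO":
            prev_bb = backbone[i - 1]
            o_prev = residues[i - 1].get_atom("O").position
            # amide H anti to the carbonyl O across the peptide plane
            pos = place_atom(o_prev, prev_bb["C"], bb["N"],
                             G["N_H"], 119.0, 180.0)
            res.atoms.append(Atom3D(name="H", element="H",
                                    position=pos, is_hydrogen=True))


def mirror_model(model: StructureModel) -> StructureModel:
    """Mirror image: x-coordinate negated on every atom.

    Swaps every L and D stereocenter, negates every torsion, preserves all
    interatomic distances (hence the clash set).  An involution.
    """
    out = model.copy()
    for atom in out.atoms():
        atom.position = atom.position * np.array([-1.0, 1.0, 1.0])
    return out


def inject_clash(model: StructureModel,
                 target_residue: tuple[str, int] | tuple[str, int, str],
                 distance: float,
                 vdw: VdwTable | None = None,
                 tolerance: float = DEFAULT_TOLERANCE,
                 seed: int = 0) -> StructureModel:
    """Add a pseudo side-chain carbon ("CX") to ``target_residue`` placed
    at exactly ``distance`` from an atom of a sequence-distant residue,
    without creating any other close contact.

    If ``distance`` is below the clash criterion for the chosen pair the
    clash count increases by exactly one; above it, by zero.  The
    placement search is deterministic for a given seed.

    Raises
    ------
    StructCheckError
        If no partner/direction admits the placement, or the target is
        missing.
    """
    if distance <= 0:
        raise StructCheckError("distance must be positive")
    if vdw is None:
        vdw = VdwTable()
    out = model.copy()
    chain_id, seq_id = target_residue[0], target_residue[1]
    icode = target_residue[2] if len(target_residue) > 2 else ""
    target = out.get_residue(chain_id, seq_id, icode)
    if target is None or not target.is_polymer:
        raise StructCheckError(f"target residue {target_residue} not found")

    polymer = list(out.residues())
    t_idx = polymer.index(target)
    # candidate partners ordered by decreasing sequence separation;
    # carbonyl O first (it has a single bonded neighbor, so a sphere of
    # clear directions always exists around it)
    candidates = sorted((r for k, r in enumerate(polymer) if abs(k - t_idx) >= 2),
                        key=lambda r: -abs(polymer.index(r) - t_idx))
    if not candidates:
        raise StructCheckError("model too short to inject a clash")

    r_new = vdw.radius("C")
    rng = np.random.default_rng(seed)
    directions = sphere_lattice(192)[rng.permutation(192)]

    for partner in candidates:
        for atom_name in ("O", "CB", "CA"):
            partner_atom = partner.get_atom(atom_name)
            if partner_atom is None:
                continue
            others = []
            for res in out.all_residues():
                if res is target:
                    continue  # same-residue pairs are excluded downstream
                for atom in res.atoms:
                    if atom is partner_atom or atom.is_hydrogen:
                        continue
                    others.append((atom.position, vdw.radius(atom.element)))
            for direction in directions:
                pos = partner_atom.position + distance * direction
                if all(np.linalg.norm(pos - opos) >= r_new + orad - tolerance + 1e-6
                       for opos, orad in others):
                    target.atoms.append(Atom3D(name="CX", element="C",
                                               position=pos))
                    return out
    raise StructCheckError(
        "placement search exhausted: cannot inject a single clean clash")
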