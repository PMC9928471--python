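"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from structcheck.fixtures import PeptideSpec, build_peptide

#: One of each standard amino acid, fixed order (glycine included).
AA20 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"]


@pytest.fixture(scope="session")
def ala5():
    """Clean all-trans, all-L penta-alanine."""
    return build_peptide(PeptideSpec(sequence=["ALA"] * 5))


@pytest.fixture(scope="session")
def mixed20():
    """All 20 standard residues, all-trans, all-L, with hydrogens."""
    return build_peptide(PeptideSpec(sequence=list(AA20),
                                     include_hydrogens=True))


@pytest.fixture(scope="session")
def defect_model():
    """A model with one planted D residue, one cis bond, one cis-Pro and
    one non-planar bond (no clash)."""
    spec = PeptideSpec(
        sequence=["ALA", "SER", "ALA", "PRO", "GLY", "LEU", "ALA", "VAL"],
        omega=[180.0, 5.0, 0.0, 180.0, 90.0, 180.0, 180.0],
        chirality=["L", "L", "L", "L", "L", "D", "L", "L"])
    return build_peptide(spec)


# ---------------------------------------------------------------- oracles

def signed_volume(center, a1, a2, a3) -> float:
    """Independent chirality oracle: det[a1-c, a2-c, a3-c]."""
    return float(np.linalg.det(np.stack([
        np.asarray(a1, float) - center,
        np.asarray(a2, float) - center,
        np.asarray(a3, float) - center])))


def quaternion_superpose(mobile: np.ndarray, ref: np.ndarray) -> float:
    """Independent RMSD oracle: Horn's closed-form quaternion method."""
    mob = mobile - mobile.mean(axis=0)
    r = ref - ref.mean(axis=0)
    m = mob.T @ r
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = float((mob ** 2).sum() + (r ** 2).sum())
    sq = max(0.0, (e0 - 2.0 * lam) / len(mob))
    return float(np.sqrt(sq))


def _bond_graph(model, max_cn=2.0, ss_cutoff=2.5):
    """Covalent bond list reconstructed independently from templates."""
    template = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT"),
                ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N"),
                ("N", "H"), ("CA", "HA"), ("CA", "HA2"), ("CA", "HA3"),
                ("CB", "SG")]
    atoms = []
    index = {}
    for res in model.all_residues():
        if res.resname in ("HOH", "WAT", "DOD"):
            continue
        for atom in res.atoms:
            index[(id(res), atom.name)] = len(atoms)
            atoms.append((res, atom))
    edges = set()
    for res in model.all_residues():
        for a, b in template:
            i = index.get((id(res), a))
            j = index.get((id(res), b))
            if i is not None and j is not None:
                edges.add((i, j))
    # peptide bonds
    for _, residues in model.chains:
        polymer = [r for r in residues if r.is_polymer]
        for r1, r2 in zip(polymer, polymer[1:]):
            c = r1.get_atom("C")
            n = r2.get_atom("N")
            if c is None or n is None:
                continue
            if np.linalg.norm(c.position - n.position) <= max_cn:
                edges.add((index[(id(r1), "C")], index[(id(r2), "N")]))
    # disulfides
    sgs = [i for i, (_, a) in enumerate(atoms) if a.name == "SG"]
    for x, i in enumerate(sgs):
        for j in sgs[x + 1:]:
            d = np.linalg.norm(atoms[i][1].position - atoms[j][1].position)
            if d <= ss_cutoff:
                edges.add((i, j))
    adj = {i: set() for i in range(len(atoms))}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    return atoms, adj


def brute_force_clashes(model, vdw, tolerance=0.4, include_hydrogens=False):
    """Independent clash oracle: exhaustive double loop with exclusions
    derived from a reconstructed bond graph (graph distance <= 3) and the
    same-residue rule."""
    atoms, adj = _bond_graph(model)
    keep = [k for k, (_, a) in enumerate(atoms)
            if include_hydrogens or not a.is_hydrogen]
    # graph distances up to 3 bonds (BFS from every atom, depth 3)
    near = {}
    for i in range(len(atoms)):
        seen = {i: 0}
        frontier = [i]
        for depth in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        near[i] = set(seen)
    pairs = set()
    for x, i in enumerate(keep):
        res_i, atom_i = atoms[i]
        ri = vdw.radius(atom_i.element)
        for j in keep[x + 1:]:
            res_j, atom_j = atoms[j]
            if res_i is res_j:
                continue
            if j in near[i]:
                continue
            d = float(np.linalg.norm(atom_i.position - atom_j.position))
            if d < ri + vdw.radius(atom_j.element) - tolerance:
                a = (*res_i.ref, atom_i.name)
                b = (*res_j.ref, atom_j.name)
                pairs.add(tuple(sorted((a, b))))
    return pairs
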