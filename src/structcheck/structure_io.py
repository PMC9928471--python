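"""Structure model container and PDB/mmCIF input/output.

The in-memory hierarchy is deliberately small: a :class:`StructureModel`
holds ordered chains of :class:`Residue` objects, each holding
:class:`Atom3D` records.  File order (author order) is preserved exactly;
residue identity is the author numbering ``(chain_id, seq_id, icode)``.

PDB reading and writing are implemented directly against the wwPDB v3.3
fixed-column format; mmCIF files are read through :mod:`gemmi`.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyModelError, StructureParseError
from .constants import STANDARD_AA

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD"}

# Backbone atom names required for a HETATM residue to count as polymer
# (covers modified amino acids inserted in a chain).
_BACKBONE = ("N", "CA", "C")


@dataclass
class Atom3D:
    """A single atom site."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    is_hydrogen: bool = False
    serial: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    def copy(self) -> "Atom3D":
        return replace(self, position=self.position.copy())


@dataclass
class Residue:
    """One residue: author identity plus its atoms in file order."""

    resname: str
    seq_id: int
    icode: str
    chain_id: str
    atoms: list[Atom3D] = field(default_factory=list)
    is_polymer: bool = True

    @property
    def ref(self) -> tuple[str, int, str, str]:
        """(chain_id, seq_id, icode, resname) — the author-facing identity."""
        return (self.chain_id, self.seq_id, self.icode, self.resname)

    @property
    def id_str(self) -> str:
        return f"{self.chain_id}:{self.resname}{self.seq_id}{self.icode}".strip()

    def get_atom(self, name: str) -> Atom3D | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, *names: str) -> bool:
        return all(self.get_atom(n) is not None for n in names)

    def copy(self) -> "Residue":
        return replace(self, atoms=[a.copy() for a in self.atoms])


@dataclass
class StructureModel:
    """Ordered chains of residues, as read from a structure file."""

    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    source_path: str = "<memory>"

    @property
    def n_residues(self) -> int:
        """Number of polymer residues."""
        return sum(1 for _ in self.residues())

    def residues(self):
        """Iterate polymer residues in chain / file order."""
        for _, residues in self.chains:
            for res in residues:
                if res.is_polymer:
                    yield res

    def all_residues(self):
        for _, residues in self.chains:
            yield from residues

    def atoms(self):
        for res in self.all_residues():
            yield from res.atoms

    def copy(self) -> "StructureModel":
        return StructureModel(
            chains=[(cid, [r.copy() for r in residues]) for cid, residues in self.chains],
            source_path=self.source_path,
        )

    def get_residue(self, chain_id: str, seq_id: int, icode: str = "") -> Residue | None:
        for cid, residues in self.chains:
            if cid != chain_id:
                continue
            for res in residues:
                if res.seq_id == seq_id and res.icode == icode:
                    return res
        return None


def _guess_element(name: str) -> str:
    """Element from a PDB atom name when columns 77-78 are blank."""
    stripped = name.strip()
    if stripped[:1].isdigit():  # e.g. "1HB2"
        stripped = stripped.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] in "HD" and len(name) == 4 and name[0] != " ":
        return "H"
    return stripped[0].upper()


def _parse_pdb_lines(lines, model_number: int | None, source: str) -> StructureModel:
    chains: list[tuple[str, list[Residue]]] = []
    chain_index: dict[str, int] = {}
    current_res: Residue | None = None
    in_wanted_model = True
    seen_models: list[int] = []

    for lineno, raw in enumerate(lines, start=1):
        record = raw[:6]
        if record == "MODEL ":
            try:
                num = int(raw[10:14])
            except ValueError:
                num = len(seen_models) + 1
            seen_models.append(num)
            if model_number is None:
                in_wanted_model = len(seen_models) == 1
            else:
                in_wanted_model = num == model_number
            continue
        if record == "ENDMDL":
            continue
        if record not in ("ATOM  ", "HETATM"):
            continue
        if not in_wanted_model:
            continue
        try:
            name = raw[12:16].strip()
            altloc = raw[16].strip()
            resname = raw[17:20].strip()
            chain_id = raw[21].strip()
            seq_id = int(raw[22:26])
            icode = raw[26].strip()
            x = float(raw[30:38])
            y = float(raw[38:46])
            z = float(raw[46:54])
            occ_field = raw[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
        except (ValueError, IndexError) as exc:
            raise StructureParseError(
                f"{source}: malformed {record.strip()} record at line {lineno}: {exc}"
            ) from exc
        element = raw[76:78].strip().upper() if len(raw) >= 78 else ""
        if not element:
            element = _guess_element(raw[12:16])
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            raise StructureParseError(
                f"{source}: non-finite coordinates at line {lineno}")
        atom = Atom3D(
            name=name,
            element=element,
            position=np.array([x, y, z]),
            occupancy=occupancy,
            altloc=altloc,
            is_hydrogen=element in ("H", "D"),
            serial=lineno,
        )
        if chain_id not in chain_index:
            chain_index[chain_id] = len(chains)
            chains.append((chain_id, []))
        residues = chains[chain_index[chain_id]][1]
        if (current_res is None or current_res.chain_id != chain_id
                or current_res.seq_id != seq_id or current_res.icode != icode
                or current_res.resname != resname):
            current_res = Residue(
                resname=resname, seq_id=seq_id, icode=icode, chain_id=chain_id,
                is_polymer=(record == "ATOM  "),
            )
            residues.append(current_res)
        current_res.atoms.append(atom)

    model = StructureModel(chains=chains, source_path=source)
    _promote_polymer_hetatms(model)
    return model


def _promote_polymer_hetatms(model: StructureModel) -> None:
    """Modified amino acids recorded as HETATM inside a chain are polymer."""
    for _, residues in model.chains:
        for res in residues:
            if (not res.is_polymer and res.resname not in _WATER_NAMES
                    and res.has_atoms(*_BACKBONE)):
                res.is_polymer = True


def _parse_mmcif(path: str, model_number: int | None) -> StructureModel:
    import gemmi

    st = gemmi.read_structure(path)
    st.setup_entities()
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    if model_number is None:
        gm = st[0]
    else:
        try:
            gm = st[str(model_number)]
        except (KeyError, TypeError):
            gm = st[model_number - 1]
    chains: list[tuple[str, list[Residue]]] = []
    for gchain in gm:
        residues: list[Residue] = []
        for gres in gchain:
            is_poly = gres.entity_type == gemmi.EntityType.Polymer
            res = Residue(
                resname=gres.name,
                seq_id=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                chain_id=gchain.name,
                is_polymer=is_poly,
            )
            for ga in gres:
                el = ga.element.name.upper()
                res.atoms.append(Atom3D(
                    name=ga.name,
                    element=el,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    altloc=(ga.altloc or "").strip(),
                    is_hydrogen=el in ("H", "D"),
                    serial=ga.serial,
                ))
            residues.append(res)
        chains.append((gchain.name, residues))
    model = StructureModel(chains=chains, source_path=path)
    _promote_polymer_hetatms(model)
    return model


def parse_structure(path: str, format: str = "auto",
                    model_number: int | None = None) -> StructureModel:
    """Read a structure model from a PDB or mmCIF file.

    Parameters
    ----------
    path : str
        File to read.
    format : {"auto", "pdb", "mmcif"}
        "auto" decides from the extension (.cif/.mmcif -> mmCIF, else PDB).
    model_number : int, optional
        Model to use in a multi-MODEL file; default the first.

    Raises
    ------
    StructureParseError
        On unreadable or malformed input.
    EmptyModelError
        If the file contains no polymer residues.
    """
    if format == "auto":
        ext = os.path.splitext(path)[1].lower()
        format = "mmcif" if ext in (".cif", ".mmcif") else "pdb"
    if format == "mmcif":
        model = _parse_mmcif(path, model_number)
    elif format == "pdb":
        try:
            with open(path) as fh:
                lines = fh.readlines()
        except OSError as exc:
            raise StructureParseError(f"cannot read {path}: {exc}") from exc
        model = _parse_pdb_lines(lines, model_number, source=path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if model.n_residues == 0:
        raise EmptyModelError(f"{path}: empty model (no polymer residues)")
    return model


def write_pdb(model: StructureModel, path: str) -> None:
    """Write the model as a PDB file (fixed columns, 3-decimal coordinates)."""
    serial = 0
    with open(path, "w") as fh:
        for chain_id, residues in model.chains:
            for res in residues:
                record = "ATOM  " if res.is_polymer else "HETATM"
                for atom in res.atoms:
                    serial += 1
                    name = atom.name
                    # standard alignment: 1-3 char names start in column 14
                    name_field = f" {name:<3s}" if len(name) < 4 else name
                    x, y, z = atom.position
                    fh.write(
                        f"{record}{serial:5d} {name_field}{atom.altloc or ' '}"
                        f"{res.resname:>3s} {chain_id or 'A'}{res.seq_id:4d}"
                        f"{res.icode or ' '}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}\n")
            fh.write("TER\n")
        fh.write("END\n")


def resolve_altlocs(model: StructureModel,
                    policy: str = "highest_occupancy") -> StructureModel:
    """Collapse alternate locations to one atom per name per residue.

    ``highest_occupancy`` keeps the highest-occupancy location, ties broken
    by the alphabetically first altloc identifier; ``first`` keeps the first
    location in file order.  Idempotent; a model without altlocs is returned
    as an (equal-valued) copy.
    """
    if policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    out = model.copy()
    for res in out.all_residues():
        by_name: dict[str, Atom3D] = {}
        order: list[str] = []
        for atom in res.atoms:
            if atom.name not in by_name:
                by_name[atom.name] = atom
                order.append(atom.name)
            elif policy == "highest_occupancy":
                kept = by_name[atom.name]
                if (atom.occupancy, _altloc_key(atom)) > (kept.occupancy, _altloc_key(kept)):
                    by_name[atom.name] = atom
        new_atoms = []
        for name in order:
            atom = by_name[name]
            atom.altloc = ""
            new_atoms.append(atom)
        res.atoms = new_atoms
    return out


def _altloc_key(atom: Atom3D):
    # higher sort key wins; invert the alphabet so that 'A' beats 'B' on ties
    return tuple(-ord(ch) for ch in (atom.altloc or "~"))


def peptide_bonds(model: StructureModel,
                  max_cn_distance: float = 2.0) -> list[tuple[Residue, Residue]]:
    """Consecutive residue pairs joined by a peptide bond.

    A pair (i, i+1) within a chain is a bond when the C(i)-N(i+1) distance
    is at most ``max_cn_distance`` (default 2.0 A; the ideal bond is
    1.33 A).  Pairs across a chain break, and pairs where either backbone
    atom is missing, are excluded (the latter logged as incomplete).
    """
    bonds: list[tuple[Residue, Residue]] = []
    for _, residues in model.chains:
        polymer = [r for r in residues if r.is_polymer]
        for res_i, res_j in zip(polymer, polymer[1:]):
            c = res_i.get_atom("C")
            n = res_j.get_atom("N")
            if c is None or n is None:
                logger.info("incomplete backbone between %s and %s",
                            res_i.id_str, res_j.id_str)
                continue
            if np.linalg.norm(c.position - n.position) <= max_cn_distance:
                bonds.append((res_i, res_j))
    return bonds
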