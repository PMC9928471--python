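"""Solvent-accessible surface area and surface hydrophobicity mapping.

SASA is computed with a native Shrake-Rupley engine: each atom's sphere
(van der Waals radius + probe radius, probe 1.4 A by default) is sampled
on a deterministic golden-spiral lattice, and a sample point counts as
accessible when it lies outside every neighboring atom's expanded sphere.
Per-residue SASA is the sum over the residue's atoms, normalized by a
per-residue-type theoretical maximum to a relative exposure; residues
above a relative-exposure threshold (default 0.2) form the surface.

Hydrophobicity uses the Wimley-White interface scale (water -> bilayer
interface transfer free energies, kcal/mol): negative values are
hydrophobic (yellow in the conventional surface coloring), positive
hydrophilic (blue).  The model-level summary is the SASA-weighted mean
scale value over surface residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .clashes import VdwTable
from .constants import MAX_SASA, WIMLEY_WHITE_INTERFACE, WIMLEY_WHITE_NAME
from .errors import ConfigurationError, StructCheckError
from .structure_io import Residue, StructureModel

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_SURFACE_THRESHOLD = 0.2


@dataclass
class HydrophobicityScale:
    """Residue code -> transfer free energy (kcal/mol)."""

    values: dict[str, float] = field(
        default_factory=lambda: dict(WIMLEY_WHITE_INTERFACE))
    name: str = WIMLEY_WHITE_NAME

    def value(self, resname: str) -> float:
        try:
            return self.values[resname]
        except KeyError:
            raise StructCheckError(
                f"hydrophobicity scale {self.name!r} has no value for "
                f"residue {resname!r}") from None


def sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic unit-sphere lattice (golden spiral), shape (n, 3)."""
    if n_points < 10:
        raise ConfigurationError("n_points must be >= 10")
    k = np.arange(n_points, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(model: StructureModel, vdw: VdwTable | None = None,
                       probe_radius: float = DEFAULT_PROBE_RADIUS,
                       n_points: int = DEFAULT_N_POINTS,
                       include_hydrogens: bool = False):
    """Per-atom solvent-accessible surface areas.

    Returns ``(areas, atoms, residue_of)`` where ``areas[i]`` (A^2) belongs
    to ``atoms[i]`` and ``residue_of[i]`` is its :class:`Residue`.  Waters
    are skipped; hydrogens too unless requested.
    """
    if vdw is None:
        vdw = VdwTable()
    lattice = sphere_lattice(n_points)
    atoms, residue_of = [], []
    for res in model.all_residues():
        if res.resname in ("HOH", "WAT", "DOD"):
            continue
        for atom in res.atoms:
            if atom.is_hydrogen and not include_hydrogens:
                continue
            atoms.append(atom)
            residue_of.append(res)
    if not atoms:
        return np.zeros(0), atoms, residue_of
    coords = np.array([a.position for a in atoms])
    radii = np.array([vdw.radius(a.element) + probe_radius for a in atoms])
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * lattice
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        if neighbors:
            nb_coords = coords[neighbors]
            nb_radii = radii[neighbors]
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 >= (nb_radii ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas, atoms, residue_of


def residue_sasa(model: StructureModel, **kwargs) -> dict[int, float]:
    """Map ``id(residue)`` -> residue SASA (sum over its atoms)."""
    areas, _, residue_of = shrake_rupley_sasa(model, **kwargs)
    out: dict[int, float] = {}
    for area, res in zip(areas, residue_of):
        out[id(res)] = out.get(id(res), 0.0) + float(area)
    return out


@dataclass
class ResidueHydrophobicity:
    residue_ref: tuple[str, int, str, str]
    sasa: float
    relative_sasa: float
    scale_value: float
    is_surface: bool


@dataclass
class SurfaceHydrophobicity:
    """Per-residue exposure and hydrophobicity, with the surface summary."""

    records: list[ResidueHydrophobicity]
    scale_name: str
    probe_radius: float
    n_sphere_points: int
    surface_threshold: float

    @property
    def surface_mean(self) -> float:
        """SASA-weighted mean scale value over surface residues (kcal/mol)."""
        surf = [r for r in self.records if r.is_surface]
        total = sum(r.sasa for r in surf)
        if total == 0.0:
            return float("nan")
        return sum(r.sasa * r.scale_value for r in surf) / total

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chain,seq_id,icode,resname,sasa,relative_sasa,"
                     "scale_value,is_surface\n")
            for r in self.records:
                chain, seq, icode, resname = r.residue_ref
                fh.write(f"{chain},{seq},{icode},{resname},{r.sasa:.3f},"
                         f"{r.relative_sasa:.4f},{r.scale_value:.2f},"
                         f"{int(r.is_surface)}\n")


def surface_hydrophobicity(model: StructureModel,
                           scale: HydrophobicityScale | None = None,
                           surface_threshold: float = DEFAULT_SURFACE_THRESHOLD,
                           probe_radius: float = DEFAULT_PROBE_RADIUS,
                           n_points: int = DEFAULT_N_POINTS,
                           vdw: VdwTable | None = None) -> SurfaceHydrophobicity:
    """Assign exposure and hydrophobicity to every standard polymer residue.

    Non-standard residues (no scale value) are skipped with a warning.
    Deterministic for fixed (probe_radius, n_points, surface_threshold).
    """
    if scale is None:
        scale = HydrophobicityScale()
    per_res = residue_sasa(model, vdw=vdw, probe_radius=probe_radius,
                           n_points=n_points)
    records: list[ResidueHydrophobicity] = []
    for res in model.residues():
        if res.resname not in scale.values:
            warnings.warn(f"residue {res.id_str} has no value on scale "
                          f"{scale.name!r}; skipped", stacklevel=2)
            continue
        sasa = per_res.get(id(res), 0.0)
        max_sasa = MAX_SASA.get(res.resname)
        rel = sasa / max_sasa if max_sasa else 0.0
        records.append(ResidueHydrophobicity(
            residue_ref=res.ref, sasa=sasa, relative_sasa=rel,
            scale_value=scale.value(res.resname),
            is_surface=rel >= surface_threshold))
    return SurfaceHydrophobicity(
        records=records, scale_name=scale.name, probe_radius=probe_radius,
        n_sphere_points=n_points, surface_threshold=surface_threshold)


def hydrophobicity_viewer_script(result: SurfaceHydrophobicity,
                                 structure_path: str) -> str:
    """PyMOL script coloring surface residues on a blue -> yellow gradient.

    Yellow marks hydrophobic surface (negative transfer free energy), blue
    hydrophilic, following the conventional surface-hydrophobicity coloring.
    """
    lines = [f"load {structure_path}", "hide everything", "show surface",
             "color grey80"]
    surf = [r for r in result.records if r.is_surface]
    if surf:
        vals = [r.scale_value for r in surf]
        lo, hi = min(vals), max(vals)
        span = (hi - lo) or 1.0
        for r in surf:
            chain, seq, icode, _ = r.residue_ref
            # hydrophobic (low value) -> yellow, hydrophilic (high) -> blue
            t = (r.scale_value - lo) / span
            rgb = (1.0 - t, 1.0 - t, t)
            name = f"hyd_{chain}_{seq}{icode}".strip()
            lines.append(f"set_color {name}_c, [{rgb[0]:.3f}, {rgb[1]:.3f}, {rgb[2]:.3f}]")
            sel = f"chain {chain} and resi {seq}{icode}"
            lines.append(f"color {name}_c, ({sel})")
    return "\n".join(lines) + "\n"
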