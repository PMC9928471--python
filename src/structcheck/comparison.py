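"""Model superposition and Calpha-RMSD matrices.

Models are compared by least-squares (Kabsch) superposition of
corresponding Calpha atoms; correspondence is by author residue identity
(same chain / seq_id / insertion code), never by sequence alignment.  A
loop RMSD can be measured in a framework-fitted frame by giving separate
fit and measurement selections — the convention used when contrasting
whole-domain agreement with divergence of a hypervariable loop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError
from .structure_io import StructureModel

_RANGE_RE = re.compile(r"^([^:]+):(-?\d+)([A-Za-z]?)(?:-(-?\d+)([A-Za-z]?))?$")


@dataclass
class ResidueSelection:
    """A set of residue ranges, e.g. the Fv framework or a CDR loop.

    ``entries`` are (chain_id, first_seq_id, last_seq_id, icode) with
    inclusive bounds on the author numbering.
    """

    entries: list[tuple[str, int, int, str]]
    label: str = ""

    @classmethod
    def from_string(cls, text: str, label: str = "") -> "ResidueSelection":
        """Parse "H:95-102,L:1-10" style range lists."""
        entries = []
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            m = _RANGE_RE.match(part)
            if not m:
                raise SelectionError(f"cannot parse selection {part!r}")
            chain, first, icode1, last, _ = m.groups()
            lo = int(first)
            hi = int(last) if last is not None else lo
            entries.append((chain, lo, hi, icode1 or ""))
        if not entries:
            raise SelectionError(f"empty selection {text!r}")
        return cls(entries=entries, label=label or text)

    def resolve(self, model: StructureModel):
        """Residues of ``model`` matching this selection, in model order."""
        out = []
        for res in model.residues():
            for chain, lo, hi, _ in self.entries:
                if res.chain_id == chain and lo <= res.seq_id <= hi:
                    out.append(res)
                    break
        return out

    def ca_coordinates(self, model: StructureModel) -> np.ndarray:
        """(N, 3) Calpha coordinates; raises if a residue or CA is missing."""
        residues = self.resolve(model)
        if not residues:
            raise SelectionError(
                f"selection {self.label!r} matches no residue in {model.source_path}")
        coords = []
        for res in residues:
            ca = res.get_atom("CA")
            if ca is None:
                raise SelectionError(
                    f"{model.source_path}: residue {res.id_str} has no CA atom")
            coords.append(ca.position)
        return np.array(coords)


def kabsch_superpose(coords_mobile: np.ndarray,
                     coords_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of two corresponding point sets.

    Returns (rotation, translation, rmsd) such that
    ``coords_mobile @ rotation.T + translation`` best fits ``coords_ref``
    in the least-squares sense.  The rotation is always proper
    (determinant +1): reflections are forbidden.
    """
    mob = np.asarray(coords_mobile, dtype=float)
    ref = np.asarray(coords_ref, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError(f"shape mismatch: {mob.shape} vs {ref.shape}")
    if mob.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    h = (mob - cm).T @ (ref - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cr - rotation @ cm
    fitted = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


@dataclass
class RmsdMatrix:
    """Symmetric pairwise Calpha-RMSD matrix over a set of models."""

    model_labels: list[str]
    values: np.ndarray
    selection: ResidueSelection
    superposition_selection: ResidueSelection = None

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("," + ",".join(self.model_labels) + "\n")
            for label, row in zip(self.model_labels, self.values):
                fh.write(label + "," + ",".join(f"{v:.4f}" for v in row) + "\n")


def pair_rmsd(model_a: StructureModel, model_b: StructureModel,
              rmsd_selection: ResidueSelection,
              fit_selection: ResidueSelection | None = None) -> float:
    """RMSD over ``rmsd_selection`` CAs after superposing on ``fit_selection``.

    With ``fit_selection`` None (or equal to the measurement selection) this
    is the plain best-fit RMSD.
    """
    if fit_selection is None:
        fit_selection = rmsd_selection
    fit_a = fit_selection.ca_coordinates(model_a)
    fit_b = fit_selection.ca_coordinates(model_b)
    if fit_a.shape != fit_b.shape:
        raise SelectionError("fit selections resolve to different residue counts")
    rotation, translation, _ = kabsch_superpose(fit_a, fit_b)
    meas_a = rmsd_selection.ca_coordinates(model_a)
    meas_b = rmsd_selection.ca_coordinates(model_b)
    if meas_a.shape != meas_b.shape:
        raise SelectionError("rmsd selections resolve to different residue counts")
    moved = meas_a @ rotation.T + translation
    return float(np.sqrt(np.mean(np.sum((moved - meas_b) ** 2, axis=1))))


def rmsd_matrix(models: list[StructureModel],
                rmsd_selection: ResidueSelection,
                fit_selection: ResidueSelection | None = None,
                labels: list[str] | None = None) -> RmsdMatrix:
    """Pairwise RMSD matrix over models (zero diagonal, symmetric)."""
    n = len(models)
    if labels is None:
        labels = [m.source_path for m in models]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = pair_rmsd(models[i], models[j], rmsd_selection, fit_selection)
            values[i, j] = values[j, i] = r
    return RmsdMatrix(model_labels=list(labels), values=values,
                      selection=rmsd_selection,
                      superposition_selection=fit_selection or rmsd_selection)
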