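"""Aggregate validation findings and render them for humans and viewers.

``validate`` runs the chirality, amide and clash scans over a model and
collects only the *findings* (D-amino acids, cis and non-planar amide
bonds, clashes) with totals.  Reports serialize to JSON (round-trip safe)
or plain text, and can be rendered as a PyMOL coloring script using the
conventional legend: D-amino acids purple, cis-amide bonds red,
cis-proline green, non-planar amide bonds cyan, clashing atoms yellow.
Cis-proline is informational rather than an error: it occurs at an
appreciable rate in native structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .amide import (AmideBond, AmideLabel, DEFAULT_CIS_THRESHOLD,
                    DEFAULT_TRANS_THRESHOLD, scan_amides)
from .chirality import Chirality, ChiralityAssignment, scan_chirality
from .clashes import (ClashReport, DEFAULT_TOLERANCE, clash_report)
from .constants import FINDING_COLORS
from .structure_io import StructureModel, resolve_altlocs

#: Finding classes that should be fixed; CIS_PRO is informational only.
ERROR_CLASSES = ("D", "CIS", "NON_PLANAR", "CLASH")


@dataclass
class ValidationConfig:
    cis_threshold: float = DEFAULT_CIS_THRESHOLD
    trans_threshold: float = DEFAULT_TRANS_THRESHOLD
    clash_tolerance: float = DEFAULT_TOLERANCE
    include_hydrogens: bool = False
    with_score: bool = True
    max_cn_distance: float = 2.0
    altloc_policy: str = "highest_occupancy"


@dataclass
class ValidationReport:
    """All findings for one structure model."""

    source: str
    chirality: list[ChiralityAssignment]
    amides: list[AmideBond]
    clashes: ClashReport
    n_residues: int
    score: float | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def recompute_counts(self) -> dict[str, int]:
        return {
            "D": sum(1 for c in self.chirality if c.label == Chirality.D),
            "CIS": sum(1 for a in self.amides if a.label == AmideLabel.CIS),
            "CIS_PRO": sum(1 for a in self.amides
                           if a.label == AmideLabel.CIS_PRO),
            "NON_PLANAR": sum(1 for a in self.amides
                              if a.label == AmideLabel.NON_PLANAR),
            "CLASH": self.clashes.n_clashes,
        }

    @property
    def has_findings(self) -> bool:
        return any(self.counts.values())

    @property
    def has_errors(self) -> bool:
        """True when anything beyond informational cis-Pro was found."""
        return any(self.counts[k] for k in ERROR_CLASSES)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "n_residues": self.n_residues,
            "counts": dict(self.counts),
            "score": self.score,
            "d_residues": [
                {"residue": list(c.residue_ref), "scalar": c.scalar}
                for c in self.chirality if c.label == Chirality.D],
            "undetermined_residues": [
                {"residue": list(c.residue_ref), "reason": c.reason}
                for c in self.chirality if c.label == Chirality.UNDETERMINED],
            "amide_findings": [
                {"res_i": list(a.res_i), "res_j": list(a.res_j),
                 "omega": a.omega, "label": a.label.value}
                for a in self.amides
                if a.label not in (AmideLabel.TRANS,)],
            "clashes": [
                {"atom_a": list(p.atom_a), "atom_b": list(p.atom_b),
                 "distance": round(p.distance, 4),
                 "vdw_sum": round(p.vdw_sum, 4),
                 "overlap": round(p.overlap, 4)}
                for p in self.clashes.pairs],
        }


def validate(model: StructureModel,
             config: ValidationConfig | None = None) -> ValidationReport:
    """Run all checks on a model and return the combined report."""
    if config is None:
        config = ValidationConfig()
    model = resolve_altlocs(model, policy=config.altloc_policy)
    chirality = scan_chirality(model)
    amides = scan_amides(model, cis_threshold=config.cis_threshold,
                         trans_threshold=config.trans_threshold,
                         max_cn_distance=config.max_cn_distance)
    clashes = clash_report(model, tolerance=config.clash_tolerance,
                           include_hydrogens=config.include_hydrogens,
                           with_score=config.with_score)
    report = ValidationReport(
        source=model.source_path, chirality=chirality, amides=amides,
        clashes=clashes, n_residues=model.n_residues,
        score=clashes.score if config.with_score else None)
    report.counts = report.recompute_counts()
    return report


def _resi(ref) -> tuple[str, str]:
    chain, seq, icode, _ = ref[:4]
    return chain, f"{seq}{icode}".strip()


def viewer_script(report: ValidationReport, structure_path: str) -> str:
    """PyMOL command script highlighting the report's findings.

    One selection per finding class, colored by the standard legend; amide
    findings are attributed to the following residue of the bond.  With no
    findings the script just loads and renders the structure.
    """
    lines = [f"load {structure_path}", "hide everything", "show cartoon",
             "color grey80"]
    selections: dict[str, list[tuple[str, str]]] = {
        "D": [], "CIS": [], "CIS_PRO": [], "NON_PLANAR": [], "CLASH": []}
    for c in report.chirality:
        if c.label == Chirality.D:
            selections["D"].append(_resi(c.residue_ref))
    for a in report.amides:
        if a.label in (AmideLabel.CIS, AmideLabel.CIS_PRO,
                       AmideLabel.NON_PLANAR):
            selections[a.label.value].append(_resi(a.res_j))
    for p in report.clashes.pairs:
        selections["CLASH"].append(_resi(p.atom_a))
        selections["CLASH"].append(_resi(p.atom_b))

    names = {"D": "d_amino_acids", "CIS": "cis_amides",
             "CIS_PRO": "cis_prolines", "NON_PLANAR": "nonplanar_amides",
             "CLASH": "clashes"}
    for cls in ("D", "CIS", "CIS_PRO", "NON_PLANAR", "CLASH"):
        refs = sorted(set(selections[cls]))
        if not refs:
            continue
        sel = " or ".join(
            f"(chain {chain} and resi {resi})" if chain
            else f"(resi {resi})" for chain, resi in refs)
        lines.append(f"select {names[cls]}, {sel}")
        lines.append(f"show sticks, {names[cls]}")
        lines.append(f"color {FINDING_COLORS[cls]}, {names[cls]}")
    lines.append("deselect")
    return "\n".join(lines) + "\n"


def render_report(report: ValidationReport, format: str = "text") -> str:
    """Serialize a report as human-readable text or JSON."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2)
    if format != "text":
        raise ValueError(f"unknown format {format!r}")
    out = [f"Validation report for {report.source}",
           f"  residues: {report.n_residues}"]
    if not report.has_findings:
        out.append("  no issues detected")
    counts = report.counts
    label_text = {
        "D": "D-amino acids", "CIS": "cis-amide bonds",
        "CIS_PRO": "cis-prolines (informational)",
        "NON_PLANAR": "non-planar amide bonds",
        "CLASH": "van der Waals clashes"}
    for cls, text in label_text.items():
        if counts.get(cls):
            out.append(f"  {text}: {counts[cls]}")
    for c in report.chirality:
        if c.label == Chirality.D:
            out.append(f"    D: {c.id_str}")
    for a in report.amides:
        if a.label in (AmideLabel.CIS, AmideLabel.CIS_PRO,
                       AmideLabel.NON_PLANAR):
            out.append(f"    {a.label.value}: {a.id_str} "
                       f"(omega {a.omega:.1f} deg)")
    for p in report.clashes.pairs:
        a = ":".join(str(x) for x in p.atom_a)
        b = ":".join(str(x) for x in p.atom_b)
        out.append(f"    CLASH: {a} -- {b} ({p.distance:.2f} A, "
                   f"overlap {p.overlap:.2f} A)")
    if report.score is not None:
        out.append(f"  clash score: {report.score:.2f} clashes per 100 residues")
    return "\n".join(out) + "\n"
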