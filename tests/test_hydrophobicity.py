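"""Shrake-Rupley SASA engine and Wimley-White surface mapping."""

import numpy as np
import pytest

from structcheck.constants import MAX_SASA
from structcheck.errors import ConfigurationError, StructCheckError
from structcheck.fixtures import PeptideSpec, build_peptide
from structcheck.hydrophobicity import (HydrophobicityScale, residue_sasa,
                                        shrake_rupley_sasa, sphere_lattice,
                                        surface_hydrophobicity)
from structcheck.structure_io import Atom3D, Residue, StructureModel

PROBE = 1.4
R_C = 1.7  # carbon radius in the embedded table


def _atoms_model(positions, elements):
    residues = [Residue(resname="UNK", seq_id=k + 1, icode="", chain_id="A",
                        atoms=[Atom3D(name="X", element=el, position=p)])
                for k, (p, el) in enumerate(zip(positions, elements))]
    return StructureModel(chains=[("A", residues)])


def two_sphere_accessible_area(r1, r2, d):
    """Closed-form accessible area of two intersecting spheres (the
    analytic oracle): each sphere loses the spherical cap inside the
    other."""
    a1 = 4 * np.pi * r1 ** 2
    a2 = 4 * np.pi * r2 ** 2
    if d >= r1 + r2:
        return a1 + a2
    cos1 = (d ** 2 + r1 ** 2 - r2 ** 2) / (2 * d * r1)
    cos2 = (d ** 2 + r2 ** 2 - r1 ** 2) / (2 * d * r2)
    cap1 = 2 * np.pi * r1 ** 2 * (1 - cos1)
    cap2 = 2 * np.pi * r2 ** 2 * (1 - cos2)
    return (a1 - cap1) + (a2 - cap2)


class TestLattice:
    def test_points_on_unit_sphere(self):
        pts = sphere_lattice(960)
        assert pts.shape == (960, 3)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigurationError):
            sphere_lattice(5)


class TestSasa:
    def test_isolated_atom_is_analytic_sphere(self):
        model = _atoms_model([[0.0, 0.0, 0.0]], ["C"])
        areas, _, _ = shrake_rupley_sasa(model, n_points=960)
        expected = 4 * np.pi * (R_C + PROBE) ** 2
        assert areas[0] == pytest.approx(expected, rel=0.01)
        assert expected == pytest.approx(120.76, rel=0.001)

    def test_distant_atoms_keep_full_spheres(self):
        model = _atoms_model([[0, 0, 0], [2 * (R_C + PROBE) + 1, 0, 0]],
                             ["C", "C"])
        areas, _, _ = shrake_rupley_sasa(model, n_points=960)
        full = 4 * np.pi * (R_C + PROBE) ** 2
        assert np.allclose(areas, full, rtol=0.01)

    @pytest.mark.parametrize("d", [1.5, 2.5, 4.0, 5.5])
    def test_two_overlapping_spheres_match_cap_formula(self, d):
        model = _atoms_model([[0, 0, 0], [d, 0, 0]], ["C", "C"])
        areas, _, _ = shrake_rupley_sasa(model, n_points=960)
        r = R_C + PROBE
        assert areas.sum() == pytest.approx(
            two_sphere_accessible_area(r, r, d), rel=0.01)

    def test_residue_sums_equal_total(self, mixed20):
        areas, _, _ = shrake_rupley_sasa(mixed20, n_points=240)
        per_res = residue_sasa(mixed20, n_points=240)
        assert sum(per_res.values()) == pytest.approx(areas.sum(), abs=1e-9)

    def test_translation_invariance_exact(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 8, size=(20, 3))
        a1, _, _ = shrake_rupley_sasa(_atoms_model(pos, ["C"] * 20), n_points=240)
        a2, _, _ = shrake_rupley_sasa(
            _atoms_model(pos + np.array([17.0, -4.0, 2.0]), ["C"] * 20),
            n_points=240)
        assert np.allclose(a1, a2, atol=1e-9)

    def test_rotation_invariance_within_quadrature_error(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 8, size=(20, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a1, _, _ = shrake_rupley_sasa(_atoms_model(pos, ["C"] * 20), n_points=960)
        a2, _, _ = shrake_rupley_sasa(_atoms_model(pos @ q.T, ["C"] * 20),
                                      n_points=960)
        assert a2.sum() == pytest.approx(a1.sum(), rel=0.02)

    def test_quadrature_converges(self):
        model = _atoms_model([[0, 0, 0], [2.5, 0, 0]], ["C", "C"])
        r = R_C + PROBE
        exact = two_sphere_accessible_area(r, r, 2.5)
        errors = []
        for n in (60, 240, 960):
            areas, _, _ = shrake_rupley_sasa(model, n_points=n)
            errors.append(abs(areas.sum() - exact))
        assert errors[2] < errors[0]


class TestSurfaceHydrophobicity:
    def test_summary_is_sasa_weighted_mean(self, mixed20):
        """Oracle: recompute the weighted mean directly from the records."""
        result = surface_hydrophobicity(mixed20, n_points=240)
        surf = [r for r in result.records if r.is_surface]
        want = (sum(r.sasa * r.scale_value for r in surf)
                / sum(r.sasa for r in surf))
        assert result.surface_mean == pytest.approx(want, abs=1e-12)

    def test_deterministic(self, mixed20):
        r1 = surface_hydrophobicity(mixed20, n_points=240)
        r2 = surface_hydrophobicity(mixed20, n_points=240)
        assert r1.surface_mean == r2.surface_mean
        assert [a.sasa for a in r1.records] == [a.sasa for a in r2.records]

    def test_buried_residue_excluded_from_summary(self, mixed20):
        """Raising the exposure threshold shrinks the surface set; fully
        buried residues never contribute."""
        loose = surface_hydrophobicity(mixed20, surface_threshold=0.0,
                                       n_points=240)
        strict = surface_hydrophobicity(mixed20, surface_threshold=0.9,
                                        n_points=240)
        assert (sum(r.is_surface for r in strict.records)
                <= sum(r.is_surface for r in loose.records))
        for r in strict.records:
            assert r.is_surface == (r.relative_sasa >= 0.9)

    def test_relative_sasa_uses_reference_maxima(self, ala5):
        result = surface_hydrophobicity(ala5, n_points=240)
        for rec in result.records:
            assert rec.relative_sasa == pytest.approx(
                rec.sasa / MAX_SASA[rec.residue_ref[3]], abs=1e-9)

    def test_exposing_tryptophan_shifts_mean_toward_its_value(self):
        """Same sequence, two conformations: moving the lone Trp out of
        the chain raises its relative exposure, and the SASA-weighted mean
        moves toward Trp's (strongly hydrophobic, -1.85 kcal/mol) value
        and away from the lysine background (+0.99)."""
        seq = ["LYS"] * 3 + ["TRP"] + ["LYS"] * 3
        buried = build_peptide(PeptideSpec(sequence=seq, phi=-57.0, psi=-47.0))
        exposed = buried.copy()
        for atom in exposed.get_residue("A", 4).atoms:
            atom.position = atom.position + np.array([0.0, 0.0, 30.0])
        res_b = surface_hydrophobicity(buried, n_points=240)
        res_e = surface_hydrophobicity(exposed, n_points=240)
        trp_b = next(r for r in res_b.records if r.residue_ref[3] == "TRP")
        trp_e = next(r for r in res_e.records if r.residue_ref[3] == "TRP")
        assert trp_e.relative_sasa > trp_b.relative_sasa
        assert res_e.surface_mean < res_b.surface_mean

    def test_unknown_residue_in_scale_errors(self):
        scale = HydrophobicityScale()
        with pytest.raises(StructCheckError, match="XYZ"):
            scale.value("XYZ")

    def test_csv_export(self, ala5, tmp_path):
        result = surface_hydrophobicity(ala5, n_points=240)
        out = tmp_path / "h.csv"
        result.to_csv(str(out))
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("chain,seq_id")
        assert len(lines) == 1 + len(result.records)
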