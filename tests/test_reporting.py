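"""Report aggregation, serialization, viewer scripts and the CLI."""

import json

import pytest
from click.testing import CliRunner

from structcheck.cli import main as cli_main
from structcheck.fixtures import PeptideSpec, build_peptide, inject_clash
from structcheck.reporting import (ValidationConfig, render_report, validate,
                                   viewer_script)
from structcheck.structure_io import write_pdb


@pytest.fixture(scope="module")
def full_report():
    spec = PeptideSpec(
        sequence=["ALA", "SER", "ALA", "PRO", "GLY", "LEU", "ALA", "VAL"],
        omega=[180.0, 5.0, 0.0, 180.0, 90.0, 180.0, 180.0],
        chirality=["L", "L", "L", "L", "L", "D", "L", "L"])
    model = inject_clash(build_peptide(spec), ("A", 4), 2.0)
    return validate(model)


class TestValidate:
    def test_clean_model_zero_findings(self, mixed20):
        report = validate(mixed20)
        assert report.counts == {"D": 0, "CIS": 0, "CIS_PRO": 0,
                                 "NON_PLANAR": 0, "CLASH": 0}
        assert report.score == 0.0
        assert not report.has_findings
        assert not report.has_errors

    def test_planted_findings_counted(self, full_report):
        assert full_report.counts == {"D": 1, "CIS": 1, "CIS_PRO": 1,
                                      "NON_PLANAR": 1, "CLASH": 1}

    def test_counts_recomputable_from_lists(self, full_report):
        assert full_report.counts == full_report.recompute_counts()

    def test_chirality_labels_partition_residues(self, full_report):
        from structcheck.chirality import Chirality
        by_label = {label: sum(1 for c in full_report.chirality
                               if c.label == label) for label in Chirality}
        assert sum(by_label.values()) == full_report.n_residues

    def test_cis_pro_only_is_informational(self):
        spec = PeptideSpec(sequence=["ALA", "ALA", "PRO", "ALA"],
                           omega=[180.0, 0.0, 180.0])
        report = validate(build_peptide(spec))
        assert report.counts["CIS_PRO"] == 1
        assert report.has_findings
        assert not report.has_errors

    def test_score_optional(self, mixed20):
        without = validate(mixed20, ValidationConfig(with_score=False))
        assert without.score is None


class TestRender:
    def test_json_round_trip(self, full_report):
        data = json.loads(render_report(full_report, "json"))
        assert data["counts"] == full_report.counts
        assert len(data["d_residues"]) == 1
        assert len(data["clashes"]) == 1
        labels = {f["label"] for f in data["amide_findings"]}
        assert labels == {"CIS", "CIS_PRO", "NON_PLANAR"}

    def test_clean_text_mentions_no_issues(self, mixed20):
        text = render_report(validate(mixed20), "text")
        assert "no issues detected" in text
        assert "clash score: 0.00" in text

    def test_text_lists_findings_with_author_numbering(self, full_report):
        text = render_report(full_report, "text")
        assert "D: A:LEU6" in text
        assert "CIS_PRO" in text and "NON_PLANAR" in text

    def test_score_line_only_when_enabled(self, mixed20):
        on = render_report(validate(mixed20), "text")
        off = render_report(
            validate(mixed20, ValidationConfig(with_score=False)), "text")
        assert "clash score" in on
        assert "clash score" not in off

    def test_unknown_format_rejected(self, full_report):
        with pytest.raises(ValueError):
            render_report(full_report, "yaml")


class TestViewerScript:
    def test_legend_colors_and_selections(self, full_report):
        script = viewer_script(full_report, "model.pdb")
        assert script.startswith("load model.pdb")
        for name, color in (("d_amino_acids", "purple"),
                            ("cis_amides", "red"),
                            ("cis_prolines", "green"),
                            ("nonplanar_amides", "cyan"),
                            ("clashes", "yellow")):
            assert script.count(f"select {name},") == 1
            assert f"color {color}, {name}" in script

    def test_d_residue_selected_by_chain_and_number(self, full_report):
        script = viewer_script(full_report, "model.pdb")
        d_line = next(l for l in script.splitlines()
                      if l.startswith("select d_amino_acids"))
        assert "chain A and resi 6" in d_line

    def test_clash_selection_contains_both_partners(self, full_report):
        script = viewer_script(full_report, "model.pdb")
        clash_line = next(l for l in script.splitlines()
                          if l.startswith("select clashes"))
        pair = full_report.clashes.pairs[0]
        for ref in (pair.atom_a, pair.atom_b):
            assert f"resi {ref[1]}" in clash_line

    def test_empty_report_is_noop_script(self, mixed20):
        script = viewer_script(validate(mixed20), "clean.pdb")
        assert "load clean.pdb" in script
        assert "\nselect" not in script
        assert "color purple" not in script

    def test_deterministic_text(self, full_report):
        assert (viewer_script(full_report, "m.pdb")
                == viewer_script(full_report, "m.pdb"))


class TestCli:
    def _write(self, tmp_path, model, name):
        path = tmp_path / name
        write_pdb(model, str(path))
        return str(path)

    def test_clean_model_exits_zero(self, tmp_path, mixed20):
        path = self._write(tmp_path, mixed20, "clean.pdb")
        result = CliRunner().invoke(cli_main, ["validate", path])
        assert result.exit_code == 0
        assert "no issues detected" in result.output

    def test_defective_model_exits_one_with_counts(self, tmp_path):
        spec = PeptideSpec(sequence=["ALA", "ALA", "GLY", "LEU", "ALA"],
                           omega=[180.0, 5.0, 180.0, 180.0],
                           chirality=["L", "L", "L", "D", "L"])
        model = build_peptide(spec)
        path = self._write(tmp_path, model, "bad.pdb")
        json_out = tmp_path / "report.json"
        result = CliRunner().invoke(
            cli_main, ["validate", path, "--json", str(json_out)])
        assert result.exit_code == 1
        assert "cis-amide bonds: 1" in result.output
        assert "D-amino acids: 1" in result.output
        data = json.loads(json_out.read_text())
        assert data["counts"]["CIS"] == 1
        assert data["counts"]["D"] == 1

    def test_garbage_input_exits_two(self, tmp_path):
        bad = tmp_path / "garbage.pdb"
        bad.write_text("not a structure\n")
        result = CliRunner().invoke(cli_main, ["validate", str(bad)])
        assert result.exit_code == 2

    def test_viewer_script_written(self, tmp_path, mixed20):
        path = self._write(tmp_path, mixed20, "m.pdb")
        out = tmp_path / "view.pml"
        result = CliRunner().invoke(
            cli_main, ["validate", path, "--viewer-script", str(out)])
        assert result.exit_code == 0
        assert out.read_text().startswith(f"load {path}")

    def test_compare_writes_matrix(self, tmp_path):
        model = build_peptide(PeptideSpec(sequence=["ALA"] * 8))
        p1 = self._write(tmp_path, model, "m1.pdb")
        p2 = self._write(tmp_path, model, "m2.pdb")
        out = tmp_path / "rmsd.csv"
        result = CliRunner().invoke(
            cli_main, ["compare", p1, p2, "--select", "A:1-8",
                       "--out", str(out)])
        assert result.exit_code == 0
        assert out.exists()
        rows = out.read_text().strip().splitlines()
        assert len(rows) == 3

    def test_hydrophobicity_csv(self, tmp_path, ala5):
        path = self._write(tmp_path, ala5, "m.pdb")
        out = tmp_path / "hyd.csv"
        result = CliRunner().invoke(
            cli_main, ["hydrophobicity", path, "--out", str(out),
                       "--n-points", "240"])
        assert result.exit_code == 0
        assert "surface mean hydrophobicity" in result.output
        assert len(out.read_text().strip().splitlines()) == 6
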