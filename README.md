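# structcheck

Validation of protein structure models — especially antibody models from
structure-prediction tools — for physical artifacts that no amount of
downstream refinement can repair: **D-amino acids**, **cis and non-planar
amide bonds**, and **van der Waals clashes**. The package also compares
models by Cα RMSD over whole domains or selected loops, and maps
Wimley–White surface hydrophobicity onto the solvent-exposed surface.

Predicted structures (antibody Fv models in particular) frequently contain
these defects in the CDR loops, where they silently distort every
structure-based property downstream: surface-hydrophobicity estimates,
docking, and MD starting ensembles. Because molecular dynamics cannot
cross the cis↔trans or D↔L barriers, such errors are effectively
permanent — the point of this tool is to catch them *before* any
computation or experiment is built on the model.

## What is checked

**Chirality.** At each Cα the three heavy substituents are taken in fixed
priority order N > C(carbonyl) > Cβ (the implicit Hα ranks lowest and is
omitted, so the verdict is hydrogen-independent). They span a triangle;
the scalar

&nbsp;&nbsp;&nbsp;&nbsp;*s* = [(C−N) × (Cβ−N)] · (centroid − Cα) = det[N−Cα, C−Cα, Cβ−Cα]

is positive for L and negative for D (calibrated against ideal
L-amino-acid geometry and cross-checked against an independent 3D
embedding of L-/D-alanine). Glycine is achiral; residues with missing
atoms are reported UNDETERMINED, never an error.

**Amide bonds.** The ω torsion Cα(i)–C(i)–N(i+1)–Cα(i+1) of every peptide
bond is classified: |ω| ≤ 30° cis, |ω| ≥ 150° trans, otherwise
non-planar. Cis bonds preceding proline are labeled separately (cis-Pro)
and treated as informational, because they occur naturally. Chain breaks
(C–N distance > 2.0 Å) never yield spurious angles.

**Clashes.** Two atoms clash when *d* < r₁ + r₂ − 0.4 Å with van der
Waals radii from an embedded table (Bondi values; carbonyl-type oxygen
reduced to 1.40 Å as in the standard protein-contact convention). Pairs
within one residue or within three covalent bonds through a peptide or
disulfide bond are exempt. The neighbor search uses a k-d tree but
returns exactly the brute-force pair set. An optional score normalizes
severity by chain length: **score = 100 · n_clashes / n_residues**
(clashes per 100 residues). Chirality and amide findings are never part
of the score.

Findings can be rendered as a PyMOL script with the conventional colors:
purple = D-amino acid, red = cis-amide, green = cis-proline,
cyan = non-planar amide, yellow = clashing atoms.

## Worked example

The built-in generator plants defects at exact positions; the validator
must find exactly those. Build an 8-mer with one D-leucine, a cis bond, a
cis-proline, a non-planar bond and one injected clash, then validate:

```python
from structcheck import PeptideSpec, build_peptide, inject_clash, write_pdb
spec = PeptideSpec(
    sequence=["ALA", "SER", "ALA", "PRO", "GLY", "LEU", "ALA", "VAL"],
    omega=[180.0, 5.0, 0.0, 180.0, 90.0, 180.0, 180.0],
    chirality=["L", "L", "L", "L", "L", "D", "L", "L"])
model = inject_clash(build_peptide(spec), ("A", 4), 2.0)
write_pdb(model, "example.pdb")
```

```console
$ structcheck validate example.pdb --score --viewer-script example.pml
Validation report for example.pdb
  residues: 8
  D-amino acids: 1
  cis-amide bonds: 1
  cis-prolines (informational): 1
  non-planar amide bonds: 1
  van der Waals clashes: 1
    D: A:LEU6
    CIS: A:SER2-ALA3 (omega 5.1 deg)
    CIS_PRO: A:ALA3-PRO4 (omega 0.1 deg)
    NON_PLANAR: A:GLY5-LEU6 (omega 90.0 deg)
    CLASH: A:4::PRO:CX -- A:8::VAL:O (2.00 A, overlap 0.70 A)
  clash score: 12.50 clashes per 100 residues
```

Every planted defect is reported, at its planted position, and nothing
else. The exit code is 1 (findings present); a clean model exits 0, and
a model whose only finding is cis-Pro also exits 0. The `.pml` script
opens the model in PyMOL with the findings colored as above.

Amide findings name the bond but are attributed to the *following*
residue (the one whose conformation is unusual), which is why the
non-planar bond GLY5–LEU6 colors residue 6.

Model comparison and hydrophobicity from the same CLI:

```bash
structcheck compare m1.pdb m2.pdb --select "H:95-102" \
    --fit "H:1-94,H:103-113" --out cdrh3_rmsd.csv
structcheck hydrophobicity model.pdb --out residues.csv
```

`compare` writes the pairwise Cα-RMSD matrix over the `--select` residues
after superposing on the `--fit` residues (loop RMSD in a
framework-fitted frame — omit `--fit` for a plain best fit).
`hydrophobicity` writes per-residue SASA, relative exposure and
Wimley–White interface scale values, and prints the SASA-weighted mean
over surface residues.

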