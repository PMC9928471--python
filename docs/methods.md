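# Methods

This note records the models, conventions and numerical choices behind
`structcheck`, and what its synthetic test substrate does and does not
establish about real structure models.

## Structure model and input handling

A `StructureModel` is an ordered list of chains of residues in author
order; residue identity is the author numbering `(chain, seq_id, icode)`
and is never renumbered. PDB files are read and written directly against
the wwPDB v3.3 fixed-column layout; mmCIF input goes through gemmi into
the same hierarchy. Waters are non-polymer; a HETATM residue with an
N/CA/C backbone inside a chain (a modified amino acid) is treated as
polymer so that it is checked rather than ignored. In multi-MODEL files
the first model is used unless another is requested.

Alternate locations are collapsed before any check: per atom name the
highest-occupancy location wins, ties broken to the alphabetically first
altloc identifier (`first` keeps file order instead). The operation is
idempotent.

Peptide connectivity is distance-based: consecutive residues are bonded
when d(C(i), N(i+1)) ≤ 2.0 Å (ideal bond 1.33 Å). The generous cutoff
tolerates distorted models while guaranteeing that chain breaks and gaps
never produce an omega angle between unconnected residues.

## Chirality

The Cα verdict uses only heavy atoms — N, C (carbonyl), Cβ in that
priority order — so models without hydrogens get identical labels. The
orientation scalar is the triple product
dot((C−N) × (Cβ−N), centroid(N, C, Cβ) − Cα), which equals the signed
volume det[N−Cα, C−Cα, Cβ−Cα]; the sign meaning "L" was calibrated once
against ideal L-amino-acid geometry (and is cross-checked in the tests
against RDKit's 3D embedding of (S)- and (R)-alanine) and frozen as
`L_SIGN = +1`. |scalar| < 1e-6 (near-planar center) is reported
UNDETERMINED, as is any residue missing one of the four atoms. Glycine
is ACHIRAL by name. Cysteine's CIP quirk (sulfur outranks the carbonyl
chain, so L-Cys is formally (R)) does not affect the geometric L/D
verdict because the same three heavy atoms are used for every residue
type. Side-chain stereocenters (Thr Cβ, Ile Cβ) are not checked in this
version.

## Amide classification

ω(i→i+1) = dihedral Cα(i)–C(i)–N(i+1)–Cα(i+1), reported in (−180°, 180°]
with trans mapped to +180°. Classes: |ω| ≤ 30° cis (cis-Pro when residue
i+1 is proline), |ω| ≥ 150° trans, otherwise non-planar; both thresholds
are configurable (the 30° cutoff is the common cis-peptide criterion in
the validation literature). A 1e-9° tolerance is applied at both
boundaries so angles reconstructed exactly at a threshold classify as
the threshold value. In reports and viewer scripts a bond finding is
attributed to the following residue — the one whose conformation is
unusual. Cis-Pro is severity "info"; everything else is an error-level
finding and drives the CLI exit code.

## Clash detection

Criterion: d < r_a + r_b − tolerance, default tolerance 0.4 Å. Radii are
an embedded Bondi (1964) table with one deliberate change: oxygen uses
the reduced protein-contact radius 1.40 Å (the Probe/MolProbity
convention). The full Bondi 1.52 Å would flag canonical native geometry
— the Cβ(i)⋯O(i+2) contact of a polyproline-I (all-cis) helix sits at
2.71 Å — which is unacceptable for a validator whose findings must mean
"physically implausible". Unknown elements fall back to 1.70 Å with a
warning, or raise in strict mode.

Exclusions: pairs within one residue, and inter-residue pairs separated
by three covalent bonds or fewer through the peptide bond C(i)–N(i+1) or
through a disulfide SG–SG bond (detected at ≤ 2.5 Å). Connectivity comes
from residue-template atom names, not from distance-based bond
perception. The three-bond rule is load-bearing: the 1-4 pairs across a
peptide bond (O(i)⋯Cα(i+1) at ~2.77 Å in the ideal trans conformation,
Cα(i)⋯Cα(i+1) at ~2.9 Å in cis) are fixed by covalent geometry and carry
no information about packing quality.

Hydrogens are excluded by default — predicted models usually lack them,
and mixed-protonation comparisons would be inconsistent — and can be
included by flag. The k-d tree (scipy `cKDTree`) is purely an
accelerator: the tests assert exact pair-set equality with an exhaustive
double loop whose exclusions are derived independently from a
reconstructed bond graph.

Score: 100 × n_clashes / n_residues, i.e. clashes per 100 residues. The
two stated ingredients are the clash count and the chain length; the
normalization constant is this package's choice. Chirality and amide
results cannot enter the score (it is a function of two integers only).

## Superposition and RMSD matrices

Kabsch superposition via SVD with the determinant correction, so the
rotation is always proper — a mirror-image model cannot "superpose" by
reflection. Correspondence between models is by author residue identity;
there is no alignment fallback, and a missing residue or Cα is an error
naming the model and residue. Loop RMSD uses the fit-on-framework,
measure-on-loop convention (both selections are free, so a plain fit is
the special case fit = measure). When fit and measure selections differ
the matrix is symmetrized only by construction of the pairwise values;
the fit-direction asymmetry is below 1e-6 Å in the tested regimes.

## SASA and surface hydrophobicity

Shrake–Rupley with a deterministic golden-spiral lattice (default 960
points) on each atom's expanded sphere (van der Waals radius + 1.4 Å
probe); a lattice point is accessible when outside every neighbor's
expanded sphere. Per-residue SASA is the sum over its atoms; relative
exposure divides by the Tien et al. (2013) theoretical maxima, and
residues with relative exposure ≥ 0.2 count as surface. The lattice has
a fixed orientation in space, so SASA is exactly translation-invariant
and rotation-invariant only to within quadrature error (≈ 1% at 960
points; the isolated-sphere and two-sphere analytic cases are reproduced
to better than 1%).

Hydrophobicity uses the Wimley–White *interface* scale (water → POPC
bilayer interface transfer free energies, kcal/mol; Asp/Glu charged, His
neutral), embedded as a constant table. Negative = hydrophobic = yellow
in the viewer-script gradient, positive = hydrophilic = blue. The
summary statistic is the SASA-weighted mean scale value over surface
residues. The octanol scale was the alternative; the interface scale was
chosen as the variant aimed at membrane/surface partitioning, and the
scale name is stored with every result so the choice is visible. No
patch clustering is attempted — only per-residue values and the weighted
mean.

## Synthetic peptides (the test substrate)

`build_peptide` realizes a `PeptideSpec` — sequence, per-bond ω, per
residue L/D, optional hydrogens — by sequential internal-to-Cartesian
(NeRF) placement from standard bond lengths and angles (N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; Engh–Huber-style values frozen
in `constants.py`). Side chains are stubbed at Cβ, except proline which
gets its CB/CG/CD ring because CD is bonded to N and participates in the
exclusion rules. D residues reflect the side-chain (and Hα) placement
through the backbone plane at Cα, flipping the stereocenter without
touching the backbone; when φ/ψ are given as scalars they are mirrored
for D residues so a planted D center never creates a collateral contact.

ω and chirality are reproduced exactly as requested (ω to ≪ 0.1°). φ/ψ
are free parameters: defaults are extended (−120°, 130°), switched to a
polyproline-I-like (−81°, 155°) preference around cis bonds, and when
the requested angles would make the growing chain collide with itself
the builder searches — the whole ψ grid is screened in one vectorized
pass (the O/N/Cα unit rotates rigidly about the Cα–C axis), candidates
are drawn with a bias toward growth away from the existing atoms, dead
ends unwind up to three residues, and failed passes restart with
progressively deeper candidate caps. The search is seeded from the spec,
so builds are bitwise deterministic. A small margin (0.01 Å) beyond the
clash criterion is enforced during growth so built models are never
borderline.

`mirror_model` negates x on every atom: an involution that swaps all
L/D, negates all torsions and preserves all distances. `inject_clash`
adds a pseudo side-chain carbon ("CX") at an exact distance from a
sequence-distant residue's atom, searching deterministic sphere
directions so that no unintended contact is created — the clash count
changes by exactly one (or zero if the distance is outside the
criterion).

What passing the closure tests shows: on ideal-geometry chains whose
defects are planted exactly, the validator recovers precisely the
planted finding set, with zero false positives, over thousands of
randomized defects. What it does not show: behavior on real models with
full side chains, alternate conformations of long side chains, or
borderline geometry near the thresholds — real models can produce
genuine findings these fixtures never exercise, which is why thresholds
and tolerance are configurable and reported with every finding.

## Problem sizes

The randomized closure runs use 200 recipes of 3–30 residues (the suite
and the acceptance script alike); the clash-oracle comparisons use
400–500 free atoms in a 20 Å box over 25–50 seeds; SASA analytic checks
use 960 lattice points; superposition checks 100 random 10-point pairs.
These sizes make every check exhaustive at the scale where the expected
answer is known exactly, and keep the full suite around a minute.

## Known limitations

- Chirality is checked at Cα only; side-chain stereocenters and ligand
  chirality are out of scope.
- The clash exclusion templates cover standard-residue connectivity;
  exotic covalent modifications (beyond peptide and disulfide links) are
  not exempted and could register as contacts.
- SASA is not ensemble-averaged and the lattice orientation is fixed;
  sub-percent anisotropy remains at 960 points.
- The fixture builder stubs side chains at Cβ: it cannot emulate
  rotamer-level packing defects.
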