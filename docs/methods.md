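# Methods

This note records the models, conventions and numerical choices behind
`rotormat`, and what its synthetic benchmarks do and do not demonstrate.

## Rotors and their extraction

Each residue carries up to four torsions: φ = C(i−1)–N–CA–C,
ψ = N–CA–C–N(i+1), χ₁ = N–CA–CB–γ, χ₂ = CA–CB–γ–δ. Angles are degrees
in the half-open interval (−180, +180], IUPAC sign convention
(clockwise positive looking from the second to the third atom).
Undefined rotors — chain termini for φ/ψ, residue types lacking the
atoms (GLY has no χ; ALA stops at CB; SER, CYS, THR and VAL have no δ
atom), or missing coordinates — are an explicit `None`, never 0.0,
since 0 is a legal angle. Branch ambiguities in the χ atom quadruples
are fixed once in a shipped table (ILE χ₁ via CG1 and χ₂ via CD1, THR
χ₁ via OG1, VAL χ₁ via CG1, ASN/ASP χ₂ via OD1, HIS χ₂ via ND1,
LEU/PHE/TYR/TRP χ₂ via CD1); any fixed convention yields reproducible
statistics, and no claim of parity with other software's choices is
made.

PDB input is deliberately narrow: ATOM records only, waters and HETATM
skipped, first MODEL of multi-model files, alternate locations ' ' and
'A' kept (first occurrence wins). Residues missing a backbone atom are
flagged incomplete — a warning, not an error — and contribute only the
rotors their atoms support. mmCIF is out of scope.

### Coordinate precision and the writer's `decimals` option

Standard PDB stores coordinates as `%8.3f`; that milli-ångström
quantization perturbs recomputed torsions by roughly 0.05–0.1°. For
workflows that must reproduce torsions far below that (e.g. verifying
the chain builder to 1e−6°), `write_pdb(..., decimals=9)` widens the
three coordinate fields while leaving every column before them
standard. The parser reads both layouts: it takes the three floats
from columns 31–54 when that slice holds exactly three numbers, and
otherwise tokenizes the line's tail. Nine decimals bring the
round-trip torsion error to ~1e−7°; the default remains 3 (standard
PDB).

## Secondary structure and flanks

Classification is purely dihedral — a residue is H if (φ, ψ) falls in
the helix window, S if in the sheet window, else O; no hydrogen-bond
assignment (DSSP/STRIDE) is attempted, because the three-group scheme
this package implements is defined on dihedral distributions. The
default windows are conventional Ramachandran regions, declared rather
than fitted: helix φ ∈ (−100, −30), ψ ∈ (−80, −5); sheet
φ ∈ (−170, −50), ψ ∈ (90, 180]. Runs shorter than the minimum element
length (helix 4 ≈ one turn, sheet 3) are demoted to O. All of these
are configurable; results depend on them and comparisons across
window choices should hold them fixed. The left-handed-helix region is
not a separate class and falls into O.

Each maximal element labels its interior residues with offset 0 and up
to three residues on each side with offsets ∓1..∓3, truncated at chain
ends. When two elements are close, the gap residues keep the labels
from both sides (multi-labeling); a precedence rule would discard
counts asymmetrically and would be an arbitrary invention.

## Grids and basins

The 37×37 grid uses 10° cells centered on −180, −170, …, +180. Note
360/10 = 36: the wrap point intentionally occupies two distinct
centers, +180 (covering (+175, +180]) and −180 (covering
(−180, −175]), reproducing the 37-center convention this grid follows.
Cell choice is nearest-center with midpoints rounded away from zero.

The four basins partition (−180, +180] as
[+150, +180] ∪ (−180, −150) | [−150, −50) | [−50, +50) | [+50, +150),
half-open at the upper edge so every angle belongs to exactly one
basin and +180 belongs to the wrap basin. Boundary ownership (e.g.
−150 opens basin 2) is a declared convention; occupancy totals always
equal the number of defined input angles.

## Basin free energies

ΔG*ᵢ* = −RT ln(*Nᵢ*/*Bᵢ*), read as log-odds of the reference basin
against the aggregate *B* — the reading under which the three variants
are meaningfully different:

- MIDMAT1: *Bᵢ* = Σ*b* − *bᵢ* (sum of remaining basins),
- MIDMAT2: *Bᵢ* = (Σ*b* − *bᵢ*)/3 (their average),
- MIDMAT3: *Bᵢ* = Σ*b*/4 (average over all four).

R = 8.314 J·mol⁻¹·K⁻¹ and T = 298.15 K (25 °C) by default; energies
are reported in kJ/mol. Whether the original tables used joules or
calories, or N·B instead of N/B, cannot be settled; both knobs are
exposed (`EnergyParams`, and the ratio reading is fixed in code as the
only internally consistent one). A Laplace pseudocount (default 1) is
added to every basin before taking odds so empty basins stay finite;
pseudocount 0 is available for exact small-count checks and raises
only when all four counts are zero. Closed forms used as self-checks:
uniform counts give exactly 0 for MIDMAT2/3 and +RT ln 3 per basin for
MIDMAT1. Rotors a residue type lacks contribute a row of zeros to the
4×4 profile and are flagged; this means GLY/ALA differences in the
matrix stage come only from φ/ψ (and the zero rows), a declared policy
rather than a derivable fact.

## Rotor directions

The modal angle of a rotor at a flank offset is the most populated 10°
bin center (ties broken toward 0, then negative). A transition's
displacement per rotor is the minimal signed arc between the modal
angles at its two end offsets (formation −3 → 0, breaking 0 → +3);
signs use a zero-tolerance of 5° (half a bin, configurable). A net arc
cannot represent a full-circle 360° rotation; the per-offset modal
trajectory is therefore retained in the report so multi-step paths
remain visible, while the sign always refers to the net end-to-end
arc.

The reference sign table (helix formation +, +, −, + for φ, ψ, χ₁,
χ₂; helix breaking −, +, +, −; sheet formation −, +, +, −; sheet
breaking +, −, −, +) encodes the χ₁/χ₂ counter-rotation and the
χ₁-against-φ counter-rotation in every row. Two caveats are inherent
to it: the narrative descriptions it derives from are internally
inconsistent about ψ (stated both as always left-handed outside sheet
breaking and as right-handed throughout helix formation and breaking —
the table follows the per-transition figure annotations, and is
overridable rather than second-guessed), and the helix-breaking and
sheet-formation rows coincide, so sign vectors alone cannot
distinguish those two transitions.

## Substitution matrices

D*ₓᵧ* is the Euclidean distance over the 16 energy components (4
rotors × 4 basins) of two profiles. Distances are divided by a common
denominator (default 1000, independent of the J/kJ choice upstream;
both knobs are exposed so their composition can be explored), the
median is taken over the 190 unordered distinct pairs (self-distances,
identically zero, excluded; even count → mean of the two middle
values), and SV*ₓᵧ* = 0.5 · (median − D*ₓᵧ*). The self-score rule
SV*ₓₓ* = max(SV) + max(row *x*) is applied on unrounded values and the
whole matrix is rounded once, halves away from zero. Applying the
diagonal rule after rounding is inconsistent with the printed
reference tables (their global and row maxima would not reproduce
their diagonals), which is why the unrounded order was chosen.
"Nearest decimal point" is read as nearest integer — the reference
tables are integer-valued.

The shipped `data/MIDMAT{1,2,3}.mat` files are verbatim transcriptions
of the published tables. As printed, MIDMAT3 is exactly symmetric but
MIDMAT1 and MIDMAT2 contain asymmetric entry pairs (13 and 88 of the
190, respectively, differing by 1–2 units); the files are distributed
as printed, the reader does not enforce symmetry, and the test suite
reports — rather than repairs — the asymmetry. Regenerating the tables
numerically is not attempted: it would require the original
≈23,000-structure culled PDB snapshot and conventions the source does
not state.

## Synthetic data

- `build_ideal_chain` places N, CA, C, O and CB by natural-extension
  (NeRF) internal coordinates with fixed ideal values (N–CA 1.458 Å,
  CA–C 1.525 Å, C–N 1.329 Å, C–O 1.231 Å, CA–CB 1.521 Å; backbone
  angles 111.2/116.2/121.7°, ω = 180). The constants need only be
  internally consistent: the round-trip oracle compares torsions,
  which do not depend on them.
- `sample_rotor_records` draws a basin by weight, then an angle
  uniformly within it (the wrap basin on [150, 210) wrapped into
  range). It makes no claim about real rotamer statistics — no
  χ correlations, no SS-dependence — so tests passing on it validate
  the counting and energy machinery, not biological realism.
- `make_transition_cohort` draws wrapped-normal angles (default σ = 5°,
  n = 500 per offset) around prescribed per-offset modal angles.
  `reference_cohort_spec` provides canonical endpoint modes per
  transition, consistent with the reference sign rows and carrying the
  +80° φ shift (−140 → −60) for helix formation; intermediates
  interpolate along the minimal arc.

All generators are deterministic given (parameters, seed).

## Problem sizes and verification

The default test suite and the acceptance script run entirely on
synthetic data at small sizes chosen for statistical clarity: 100
random 20×(4×4) basin-count tables for the exact brute-force
equivalence of the energy→distance→score pipeline; 100 seeded cohorts
at n = 500 per offset for the ≥95% helix-formation sign-recovery rate;
12-residue chains for the geometry round trip. The full run takes
seconds on one core.

## Known limitations

- Dihedral-window SS assignment disagrees with hydrogen-bond-based
  assignments near element ends; flank statistics are sensitive to the
  window and minimum-length choices.
- Exact numeric reproduction of the published MIDMAT tables is out of
  reach (unavailable dataset and unstated conventions); the shipped
  copies serve as parse fixtures and plausibility anchors only.
- The sign analysis reduces a trajectory to a net arc; rotations of a
  full turn alias to 0 and are only visible in the reported modal
  trajectory.
- No BLAST benchmarking or alignment engine is included; matrices are
  exported in BLAST's format but their alignment utility is not
  evaluated here.
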