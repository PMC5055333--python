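# rotormat

Dihedral-rotor statistics of protein secondary structure, and the
MIDMAT family of substitution matrices derived from them.

## The problem

A folding polypeptide can be pictured as a machine with four rotors per
residue: the backbone torsions φ (C(i−1)–N–CA–C) and ψ (N–CA–C–N(i+1)),
and the first two side-chain torsions χ₁ (N–CA–CB–γ) and χ₂
(CA–CB–γ–δ). Which way these rotors turn as residues enter and leave
helices and sheets, and how strongly each amino acid prefers particular
angular regions, are quantifiable geometric signatures of structure
formation. `rotormat` is a toolkit for researchers in structural
bioinformatics who want to

- extract the four rotors per residue from PDB structures;
- classify residues into helix (H), sheet (S) and other (O) from
  configurable (φ, ψ) windows, and label the three flanking residues on
  either side of each element (H−3 … H+3, S−3 … S+3);
- coarse-grain rotor distributions onto 37×37 ten-degree grids and into
  four angular basins: [+150°, +180°] ∪ (−180°, −150°), [−150°, −50°),
  [−50°, +50°) and [+50°, +150°);
- convert basin occupancies into free energies
  ΔG*ᵢ* = −RT ln(*Nᵢ*/*Bᵢ*) (kJ/mol), with three variants of the
  reference *Bᵢ*: the sum of the remaining basins (MIDMAT1), their
  average (MIDMAT2), or the average over all four (MIDMAT3);
- measure rotor rotation directions (right-handed “+” = increasing
  dihedral) across element formation (offset −3 → 0) and breaking
  (0 → +3), and compare them with the reference sign patterns,
  including the χ₁/χ₂ counter-rotation relation;
- condense the 20 per-amino-acid energy profiles into substitution
  matrices: Euclidean distance over the 16 energy components,
  normalization by a common denominator, median centering
  SV*ₓᵧ* = 0.5 · (median(D) − D*ₓᵧ*), the self-score rule
  SV*ₓₓ* = max(SV) + max(SV row *x*), and integer rounding — written in
  BLAST's ASCII scoring-matrix format.

A synthetic-data module generates every input the pipeline needs: 3-D
chains built at prescribed φ/ψ by internal-coordinate placement,
per-amino-acid rotor samples drawn from prescribed basin weights, and
flank cohorts with prescribed modal shifts. The three published MIDMAT
reference matrices are shipped verbatim as parse/comparison fixtures.

## Worked example

```python
import rotormat as rm

spec = rm.reference_cohort_spec("H", "formation", n=500, sigma=5.0, seed=7)
report = rm.transition_signs(rm.make_transition_cohort(spec), "H", "formation")
for rotor in rm.ROTOR_NAMES:
    print(rotor, report.displacements[rotor], report.signs.rotor(rotor))
print(rm.match_pattern(report).all_match)
```

prints

```
phi 80.0 +
psi 160.0 +
chi1 -120.0 -
chi2 90.0 +
True
```

φ rotates +80° (right-handed) from the H−3 flank into the helix while
χ₁ counter-rotates left-handed and χ₂ counter-rotates against χ₁ — the
canonical helix-formation signature (+, +, −, +) for (φ, ψ, χ₁, χ₂).
The scripts in `examples/` walk through each capability the same way
(dihedral extraction, SS/flank labeling, basin energies, rotor signs,
matrix construction); each prints its numbers with a line on what they
mean. A thin CLI mirrors the library:

```sh
rotormat dihedrals structure.pdb -o table.tsv
rotormat assign table.tsv -o labels.tsv
rotormat basins table.tsv --variant MIDMAT3 -o energies.tsv
rotormat midmat energies.tsv -o MIDMAT3.mat --pad-blast
```

## Layout

- `src/rotormat/structure_io.py` — PDB parsing/writing, rotor extraction, dihedral TSV
- `src/rotormat/ss_position.py` — H/S/O windows, element segmentation, flank labels
- `src/rotormat/basin_stats.py` — 37×37 grids, basin histograms, basin energies
- `src/rotormat/rotor_analysis.py` — modal angles, transition signs, reference patterns
- `src/rotormat/midmat.py` — distances, substitution values, BLAST matrix I/O
- `src/rotormat/synthetic_data.py` — chain builder, basin sampler, transition cohorts
- `src/rotormat/data/` — shipped MIDMAT1/2/3 reference matrices
- `docs/methods.md` — models, conventions, parameter choices and limitations
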