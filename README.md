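# memjm

Quantitative structural analysis of membrane-protein transmembrane/
juxtamembrane (TM/JM) helix constructs, built for the kind of study done on
single-pass innate-immunity receptors (Toll-like receptors): an NMR or MD
conformer ensemble of a short two-helix peptide in a membrane mimetic, plus
chemical-shift and NOE peak tables describing its lipid and water contacts.

The package answers, reproducibly and with explicit conventions, the
questions such a study asks:

- **Where are the helices?** Sliding-window hydropathy (window mean of the
  Kyte–Doolittle index, frame = 4 residues ≈ one α-helix turn) locates the
  TM run and any separate hydrophobic JM patch; the Wimley–White
  interfacial scale (ΔG_wif, kcal/mol) scores a segment's preference for
  the lipid/water interface.
- **How are they arranged?** Per-conformer least-squares helix axes
  (principal direction of the phase-smoothed CA trace, directed N→C), the
  interhelical angle θ = arccos(a₁·a₂) ∈ [0°, 180°] reported as mean ±
  sample SD across conformers, and per-residue bend/kink tracks from local
  rotation-geometry axes.
- **How tight is the ensemble?** Average pairwise RMSD: every unordered
  conformer pair is superposed (Kabsch, proper rotation) on the selected
  atoms — backbone {N, CA, C} or heavy — of the selected segments, mean ±
  SD over the M(M−1)/2 pairs.
- **Which parts move together?** Internal mobility maps: the sample SD of
  every CA(i)–CA(j) distance across the ensemble (nm). Rigid domains are
  low-deviation diagonal blocks; a mobile hinge shows as a high
  inter-helix block.
- **What do the spectra say?** Chemical-shift perturbations
  CSP = √(ΔδH² + ΔδN²/10²) ppm, and NOE lipid/water contact profiles
  normalised to diagonal-peak intensities, with the overlap-exclusion rule
  for residues whose own (or preceding residue's) protons resonate inside
  the lipid CH₂ window (1.35–1.25 ppm).

A first-class synthetic-data module generates ideal helices, two-helix
hairpins at an exact inter-axis angle, Gaussian-noise ensembles, designed
hydrophobic/hydrophilic sequences, and shift/peak tables with planted
effects — so every analysis is testable end-to-end against known ground
truth, with no downloads.

## Worked example

```sh
python examples/ensemble_geometry.py
```

```
TM/JM angle: 80.5 +/- 0.6 deg (built at 80.0)
average pairwise RMSD: 0.68 +/- 0.04 A over 45 conformer pairs (expected ~ sqrt(6)*sigma = 0.73 A)
kink located at residue(s) [18], track maximum 30.1 deg (planted: 30 deg at residue 18)
```

A ten-conformer ensemble is built around an 80° two-helix hairpin with
0.3 Å coordinate noise and random per-conformer rigid motion. The
interhelical angle recovers the construction angle to half a degree; the
average pairwise heavy-atom RMSD sits at the √6·σ value expected for
i.i.d. coordinate noise; and the bend-angle track of a separately built
kinked helix locates and sizes the planted 30° kink. The other scripts in
`examples/` walk through hydropathy profiling, mobility maps and the
shift/NOE table analyses the same way.

## Command line

Each analysis is also exposed as a `memjm` subcommand writing TSV with a
provenance header (`profile`, `propensity`, `angle`, `rmsd`, `bend`,
`mobility`, `csp`, `contacts`, `simulate`, `validate`), e.g.

```sh
memjm simulate hairpin --angle 65 --out hp
memjm angle --pdb hp.pdb --helix1 1-18 --helix2 22-39
```

## Validating against deposited ensembles

`memjm validate --accession-dir DIR` consumes a directory of
user-downloaded multi-model PDB depositions of TLR TM/JM constructs
(8AR0 = TLR2, 8AR1 = TLR3, 8AR2 = TLR5, 8AR3 = TLR9; the tool never
downloads) and reports computed per-segment pairwise RMSDs and TM/JM
interhelical angles next to the published values with their spreads. The
acceptance test covering this comparison requires those files under
`data/depositions/` and fails with instructions when they are absent.

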