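# Methods

This note records the models, conventions and numerical choices behind
`memjm`, and what the synthetic fixtures do and do not establish about
real data.

## Data model

A conformer ensemble is M models over one shared atom table (chain,
residue number, residue name, atom name, element) with coordinates in Å.
Residue numbering is taken verbatim from the input file (UNIPROT-style
absolute numbering in the intended use); nothing is renumbered, so segment
ranges like 586–606 can be passed straight through. Deposited NMR
ensembles sometimes differ between models in terminal or altloc atoms, so
the reader intersects the per-model atom sets and warns about what it
drops, rather than failing. Alternate locations resolve to the
highest-occupancy variant (ties to the first listed). Multi-model PDB is
the only coordinate format; MD trajectories are expected to be converted
to multi-model PDB (and thinned) by the caller.

## Hydropathy profiling

The profile value at position *i* is the arithmetic mean of a per-residue
scale over residues [i, i+frame−1]. The default frame of 4 residues is
close to one α-helix turn, so the average cancels the periodic
polar/apolar alternation of an amphipathic helical face and tracks
segment-scale character. The default scale is Kyte–Doolittle
(dimensionless; positive = hydrophobic); the Wimley–White interfacial
scale (ΔG, kcal/mol, water → POPC interface; negative = favourable;
charged residues in their neutral-pH forms, His neutral) is shipped for
interface-propensity scoring. Windows are anchored at their first residue
by default — this keeps the left edge of the TM run aligned with the
sequence annotation — with centre anchoring available. Region annotation
labels maximal runs of windows strictly above a threshold (default 0.0
scale units, configurable) as hydrophobic. The threshold and scale behind
any particular published colouring are not knowable from a figure, so
only the qualitative pattern (a JM patch separated from the TM run, or
not) should be compared across implementations.

## Helix axes

The axis of a helical segment is fitted per conformer to the CA atoms by
total least squares: the first principal direction of the centred point
cloud, sign-fixed so the axis points from the segment's N-terminus to its
C-terminus. A subtlety motivates one refinement: the principal direction
of a *finite* ideal helix is biased away from the true cylinder axis by up
to ~2° depending on how the helical phase truncates (the second moments of
an incomplete turn are anisotropic). The fit is therefore applied to the
4-residue running centroids of the CA trace — points that lie essentially
on the axis — which removes the phase bias (≤0.3° for an 18-residue ideal
helix) while remaining a least-squares line fit of CA-derived positions.
Segments shorter than 6 residues fall back to the raw CA cloud. A
degenerate cloud (rank < 2 after centring) is an error.

Interhelical angles use the N→C directed axes, arccos of the dot product,
range [0°, 180°], averaged arithmetically across conformers with sample SD
(ddof = 1). Values of interest here (60–90°) are far from the 0°/180°
wrap, so circular statistics are unnecessary; this is a documented
limitation for near-parallel geometries. Whether published ensemble angles
were averaged per conformer or measured on a mean structure is often
unstated; per-conformer averaging is the default and the mean-structure
variant is exposed as a flag.

## Bend/kink profiles

At each position along a helix, two windows of `window` residues are
placed with their starts `offset` residues apart (defaults 7/7: adjacent
two-turn windows) and the angle between their local axes is anchored to
the straddled residue. For these short windows the PCA line fit is
unusable — its phase bias reaches 18° at 7 residues — so the local axis
uses rotation geometry instead: second differences of consecutive CA
positions (bisector vectors) are perpendicular to the helix axis, so their
pairwise cross products all point along it; their oriented sum is exact
for an ideal helix at any window length and degrades gracefully with
noise. Window pairs that cleanly straddle a kink read the full kink angle,
producing a ~2-position plateau; pairs partially covering the kink can
overshoot by a fraction of a degree because the contaminated axis tilts
slightly out of the kink plane. The kink locator therefore reports the
midpoint of the contiguous run within 1° of each local maximum (above a
10° floor), which in closed-loop tests recovers planted kink positions
within one residue and magnitudes within 0.5°.

## Superposition and pairwise RMSD

Rigid superposition is the closed-form optimal (Kabsch) solution with a
proper rotation enforced, computed via `scipy`'s rotation alignment after
centring; the test suite cross-checks it against an independent
grid-search-plus-refinement oracle on small point sets. The ensemble
spread statistic superposes every unordered conformer pair on the selected
atoms of the selected segments jointly and reports mean ± sample SD of the
pair RMSDs. "Backbone" means {N, CA, C} (the convention of the NMR
structure-calculation tools this mirrors); "heavy" means all
non-hydrogen atoms of the segment residues. Per-segment statistics are the
primary reporting unit; joint multi-segment superposition is supported and
its sensitivity to the segment choice is visible by simply passing
different ranges.

## Mobility maps

Entry (i, j) is the sample SD (ddof = 1) of the Euclidean CA(i)–CA(j)
distance across conformers, reported in nm (Å/10) to match the usual
colour-scale convention; Å output is a flag. Distances are invariant under
per-conformer rigid motion, so the map isolates internal rearrangement.
Rigid-domain extraction greedily grows maximal diagonal intervals whose
internal pairwise entries all sit below a cutoff (default 0.1 nm — an
exposed convention, not an asserted constant), tiling the diagonal left to
right.

## Shift and peak tables

CSP = √(ΔδH² + (ΔδN/10)²) in ppm; the factor 10 down-weights the ¹⁵N
dimension for the gyromagnetic-ratio difference between ¹H and ¹⁵N. Only
backbone amide H/N pairs are considered. NOE contact tracks divide each
residue's lipid-window (1.35–1.25 ppm) and water (4.6 ppm) cross-peak
intensity by its diagonal-peak intensity; classification thresholds for
surface-style colouring default to 0.05 on the normalised scale and are
configuration, not science. The overlap rule excludes residue *i* when any
proton of residue *i* or *i−1* resonates within the lipid window widened
by a margin (default 0.05 ppm; "close" is not a quantified notion, so the
margin is exposed).

## Synthetic fixtures

Ideal helices use textbook α-helix constants (rise 1.5 Å/residue, twist
100°/residue, CA radius 2.3 Å), stored as named configuration. Kinks
rotate everything downstream of a chosen residue about that residue's CA,
so the up/downstream construction axes subtend exactly the requested
angle. Hairpins place a second helix at an exact inter-axis angle with a
3-residue numbering gap and no modelled linker — the linker would blur the
axis ground truth. Gaussian ensembles add i.i.d. per-coordinate noise and,
optionally, per-conformer random rigid motion that no internal statistic
should detect. Backbone N/C atoms, when emitted, are placed by simple
internal coordinates along the chain trace; they exist for atom-set
plumbing only and are never angle ground truth. Table generators plant
CSPs as pure ¹H changes, contacts as exact fractions of the diagonal
intensity, and overlap offenders as methyl protons inside the lipid
window, so the analyses must reproduce the planted values exactly.

What these fixtures do not emulate: real side-chain packing, sequence-
dependent helix irregularity, spectral noise and peak overlap beyond the
planted cases, or the restraint-driven correlations of real NMR ensembles.
Passing closed-loop tests establishes the estimators' correctness and
bias, not the experimental error of any particular deposition; the
`validate` workflow against user-downloaded depositions covers that
separately.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale fixtures chosen
to exercise every code path with exact or closed-form expectations:
18–40-residue helices, ensembles of 2–10 conformers, angle sweeps over
{10°, 45°, 65°, 80°, 90°, 135°, 170°}, 20-seed noise replicates at
σ = 0.3 Å, and 1000 random sequences for the hydropathy brute-force check.
All randomness flows through explicit integer seeds; generators are pure
functions of (specification, seed).

## Known limitations

- Near-parallel interhelical angles inherit the [0°, 180°] arccos
  compression; no circular statistics.
- The bend profile needs `window + offset` residues of contiguous CA
  coverage; gaps in deposited numbering must be handled by splitting
  segments.
- mmCIF and binary trajectory formats are out of scope by design.
- The hydropathy scale/threshold behind any specific published figure is
  unknowable; only patterns, not per-window values, transfer.
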