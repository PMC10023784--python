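"""Chemical-shift perturbations and lipid/water NOE contact profiling on
tables with planted ground truth: a 0.2 ppm perturbation at one residue,
lipid contacts over the first half, and a methyl proton placed inside the
lipid CH2 window to trigger the overlap-exclusion rule."""

from memjm import PlantedEffects, contact_profile, csp, flag_overlaps, make_tables

residues = tuple(range(810, 830))
planted = PlantedEffects(
    residues,
    csp={820: 0.2},
    lipid={r: 0.25 for r in residues[:10]},
    water={810: 0.4, 829: 0.4},
    methyl_shifts={814: 1.30},  # inside the 1.25-1.35 ppm lipid window
)
ref, perturbed, peaks, assignments = make_tables(planted, seed=3)

prof = csp(ref, perturbed)
hits = [(int(r), round(float(v), 3)) for r, v in zip(prof.residues, prof.values) if v > 0.05]
print(f"CSP > 0.05 ppm at: {hits} (planted: 0.2 ppm at residue 820)")

excluded = flag_overlaps(assignments)  # residue 814 and its successor
print(f"overlap-excluded residues: {sorted(excluded)}")

contacts = contact_profile(peaks, exclusions=excluded)
lipid_res = [int(r) for r, c in zip(contacts.residues, contacts.classes) if c == "lipid"]
water_res = [int(r) for r, c in zip(contacts.residues, contacts.classes) if c in ("water", "both")]
print(f"lipid-contacting residues: {lipid_res}")
print(f"water-exposed residues:    {water_res}")
print("-> the planted lipid block is recovered minus the excluded residues;"
      " termini show water exchange")
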