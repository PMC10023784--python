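"""Locate the TM run and the juxtamembrane hydrophobic patch of a
single-pass receptor construct with a 4-residue moving-average hydropathy
profile, then score the JM patch on the Wimley-White interface scale."""

from memjm import (
    annotate_regions,
    interface_propensity,
    make_tlr_like_sequence,
    window_hydropathy,
)

seq = make_tlr_like_sequence("separated", start_number=581)
print(f"construct {seq.name}: residues {seq.start_number}-{seq.end_number}")

profile = window_hydropathy(seq, scale="kd", frame=4)
regions = annotate_regions(profile, threshold=0.0)
for start, end, label, covered in regions.segments:
    print(f"  windows {start}-{end}  {label:<12} ({covered} residues covered)")

hydrophobic = regions.hydrophobic()
print(f"hydrophobic runs: {len(hydrophobic)} -> TM helix plus a separate JM patch"
      if len(hydrophobic) >= 2 else "single contiguous hydrophobic span")

# the JM patch is the last hydrophobic run; is it interface-seeking?
jm_start, jm_end = hydrophobic[-1]
ip = interface_propensity(seq, (jm_start, jm_end + profile.frame - 1))
print(f"JM patch {jm_start}-{jm_end + profile.frame - 1}: "
      f"mean interface dG = {ip.mean:.2f} kcal/mol "
      f"({'favours' if ip.mean < 0 else 'disfavours'} the lipid/water interface)")
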