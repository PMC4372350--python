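"""Compute the eight per-residue observation channels for one peptide.

Each channel summarizes one physicochemical view: the residue itself,
secondary structure (H/E/C), conserved-domain membership, gapless-alignment
coverage against a core database, bactericidal-propensity stretches,
aggregation hot spots, trailing-window net charge, and amphipathic
(high hydrophobic moment) windows.
"""

from ampcore import FeatureResources, featurize, hydrophobic_moment, load_scale, net_charge

seq = "GIGKFLHSAKKFGKAFVGEIMNS"
resources = FeatureResources(core_db=[("magainin_core", "GIGKFLHSAKKFGKAFVG")])
tracks = featurize(seq, "magainin2", resources=resources)

print(f"{'pos':>3} " + " ".join(f"{c:>11}" for c in tracks.channels))
for i in range(tracks.length):
    print(f"{i:>3} " + " ".join(f"{v:>11}" for v in tracks.column(i)))

scale = load_scale("eisenberg")
print(f"\nnet charge of the peptide: {net_charge(seq):+d}")
print(f"hydrophobic moment of the first 10-mer at 100 deg/residue: "
      f"{hydrophobic_moment(seq[:10], scale):.3f}")
print("(IN cells mark residues inside the channel's flagged segments)")
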