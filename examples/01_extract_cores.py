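"""Build nested families from a peptide pool and locate their cores.

A nested family groups peptides related by substring containment; its core
is the shortest member contained in every other member (7-40 residues).
The carrier (longest member) is labeled CRITICAL on the core interval.
"""

from ampcore import build_nested_families, determine_core, label_carrier
from ampcore.sequences import AminoAcidSequence

pool = [
    # a magainin-like peptide nested in two longer precursor fragments
    AminoAcidSequence("core_peptide", "GIGKFLHSAKKFGKAFVGEIMNS"),
    AminoAcidSequence("precursor_a", "EAGIGKFLHSAKKFGKAFVGEIMNSLD"),
    AminoAcidSequence("precursor_b", "SDEAGIGKFLHSAKKFGKAFVGEIMNSLDKE"),
    # an unrelated singleton stays an orphan
    AminoAcidSequence("unrelated", "WDTNEQSWDTNEQS"),
]

partition = build_nested_families(pool)
print(f"{len(partition.families)} family, {len(partition.orphans)} orphan(s)")

for family in partition.families:
    core = determine_core(family)
    labeled = label_carrier(family, core)
    print(f"family {family.family_id}: carrier {core.carrier_id}")
    print(f"  core {core.core_residues} at [{core.start}, {core.end})")
    tags = "".join("C" if l == "CRITICAL" else "." for l in labeled.labels)
    print(f"  {labeled.sequence.residues}")
    print(f"  {tags}   (C = critical residue)")
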