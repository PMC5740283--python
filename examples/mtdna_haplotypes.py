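"""Collapse mtDNA sequences into haplotypes, place them on an NJ tree,
and allocate a short internal fragment to a species."""

from hzfootprint.markers import (
    assign_haplotype_species,
    assign_internal_fragment,
    build_nj_tree,
    collapse_haplotypes,
)
from hzfootprint.core import SequenceSet
from hzfootprint.simulate import generate_mtdna_sequences

labels = {f"blue_{i}": "blue" for i in range(3)}
labels.update({f"green_{i}": "green" for i in range(3)})
seqs, haplos = generate_mtdna_sequences(labels, ("blue", "green", "outgroup"),
                                        length=658, seed=5)
# add an outgroup and a partially unreadable copy of a blue sequence
full = dict(seqs.sequences)
full["OUT"] = haplos["outgroup"]
full["query"] = "N" * 10 + haplos["blue"][10:]
S = SequenceSet(full)

H = collapse_haplotypes(S)
print(f"{len(S)} sequences collapse into {len(H)} haplotypes "
      f"(an N matches anything)")
for hid, hap in H.haplotypes.items():
    print(f"  {hid}: multiplicity {hap.multiplicity}")

tree, support = build_nj_tree(H.as_sequence_set(), ["OUT"], bootstrap_n=100, seed=0)
refs = {hid: ("blue" if hid.startswith("blue") else "green")
        for hid in H.ids if hid.startswith(("blue", "green"))}
assigned = assign_haplotype_species(H, refs, tree)
for hid, hap in assigned.haplotypes.items():
    print(f"  {hid} -> {hap.species}")

frag = haplos["blue"][100:210]
species = assign_internal_fragment(frag, assigned, (100, 210))
print(f"110 bp internal fragment allocated to: {species}")
# Fragments are assigned only when every trimmed haplotype they match
# belongs to one species, so short reads never get over-interpreted.
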