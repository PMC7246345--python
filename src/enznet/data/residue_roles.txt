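# Functional-residue role vocabulary (closed list).
# Roles describe the residue's contribution over the complete restoring
# transformation, so bidirectional roles (acid on one leg, base on the
# other) are first-class entries.
general_acid
general_base
general_acid_base
proton_shuttle
electrostatic_stabilizer
metal_ligand
nucleophile
electrophile
covalent_catalyst
hydrogen_bond_donor
hydrogen_bond_acceptor
oxyanion_stabilizer
substrate_binding
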