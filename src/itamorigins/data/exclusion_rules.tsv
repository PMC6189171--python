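rule	precedence	description
known_itam_receptor	1	protein is an established ITAM-bearing immune receptor or adaptor, so it cannot be the receptor-independent transducer sought
secreted	2	secreted or extracellular protein; its motif never faces the cytosolic kinases
nuclear_only	3	strictly nuclear localization; no access to the plasma membrane
no_membrane_binding	4	cytosolic protein with no known membrane-binding ability
itam_sterically_hindered	5	motif buried or spatially hindered in the folded structure or topology
poor_knockdown	6	gene could not be silenced efficiently, so its role is untestable
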