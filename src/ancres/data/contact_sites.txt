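# Ligand-contacting positions of the ancestral corticoid receptor LBD
# (1-based alignment sites whose side chains lie within contact distance
# of the bound steroid, annotated externally from crystal structures).
36
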