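# Functional regions of the S. frugiperda GH1 beta-glycosidase active site
# (mature-protein author numbering, chain A of PDB entry 5CG0).
CR: [97, 187, 329, 331, 399]
GBS: [39, 142, 186, 444, 451, 452]
ABS: [190, 194, 201, 371, 453]
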