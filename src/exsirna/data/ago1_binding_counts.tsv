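class	n_loci	n_bound
I	9	9
II	222	197
III	88	2
IV	5	0
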