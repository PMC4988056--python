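strain_id	OG1	OG2	OG3	OG4	OG5
I	1	2	4	0	2
J	1	4	2	2	2
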