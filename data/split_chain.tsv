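metabolite	R1	R2	R3
A	1	-1	0
B	0	1	-1
#reversible	0	1	0
#exchange	1	0	1
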