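#method	oracle
#K	inf
#seed	None
R1	R2	R3	aug:0	aug:1	aug:2
1.0	1.0	0.9999999999999997	1.0	1.0	0.9999999999999997
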