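name	window	start	end
HBR1	RWRCK	34	38
HBR2	RSRFR	73	77
HBR3	RPGRR	101	105
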