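HISLNPPR
RCTIAMRA
NYRWRC
SIRCPHNRTLNNC
RSRFRVP
PLLHCD
DLINP
PGAQN
NCTYADRPGRRFYV
DPRDSPRY
LDTTI
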