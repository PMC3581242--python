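protein	organism	accession	protein_identity_pct	motif_identity_pct	motif	note
RNase3	Homo sapiens		100	100	NYRWRCKNQN
RNase3	Pan troglodytes		97	100	NYRWRCKNQN
RNase3	Gorilla gorilla		97	100	NYRWRCKNQN
RNase3	Macaca fascicularis		88	80	NYQRRCKNQN
RNase3	Macaca nemestrina		88	80	NYQRRCKNQN
RNase3	Pongo pygmaeus		88	70	NYQRRCKDQN
RNase2	Homo sapiens		67	80	NYQRQCKNQN	printed-identity-not-positional
RNase2	Pan troglodytes		67	80	NYQRQCKNQN	printed-identity-not-positional
RNase2	Gorilla gorilla		69	80	NYQRQCKNQN	printed-identity-not-positional
RNase2	Macaca fascicularis		67	80	NYQRQCKNQN	printed-identity-not-positional
RNase2	Macaca nemestrina		66	80	NYQRQCKNQN	printed-identity-not-positional
RNase2	Pongo pygmaeus		68	70	NFQRRCKNQN
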