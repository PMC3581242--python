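protein	organism	accession	protein_identity_pct	motif_identity_pct	motif	note
RNase1	Homo sapiens	P07998	30	40	MTQGRCKPVN
RNase2	Homo sapiens	P10153	67	80	NYQRRCKNQN
RNase3	Homo sapiens	P12724	100	100	NYRWRCKNQN
RNase4	Homo sapiens	P34096	28	30	MTLYHCKRFN
RNase5	Homo sapiens	P03950	32	30	LTSP-CKDIN
RNase6	Homo sapiens	Q93061	43	20	KYFGRSLELY
RNase7	Homo sapiens	Q9H1E1	39	40	KHTKRCKDLN
RNase8	Homo sapiens	Q8TDE3	39	50	KYTERCKDLN
RNase9	Homo sapiens	P60153	23	20	YYKHRWVAEH
RNase10	Homo sapiens	Q5GAN6	26	10	EPSQSCIAQY	printed-identity-not-positional
RNase11	Homo sapiens	Q5GAN5	30	30	EANGSCKWSN
RNase12	Homo sapiens	Q5GAN4	23	20	EPDHTCKKEH
RNase13	Homo sapiens	Q5GAN3	25	10	MQNSDCPKIH
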