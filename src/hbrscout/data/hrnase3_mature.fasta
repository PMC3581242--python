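>P12724 human RNase3 (eosinophil cationic protein), mature chain, 133 aa
RPPQFTRAQWFAIQHISLNPPRCTIAMRAINNYRWRCKNQNTFLRTTFANVVNVCGNQSI
RCPHNRTLNNCHRSRFRVPLLHCDLINPGAQNISNCTYADRPGRRFYVVACDNRDPRDSP
RYPVVPVHLDTTI
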