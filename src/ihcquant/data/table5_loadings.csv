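marker,i_moy,i_sig,i_skw
Bim,0.6368,0.5765,-0.5120
Mcl-1,-0.5458,-0.5624,0.6211
P-ERK,0.7051,0.0384,-0.7081
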