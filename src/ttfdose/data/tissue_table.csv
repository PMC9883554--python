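label,sigma_S_per_m,eps_r
scalp,0.25,5000
skull,0.0211,204
gray_matter,0.141,2010
white_matter,0.0868,1290
csf,2.00,109
tumor_shell,0.24,2000
tumor_core,1.00,110
hydrogel,0.1,100
electrode,0,16000
air,0,1
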