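unit_id,exposure,sensitivity,adaptive_capacity,lvi_ipcc
AES1,0.78,0.30,0.21,0.72
AES2,0.30,1.26,0.73,-0.62
AES3,0.30,1.31,0.78,-0.72
AES4,0.60,0.94,0.45,0.18
AES5,0.76,0.21,0.25,0.71
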