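unit_id,area_km2
AES1,7200
AES2,3200
AES3,1600
AES4,1300
AES5,2400
AES6,250
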