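# Published per-unit summary rows used as report/check inputs.
sample_sizes: {AES1: 87, AES2: 183, AES3: 148, AES4: 284, AES5: 91}
temperature_increasing_pct: {AES1: 95.2, AES2: 78.3, AES3: 94.6, AES4: 79.6, AES5: 80.2}
precipitation_decreasing_pct: {AES1: 65.5, AES2: 56.0, AES3: 54.7, AES4: 69.9, AES5: 60.4}
land_holding_ha: {AES1: 1.0, AES2: 0.97, AES3: 1.23, AES4: 1.28, AES5: 1.1}
tlu_per_household: {AES1: 1.26, AES2: 1.56, AES3: 1.13, AES4: 2.16, AES5: 1.45}
gender_counts: {male: 737, total: 790}
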