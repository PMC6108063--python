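unit_id,indicator_id,value
AES1,temp_trend,0.32
AES2,temp_trend,0.27
AES3,temp_trend,0.28
AES4,temp_trend,0.29
AES5,temp_trend,0.31
AES1,precip_trend,40
AES2,precip_trend,20
AES3,precip_trend,25
AES4,precip_trend,30
AES5,precip_trend,45
AES1,extreme_events,7
AES2,extreme_events,4
AES3,extreme_events,5
AES4,extreme_events,6
AES5,extreme_events,8
AES1,land_suitability,2.0
AES2,land_suitability,4.2
AES3,land_suitability,4.0
AES4,land_suitability,3.0
AES5,land_suitability,1.8
AES1,land_use_sustainability,1.5
AES2,land_use_sustainability,2.5
AES3,land_use_sustainability,2.4
AES4,land_use_sustainability,2.0
AES5,land_use_sustainability,1.4
AES1,land_cover_change,-15
AES2,land_cover_change,-5
AES3,land_cover_change,-6
AES4,land_cover_change,-10
AES5,land_cover_change,-18
AES1,irrigation_potential_eco,120
AES2,irrigation_potential_eco,300
AES3,irrigation_potential_eco,380
AES4,irrigation_potential_eco,260
AES5,irrigation_potential_eco,90
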