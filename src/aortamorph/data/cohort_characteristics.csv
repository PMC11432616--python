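patient,age,sex,pathology_code,stent_type,stent_number,fu_days,proximal_landing_zone,landing_zone_distance_mm,stent_coverage_length_mm,lv_mass_pre_g_m2,lv_mass_post_g_m2
1,73,F,DTAA,Gore,1,511,4,160.31,132.3,82,80
2,68,M,DTAA,Gore,1,380,3,171.06,101.0,56,60
3,65,F,TBAD,Bolton,2,518,2,78.07,303.0,76,64
4,72,M,AAA,Najuta,1,413,0,74.04,169.0,48,54
5,72,F,DTAA,Najuta-Gore,4,382,0,85.03,383.0,58,
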