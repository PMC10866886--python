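name,habit,tbase,tupp,gdd_maturity,cc0,ccx,cgc,cdc,zmin,zmax,kcb,wp_star,hi0,p_up,irrigation_threshold,tcrit_heat,wc,co2_response,cc_min_leafless,budbreak_gdd,is_rice,shallow_soil
wheat,annual,0.0,26.0,1700.0,0.05,0.96,0.006,0.004,0.30,1.50,1.10,0.150,0.48,0.55,0.40,32.0,0.13,0.158,0.0,0.0,False,False
maize,annual,8.0,30.0,1500.0,0.05,0.96,0.007,0.005,0.30,1.70,1.05,0.320,0.50,0.65,0.50,35.0,0.13,0.032,0.0,0.0,False,False
rice,annual,8.0,30.0,1400.0,0.05,0.95,0.007,0.005,0.30,0.60,1.10,0.190,0.43,0.30,0.30,35.0,0.13,0.158,0.0,0.0,True,True
grape,deciduous_perennial,5.0,28.0,1300.0,0.10,0.75,0.005,0.003,1.50,1.50,0.85,0.150,0.45,0.45,0.35,40.0,0.80,0.158,0.05,120.0,False,False
citrus,evergreen_perennial,10.0,32.0,1000.0,0.30,0.70,0.004,0.002,1.20,1.20,0.75,0.170,0.35,0.50,0.35,40.0,0.85,0.158,0.0,0.0,False,False
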