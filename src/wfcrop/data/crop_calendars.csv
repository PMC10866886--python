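crop,season,planting_doy,harvest_doy
wheat,1,105,250
maize,1,120,260
rice,1,125,245
rice,2,250,360
grape,1,100,290
citrus,1,1,365
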