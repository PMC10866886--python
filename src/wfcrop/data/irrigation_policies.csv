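crop,method,trigger_depletion,rice_flooding
wheat,sprinkler,0.40,False
maize,surface,0.50,False
rice,surface,0.30,True
grape,drip,0.35,False
citrus,drip,0.35,False
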