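module_type,target_contrast_hu,resin_pct,additive,additive_pct
contrast_agent,16,99.82,NaI solution,0.18
contrast_agent,32,99.60,NaI solution,0.40
contrast_agent,48,99.39,NaI solution,0.61
contrast_agent,64,99.17,NaI solution,0.83
contrast_agent,80,98.96,NaI solution,1.04
native,16,95.60,sucrose,4.40
native,32,91.11,sucrose,8.89
native,48,86.60,sucrose,13.40
native,64,82.10,sucrose,17.90
native,80,77.61,sucrose,22.39
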