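observer_id,diameter_mm,delta_min_hu,module_type,kv,ctdi_vol_mgy,scan_id,date
observer1,3,64,contrast_agent,120,9,REF01,2021-06-01
observer1,4,48,contrast_agent,120,9,REF01,2021-06-01
observer1,5,32,contrast_agent,120,9,REF01,2021-06-01
observer1,6,32,contrast_agent,120,9,REF01,2021-06-01
observer1,8,32,contrast_agent,120,9,REF01,2021-06-01
observer1,9,48,contrast_agent,120,9,REF01,2021-06-01
observer2,3,,contrast_agent,120,9,REF01,2021-06-01
observer2,4,80,contrast_agent,120,9,REF01,2021-06-01
observer2,5,80,contrast_agent,120,9,REF01,2021-06-01
observer2,6,80,contrast_agent,120,9,REF01,2021-06-01
observer2,8,48,contrast_agent,120,9,REF01,2021-06-01
observer2,9,48,contrast_agent,120,9,REF01,2021-06-01
observer3,3,,contrast_agent,120,9,REF01,2021-06-01
observer3,4,80,contrast_agent,120,9,REF01,2021-06-01
observer3,5,64,contrast_agent,120,9,REF01,2021-06-01
observer3,6,80,contrast_agent,120,9,REF01,2021-06-01
observer3,8,48,contrast_agent,120,9,REF01,2021-06-01
observer3,9,48,contrast_agent,120,9,REF01,2021-06-01
observer4,3,64,contrast_agent,120,9,REF01,2021-06-01
observer4,4,80,contrast_agent,120,9,REF01,2021-06-01
observer4,5,80,contrast_agent,120,9,REF01,2021-06-01
observer4,6,48,contrast_agent,120,9,REF01,2021-06-01
observer4,8,48,contrast_agent,120,9,REF01,2021-06-01
observer4,9,48,contrast_agent,120,9,REF01,2021-06-01
observer5,3,,contrast_agent,120,9,REF01,2021-06-01
observer5,4,80,contrast_agent,120,9,REF01,2021-06-01
observer5,5,64,contrast_agent,120,9,REF01,2021-06-01
observer5,6,48,contrast_agent,120,9,REF01,2021-06-01
observer5,8,48,contrast_agent,120,9,REF01,2021-06-01
observer5,9,48,contrast_agent,120,9,REF01,2021-06-01
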