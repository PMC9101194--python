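item_id,mean,sd,pf_star
cardio,590.6,1.838,4.03
situps,37.8,0.789,6.09
jump,192,1.160,6.04
flex,18.59,0.099,5.93
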