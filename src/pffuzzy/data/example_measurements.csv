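item_id,value
cardio,589
cardio,593
cardio,590
cardio,591
cardio,589
cardio,590
cardio,589
cardio,589
cardio,592
cardio,594
situps,39
situps,38
situps,37
situps,38
situps,37
situps,39
situps,38
situps,37
situps,37
situps,38
jump,191
jump,190
jump,191
jump,190
jump,191
jump,189
jump,188
jump,192
jump,191
jump,190
flex,18.5
flex,18.6
flex,18.4
flex,18.7
flex,18.6
flex,18.5
flex,18.6
flex,18.7
flex,18.6
flex,18.9
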