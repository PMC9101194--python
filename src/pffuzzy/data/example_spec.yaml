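# Specification for the four-item worked example: an 18-year-old male
# student tested against Taiwan's physical-fitness norms.
defaults:
  k: 6.0
  alpha: 0.05
  phi1: 0.4
  phi2: 0.8
items:
  cardio:
    name: Cardiorespiratory endurance (1600 m run/walk, s)
    orientation: smaller_better
    limit: 598
  situps:
    name: Muscular endurance (sit-ups per minute)
    orientation: larger_better
    limit: 33
  jump:
    name: Muscular power (standing long jump, cm)
    orientation: larger_better
    limit: 185
  flex:
    name: Flexibility (seated forward flexion, cm)
    orientation: larger_better
    limit: 18
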