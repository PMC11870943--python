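# Rat (345 g) physiology — RECONSTRUCTED preset.
# Body weight and cardiac output are the study values (0.345 kg, 6.624 L/h);
# organ volumes and flows are reconstructed from standard rodent reference
# compilations (fractional organ weights and fractional cardiac output) and
# are not measured values for this model. Lung carries the full cardiac
# output as a parallel perfused compartment, mirroring the mouse layout.
species: rat
body_weight: 0.345       # kg
cardiac_output: 6.624    # L/h
plasma_volume: 0.0125    # L
organs:
  - {name: brain,     volume: 0.0020,  flow: 0.132}
  - {name: bone,      volume: 0.0250,  flow: 0.331}
  - {name: fat,       volume: 0.0240,  flow: 0.464}
  - {name: gut,       volume: 0.0110,  flow: 0.868, drains_to: liver}
  - {name: heart,     volume: 0.0012,  flow: 0.325}
  - {name: kidney,    volume: 0.0025,  flow: 0.934}
  - {name: liver,     volume: 0.0127,  flow: 0.139}
  - {name: lung,      volume: 0.0017,  flow: 6.624}
  - {name: muscle,    volume: 0.1400,  flow: 1.840}
  - {name: skin,      volume: 0.0660,  flow: 0.384}
  - {name: spleen,    volume: 0.0008,  flow: 0.066, drains_to: liver}
  - {name: remainder, volume: 0.0456,  flow: 0.331}
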