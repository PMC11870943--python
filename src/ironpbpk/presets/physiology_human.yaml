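# Human (73 kg adult) physiology — RECONSTRUCTED preset.
# Body weight and cardiac output are the study values (73 kg, 336 L/h);
# organ volumes and flows are reconstructed from standard adult reference
# compilations (fractional organ weights and fractional cardiac output).
# Lung carries the full cardiac output as a parallel perfused compartment.
# A 70 kg alternate body weight can be set by editing body_weight.
species: human
body_weight: 73.0        # kg
cardiac_output: 336.0    # L/h
plasma_volume: 3.0       # L
organs:
  - {name: brain,     volume: 1.45,  flow: 38.3}
  - {name: bone,      volume: 10.5,  flow: 16.8}
  - {name: fat,       volume: 15.6,  flow: 17.5}
  - {name: gut,       volume: 1.70,  flow: 50.4, drains_to: liver}
  - {name: heart,     volume: 0.33,  flow: 13.4}
  - {name: kidney,    volume: 0.31,  flow: 58.8}
  - {name: liver,     volume: 1.80,  flow: 21.8}
  - {name: lung,      volume: 0.53,  flow: 336.0}
  - {name: muscle,    volume: 29.2,  flow: 57.1}
  - {name: skin,      volume: 2.70,  flow: 19.5}
  - {name: spleen,    volume: 0.18,  flow: 6.7, drains_to: liver}
  - {name: remainder, volume: 5.70,  flow: 16.8}
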