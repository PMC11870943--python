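# Mouse (25 g) physiology for the whole-body iron model.
# Organ volumes in L, plasma flows in L/h. Cardiac output is metadata only:
# mass balance closes over the per-organ flows.
species: mouse
body_weight: 0.025        # kg
cardiac_output: 0.72      # L/h (literature value for 20 g, scaled linearly to 25 g)
plasma_volume: 0.00109    # L
organs:
  - {name: brain,     volume: 0.00042,  flow: 0.034}
  - {name: bone,      volume: 0.00350,  flow: 0.042}
  - {name: fat,       volume: 0.00216,  flow: 0.073}
  - {name: gut,       volume: 0.00106,  flow: 0.146, drains_to: liver}
  - {name: heart,     volume: 0.000125, flow: 0.068}
  - {name: kidney,    volume: 0.00042,  flow: 0.094}
  - {name: liver,     volume: 0.001375, flow: 0.167}
  - {name: lung,      volume: 0.00018,  flow: 1.04}
  - {name: muscle,    volume: 0.00958,  flow: 0.165}
  - {name: skin,      volume: 0.004125, flow: 0.06}
  - {name: spleen,    volume: 0.000092, flow: 0.012, drains_to: liver}
  - {name: remainder, volume: 0.008473, flow: 0.176}
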