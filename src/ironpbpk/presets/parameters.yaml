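# Named kinetic parameter presets.
# Mouse presets: naive-pooled estimates for the three diet states
# (KP dimensionless; cl_loss and q_e in L/h; t_rbc in h).
# rat_ida: iron-deficient-anemia rat under ferric carboxymaltose; KP for the
# six experimentally observed tissues are rat estimates, the rest (and
# cl_loss) are inherited from the mouse iron-deficient column; q_e/t_rbc are
# lifespan-scaled package defaults (see interspecies module).
mouse_iron_deficient:
  cl_loss: 0.124e-4
  q_e: 0.434e-3
  t_rbc: 41.53
  kp:
    brain: 1.075
    bone: 3.635
    fat: 0.186
    gut: 5.213
    heart: 10.08
    kidney: 6.541
    liver: 9.38
    lung: 17.86
    muscle: 1.288
    skin: 0.101
    spleen: 10.13
    remainder: 4.93
mouse_iron_adequate:
  cl_loss: 1.647e-4
  q_e: 0.217e-3
  t_rbc: 34.44
  kp:
    brain: 1.087
    bone: 7.703
    fat: 0.258
    gut: 5.349
    heart: 13.83
    kidney: 9.223
    liver: 18.11
    lung: 13.7
    muscle: 1.764
    skin: 4.651
    spleen: 16.34
    remainder: 2.30e-9
mouse_iron_loaded:
  cl_loss: 1.184e-4
  q_e: 0.0388e-3
  t_rbc: 197.6
  kp:
    brain: 0.9304
    bone: 7.753
    fat: 0.328
    gut: 6.979
    heart: 25.88
    kidney: 29.06
    liver: 38.53
    lung: 45.24
    muscle: 2.394
    skin: 4.252
    spleen: 23.93
    remainder: 3.06e-8
rat_ida:
  cl_loss: 0.124e-4
  q_e: 6.202e-3      # mouse iron-deficient q_e scaled by (1440/41.53)^0.75
  t_rbc: 1440.0      # 60 d rat RBC lifespan (package default)
  kp:
    brain: 1.075
    bone: 8.64
    fat: 0.186
    gut: 5.213
    heart: 17.64
    kidney: 6.41
    liver: 59.4
    lung: 17.86
    muscle: 2.28
    skin: 0.101
    spleen: 147.9
    remainder: 4.93
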