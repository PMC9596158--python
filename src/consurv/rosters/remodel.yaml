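# Single-model roster: the ten families fitted directly on a fixed gene set
# (no selector), elastic net expanded over its alpha grid.
version: 1
name: remodel
combinations:
  - "RSF"
  - "LASSO"
  - "GBM"
  - "SurvSVM"
  - "SuperPC"
  - "Ridge"
  - "plsRcox"
  - "CoxBoost"
  - "StepCox[both]"
  - "Enet[a=0.1]"
  - "Enet[a=0.2]"
  - "Enet[a=0.3]"
  - "Enet[a=0.4]"
  - "Enet[a=0.5]"
  - "Enet[a=0.6]"
  - "Enet[a=0.7]"
  - "Enet[a=0.8]"
  - "Enet[a=0.9]"
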