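# Default combination roster: every dimension-reduction-capable family
# (RSF, LASSO, CoxBoost, StepCox) feeds each pure modeling family, and every
# family also runs standalone; StepCox directions and Enet alpha values are
# enumerated as variants, with bidirectional search as the stepwise selector.
version: 1
name: default
combinations:
  - "RSF"
  - "LASSO"
  - "CoxBoost"
  - "StepCox[both]"
  - "StepCox[backward]"
  - "StepCox[forward]"
  - "GBM"
  - "SurvSVM"
  - "SuperPC"
  - "Ridge"
  - "plsRcox"
  - "Enet[a=0.1]"
  - "Enet[a=0.2]"
  - "Enet[a=0.3]"
  - "Enet[a=0.4]"
  - "Enet[a=0.5]"
  - "Enet[a=0.6]"
  - "Enet[a=0.7]"
  - "Enet[a=0.8]"
  - "Enet[a=0.9]"
  - "CoxBoost + GBM"
  - "CoxBoost + SurvSVM"
  - "CoxBoost + SuperPC"
  - "CoxBoost + Ridge"
  - "CoxBoost + plsRcox"
  - "CoxBoost + Enet[a=0.1]"
  - "CoxBoost + Enet[a=0.2]"
  - "CoxBoost + Enet[a=0.3]"
  - "CoxBoost + Enet[a=0.4]"
  - "CoxBoost + Enet[a=0.5]"
  - "CoxBoost + Enet[a=0.6]"
  - "CoxBoost + Enet[a=0.7]"
  - "CoxBoost + Enet[a=0.8]"
  - "CoxBoost + Enet[a=0.9]"
  - "LASSO + GBM"
  - "LASSO + SurvSVM"
  - "LASSO + SuperPC"
  - "LASSO + Ridge"
  - "LASSO + plsRcox"
  - "LASSO + Enet[a=0.1]"
  - "LASSO + Enet[a=0.2]"
  - "LASSO + Enet[a=0.3]"
  - "LASSO + Enet[a=0.4]"
  - "LASSO + Enet[a=0.5]"
  - "LASSO + Enet[a=0.6]"
  - "LASSO + Enet[a=0.7]"
  - "LASSO + Enet[a=0.8]"
  - "LASSO + Enet[a=0.9]"
  - "RSF + GBM"
  - "RSF + SurvSVM"
  - "RSF + SuperPC"
  - "RSF + Ridge"
  - "RSF + plsRcox"
  - "RSF + Enet[a=0.1]"
  - "RSF + Enet[a=0.2]"
  - "RSF + Enet[a=0.3]"
  - "RSF + Enet[a=0.4]"
  - "RSF + Enet[a=0.5]"
  - "RSF + Enet[a=0.6]"
  - "RSF + Enet[a=0.7]"
  - "RSF + Enet[a=0.8]"
  - "RSF + Enet[a=0.9]"
  - "StepCox[both] + GBM"
  - "StepCox[both] + SurvSVM"
  - "StepCox[both] + SuperPC"
  - "StepCox[both] + Ridge"
  - "StepCox[both] + plsRcox"
  - "StepCox[both] + Enet[a=0.1]"
  - "StepCox[both] + Enet[a=0.2]"
  - "StepCox[both] + Enet[a=0.3]"
  - "StepCox[both] + Enet[a=0.4]"
  - "StepCox[both] + Enet[a=0.5]"
  - "StepCox[both] + Enet[a=0.6]"
  - "StepCox[both] + Enet[a=0.7]"
  - "StepCox[both] + Enet[a=0.8]"
  - "StepCox[both] + Enet[a=0.9]"
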