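time_scale: 1.0
variant_tag: full
inputs:
  PD: 0.0
  Chiron: 0.0
variant_params:
  two_i_unreduced_input: 3.6
  nanog_bcat:
    s: 0.15
    K: 0.5
    n: 1.0
  reduced_core:
    erk_K: 4.46
  autoinhibition_bcat:
    s4: 0.041
    K4: 0.15
    n4: 2.0
    nb_s: 0.5
    nb_K: 0.18
    nb_n: 4.0
    bt_K: 0.3
    bt_strength: 50.0
    bt_n: 4.0
    tn_K: 0.1
    tn_n: 2.0
  autoinhibition_rest:
    s4: 0.03
    K4: 0.3
    n4: 2.0
    s6: 0.4
    K6: 0.37
    n6: 6.0
    nr_s: 0.3
    nr_K: 0.3
    nr_n: 6.0
species:
  OS:
    initial: 0.93
    noise: 0.01
    basal: 0.083818
    terms:
    - regulator: OS
      mode: activation
      s: 1.0
      K: 0.4
      n: 2
    - regulator: REST
      mode: activation
      s: 0.005
      K: 0.3
      n: 1
    degradation:
      rate: 1.0
  NANOG:
    initial: 1.0
    noise: 0.16
    terms:
    - regulator: OS
      mode: activation
      s: 0.261
      K: 0.5
      n: 2
      modifiers:
      - source: TCF3
        K: 2.07
        n: 1
    - regulator: NANOG
      mode: activation
      s: 1.79
      K: 1.0
      n: 2
      modifiers:
      - source: FGF_ERK
        K: 3.09
        n: 2
        attenuators:
        - source: PD
          K: 3.0
        - source: PRDM14
          K: 1.0
    - regulator: REST
      mode: activation
      s: 0.00125
      K: 0.3
      n: 1
    degradation:
      rate: 1.0
    basal: 0.001704
  MYCN:
    initial: 0.5
    noise: 0.02
    terms:
    - regulator: NANOG
      mode: repression
      s: 0.4
      K: 0.5
      n: 1
    - regulator: MYCN
      mode: repression
      s: 0.3
      K: 0.5
      n: 1
    - regulator: BCAT
      mode: repression
      s: 0.3
      K: 0.5
      n: 1
    degradation:
      rate: 1.0
  REST:
    initial: 0.3
    noise: 0.02
    terms:
    - regulator: NANOG
      mode: activation
      s: 0.1
      K: 0.3
      n: 1
    - regulator: BCAT
      mode: repression
      s: 0.3
      K: 0.3
      n: 1
    degradation:
      rate: 1.0
  PRDM14:
    initial: 0.6
    noise: 0.02
    terms:
    - regulator: OS
      mode: repression
      s: 0.1
      K: 0.5
      n: 1
    - regulator: NANOG
      mode: activation
      s: 0.5
      K: 0.5
      n: 1
    - regulator: MYCN
      mode: activation
      s: 0.35
      K: 0.3
      n: 1
    degradation:
      rate: 1.0
  FGF_ERK:
    initial: 0.96
    noise: 0.5
    terms:
    - regulator: OS
      mode: activation
      s: 1.5
      K: 0.5
      n: 1
    degradation:
      rate: 1.0
  BCAT:
    initial: 0.1
    noise: 0.02
    basal: 0.1
    degradation:
      rate: 1.0
      modulators:
      - source: Chiron
        direction: down
        K: 0.5
        strength: 0.95
        n: 1
  TCF3:
    initial: 0.87
    noise: 0.02
    basal: 1.0
    degradation:
      rate: 1.0
      modulators:
      - source: BCAT
        direction: up
        K: 4.0
        strength: 4.5
        n: 1
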