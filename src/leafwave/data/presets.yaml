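# Frozen stress-archetype presets: local-waveform kinetics (µM, min),
# H2O2 front speed (cm/min) and SA source onset (min) / diffusion (cm^2/min).
# One-time fixtures; see docs/methods.md.
wounding:
  wave_speed: 0.19
  kinetics:
    k: 0.01292
    kd: 0.171416
    kf1: 0.0
    kf_chain:
    - 0.05
    - 0.05
    ks: 0.05
    ki: 0.0
    kr: 0.0
    n_intermediates: 3
    a0: 0.013594
    p0: 38.059452
    pf0: 0.0
    pi0: 0.0
    t_stress: 10.0
xcc:
  wave_speed: 0.2
  sa_onset: 70.0
  sa_diffusion: 0.032646
  kinetics:
    k: 0.004491
    kd: 0.136003
    kf1: 0.002
    kf_chain:
    - 0.016679
    - 0.016679
    ks: 0.016679
    ki: 0.004
    kr: 0.1
    n_intermediates: 3
    a0: 0.299212
    p0: 70.237422
    pf0: 8.0
    pi0: 4.0
    t_stress: 10.0
light:
  wave_speed: 0.08
  sa_onset: 22.0
  sa_diffusion: 0.028155
  kinetics:
    k: 0.003666
    kd: 0.158895
    kf1: 0.002
    kf_chain:
    - 0.191501
    - 0.191501
    ks: 0.191501
    ki: 0.0
    kr: 0.0
    n_intermediates: 3
    a0: 1.297709
    p0: 83.533345
    pf0: 8.0
    pi0: 0.0
    t_stress: 10.0
    t2: 130.0
    p2: 29.23667075667588
heat:
  wave_speed: 1.2
  sa_onset: 28.0
  sa_diffusion: 0.008564
  kinetics:
    k: 0.016683
    kd: 0.024068
    kf1: 0.002
    kf_chain:
    - 0.082569
    - 0.082569
    ks: 0.082569
    ki: 0.0
    kr: 0.0
    n_intermediates: 3
    a0: 0.401438
    p0: 26.141221
    pf0: 8.0
    pi0: 0.0
    t_stress: 10.0
    t2: 100.0
    p2: 9.149427342300148
'null': {}
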