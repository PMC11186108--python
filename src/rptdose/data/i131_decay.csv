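particle,energy_keV,yield_per_decay
gamma,80.185,0.0262
gamma,284.305,0.0614
gamma,325.789,0.00274
gamma,364.489,0.815
gamma,502.991,0.00360
gamma,636.989,0.0717
gamma,722.911,0.0177
beta_mean,191.6,1.0
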