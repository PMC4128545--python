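# Baseline parameterization of the phage competition model.
# Units: rates per minute; adsorption_rate in mL/min; densities per mL.
adsorption_rate = 1e-09
washout_rate = 0.05
burst_gm = 17.0
burst_wild = 20.0
lysis_time = 10.0
max_growth_rate = 0.1
enzyme_yield = 0.1
carrying_capacity = 5e+09
release_max = 0.2
release_shape = 19.0
release_decay = 0.999997
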