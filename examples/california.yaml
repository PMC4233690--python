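# California-style experiment: 25 years, scenarios seeded at the mid-1980s
# incarceration rates (1% Black, 0.15% White).
experiment: california
n_replicates: 50
base_seed: 1
out_dir: results/california
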