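# 50-year differential-sentencing experiment at the packaged defaults,
# scaled to 50 replicates for a desk-scale run.
experiment: fifty_year
n_replicates: 50
horizon: 600
base_seed: 1
out_dir: results/fifty_year
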