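# One co-evolutionary run: altruism + density-dependent dispersal norm.
schema_version: 1
n: 2
c: 0.2
k: 10
benefit: 0.1
cost: 0.04
baseline: 0.8
num_patches: 500
generations: 5000
burn_in: 2000
mutation_prob: 0.01
mutation_sd: 0.03
P_lo: 0.8
P_hi: 1.2
seed: 7
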