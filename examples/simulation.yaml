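# Synthetic data set: 200 lines x 3 environments, 500 markers,
# two correlated continuous traits plus discretized binary/ordinal traits.
n_lines: 200
n_environments: 3
n_markers: 500
maf_range: [0.05, 0.5]
gxe_variance_ratio: 0.1
env_effect_scale: 0.5
observed_fraction: 0.8          # unbalanced trial: 80% of cells observed
seed: 1
genetic_correlation:
  - [1.0, 0.6, 0.6, 0.6]
  - [0.6, 1.0, 0.6, 0.6]
  - [0.6, 0.6, 1.0, 0.6]
  - [0.6, 0.6, 0.6, 1.0]
traits:
  - name: GY
    kind: continuous
    heritability: 0.6
  - name: Height
    kind: binary
    heritability: 0.6
    quantile_cuts: [0.5]
  - name: DTHD
    kind: ordinal
    heritability: 0.6
    quantile_cuts: [0.3333, 0.6667]
  - name: DTMT
    kind: ordinal
    heritability: 0.6
    quantile_cuts: [0.20, 0.45, 0.70, 0.90]
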