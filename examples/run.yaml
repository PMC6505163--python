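# Multi-trait network with G-by-E features, fivefold CV2, reduced grid.
model: mtdlmp          # or udl (one single-output network per trait)
interaction: I         # I = with G-by-E block, WI = without
layers: 1              # 1, 2 or 3 hidden layers
folds: 5
inner_validation_fraction: 0.2
dropout_rate: 0.3
learning_rate: 0.001
batch_size: 32
seed: 1
grid:
  preset: reduced      # 'full' = epochs 1..100, units 10..490 step 20
qc:
  apply: false         # simulated Hardy-Weinberg data: skip the inbred QC
traits:
  - name: GY
    kind: continuous
  - name: Height
    kind: binary
  - name: DTHD
    kind: ordinal
    n_categories: 3
  - name: DTMT
    kind: ordinal
    n_categories: 5
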