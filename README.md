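# gpmix

Genomic prediction of **mixed phenotypes** — continuous, binary and ordinal
traits — with multi-output dense neural networks, genomic-relationship
features and genotype-by-environment (G×E) interaction terms.

## What it does

- **Genomic features.** Builds the VanRaden genomic relationship matrix `G`
  from 0/1/2 marker dosages (after missingness / MAF / heterozygosity QC and
  mode imputation), factors it as `G = Qᵀ Q` (upper Cholesky), and assembles
  the network input `X = [ZE | ZG·Qᵀ | ZGE·(I ⊗ Qᵀ)]` from environment,
  line and cell incidence matrices. The interaction block can be dropped
  (`WI` mode).
- **Mixed-trait network.** A shared trunk of 1–3 ReLU hidden layers (equal
  unit counts, dropout) feeds one head per trait: ReLU + squared error for
  continuous traits (standardized per training set), sigmoid + binary
  cross-entropy for binary traits, softmax + categorical cross-entropy for
  ordinal traits. Training is seeded mini-batch Adam, implemented in NumPy,
  fully deterministic. The univariate counterpart (`UDL`) trains one
  single-head network per trait.
- **Tuning.** Grid search over epochs (default 1–100) and hidden units
  (default 10–490 step 20) on a 20% inner validation split, monitoring the
  validation loss per epoch so each unit candidate trains once.
- **Evaluation.** Fivefold CV2 cross-validation over (line, environment)
  cells — test lines stay observed in other environments — scored with
  Pearson's correlation (continuous) and the fraction of correctly
  classified cases (categorical), averaged over folds per
  trait × environment.
- **Simulation.** Seeded generator of Hardy–Weinberg markers and correlated
  multi-trait phenotypes with environment effects, G×E variance, target
  heritabilities, and liability-style quantile discretization, so the whole
  pipeline is testable without external data.

## CLI

```sh
# generate a synthetic data set
gpmix simulate --config examples/simulation.yaml --out data/

# run a full CV2 experiment (MTDLMP with G×E, 1 hidden layer)
gpmix -v run --config examples/run.yaml \
    --markers data/markers.tsv --phenotypes data/phenotypes.tsv \
    --out results/ --model mtdlmp --interaction I --layers 1

# recompute metrics from saved predictions
gpmix metrics --config examples/run.yaml \
    --predictions results/predictions.tsv --out recomputed/
```

`run` writes `report.tsv` (trait, environment, fold, metric_name, value),
`summary.json` (fold averages), `predictions.tsv` and `cv_plan.tsv`.
See `examples/` for commented config files.

## Python API

```python
from gpmix import RunConfig, TraitSpec, TuningGrid, run_experiment
from gpmix import read_marker_table, read_phenotype_table

specs = [TraitSpec("GY", "continuous"), TraitSpec("DTHD", "ordinal", 3)]
markers = read_marker_table("markers.tsv")
phenotypes = read_phenotype_table("phenotypes.tsv", specs)
config = RunConfig(trait_specs=specs, model_kind="MTDLMP",
                   interaction_mode="I", grid=TuningGrid.reduced(), seed=1)
report = run_experiment(config, markers, phenotypes)
print(report.summary)
```

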