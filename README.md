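# orchardqg

Genetic testing in seed-orchard plantations without a designed progeny
trial: microsatellite diversity statistics, likelihood-based maternity
assignment with Monte-Carlo confidence tiers, and a spatial animal model
(separable AR1⊗AR1 residual autoregression) fitted by REML to yield
variance components, heritability and predicted breeding values for
forward selection.

## What it does

Given a codominant microsatellite genotype table (candidate mothers plus
one or more offspring cohorts) and a phenotype/coordinate table (tree id,
DBH, planar x/y), the pipeline:

1. screens outlier trees by DBH (strictly greater than the threshold);
2. summarises per-locus/per-group diversity (allele counts, effective
   alleles, observed/expected heterozygosity, fixation index) plus marker
   informativeness (PIC, non-exclusion probabilities);
3. assigns each offspring to its maximum-LOD candidate mother under a
   genotyping-error model, with strict/relaxed/low confidence tiers
   calibrated by simulation of the delta (best minus second-best LOD)
   statistic;
4. tests spatial autocorrelation of the phenotype (Moran's I);
5. rasterizes the stand onto a row×column grid, fits the mixed model
   `y = Xb + Zu + ξ + η` under seven candidate spatial correlation
   structures (exponential, Gaussian, spherical, linear, rational
   quadratic, AR1, AR1⊗AR1) plus the plain animal model, and ranks them
   by AICc;
6. reports variance components with standard errors, heritability
   (`h² = σ²_A / (σ²_A + σ²_ξ + σ²_η)`), and BLUP breeding values for
   offspring (forward selection) and mothers (backward selection).

A first-class `synthetic_data` module simulates whole orchards with known
truth — genotypes by Mendelian transmission from an HWE pollen pool, and
phenotypes as genetic value + AR1⊗AR1 field + nugget — so every stage is
testable against oracles without external data.

## Layout

| module | contents |
|---|---|
| `orchardqg.genotypes` | `GenotypeTable` I/O (GenAlEx-style and long CSV), allele frequencies, diversity summary, PIC, non-exclusion probabilities |
| `orchardqg.parentage` | transition probabilities, LOD scores, delta statistic, simulated critical deltas, maternity assignment, `Pedigree` |
| `orchardqg.spatial` | Moran's I, rasterization, correlation structures and matrices |
| `orchardqg.animal_model` | additive relationship matrix, REML likelihood and fitting, AICc comparison, heritability, BLUP, selection ranking |
| `orchardqg.synthetic_data` | orchard/phenotype simulators with recorded `SimulationTruth` |
| `orchardqg.pipeline` / `orchardqg.cli` | end-to-end orchestration and the `orchardqg` command |

## CLI

```sh
# simulate a synthetic orchard into ./demo
orchardqg simulate --n-mothers 60 --grid 30 30 --seed 1 --out demo

# diversity summary and marker informativeness
orchardqg diversity demo/genotypes.csv

# maternity assignment with simulated confidence
orchardqg assign demo/genotypes.csv --offspring-group HC --candidate-group PT \
    --out parentage.csv --pedigree-out pedigree.csv

# Moran's I on DBH
orchardqg moran demo/phenotypes.csv

# fit the animal + AR1xAR1 model / compare all candidate models
orchardqg fit demo/phenotypes.csv --pedigree demo/pedigree_true.csv --grid 30 30
orchardqg compare demo/phenotypes.csv --pedigree demo/pedigree_true.csv --grid 30 30

# full pipeline from a YAML config
orchardqg run --config config.yaml
```

A minimal `config.yaml`:

```yaml
genotypes: demo/genotypes.csv
phenotypes: demo/phenotypes.csv
output_dir: out
grid_rows: 30
grid_cols: 30
seed: 1
parentage:
  error_rate: 0.01
  n_sim: 10000
```

## Conventions worth knowing

- H_E is the uncorrected gene diversity `1 − Σp²` so `H_E = 1 − 1/N_E`
  holds exactly; a small-sample corrected variant is available via
  `unbiased=True`.
- The genotyping-error model replaces an observed genotype with a random
  HWE genotype with probability `e`; the single-locus likelihood ratio is
  `(1−e)² T/P_HWE + e(2−e)`.
- Non-exclusion probabilities: first parent `NE_1P = 4a₂ − 2a₂² − 4a₃ + 3a₄`
  and identity `NE_I = 2a₂² − a₄` with `a_k = Σ p_iᵏ`; multilocus values are
  products over loci.
- Unknown sires are distinct unrelated founders (maternal half-sibs get
  A = 0.25); heritability includes the spatial variance in the denominator.
- AICc parameter count k = fixed effects + variance components +
  correlation/range parameters.
- All stochastic steps are seeded; identical inputs, config and seed give
  byte-identical pipeline outputs.
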