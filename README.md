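# hybridgp

Genomic prediction for structured testcross hybrid populations across
environments, as a tested, reusable pipeline:

- **`hybridgp.simulate`** — synthetic study generator: homozygous founders on a
  centimorgan map, explicit-meiosis derivation of four population types
  (backcross-selfed BC1F3, doubled haploid, F4:5 selfing series, unrelated
  materials), testcross to a common tester, and plot-level multi-environment
  yield trials with controlled variance components.
- **`hybridgp.qc`** — SNP QC (call rate, position, missing rate, MAF, in that
  order), stand-in imputation, minor-allele coding, and inference of hybrid
  additive (Z) and dominance (W) genotype codes from line × tester matings.
- **`hybridgp.structure`** — SVD principal components of the scaled codes and a
  Pearson line-by-line similarity matrix.
- **`hybridgp.trial`** — per-line BLUEs (REML mixed model; balanced shortcut),
  balanced ANOVA of the yield model `y = mu + g + e + ge + rep(e) + eps`, and
  entry-mean broad-sense heritability `H2 = s2g / (s2g + s2ge/e + s2e/(e·r))`.
- **`hybridgp.kinship`** — additive/dominance genomic relationship matrices
  `K = MMᵀ / mean(diag(MMᵀ))`.
- **`hybridgp.gblup`** — single-trait GBLUP (A and A+D models) with a
  deterministic REML solver and an optional conjugate Gibbs sampler.
- **`hybridgp.multienv`** — SE / AE / G×E stacked multi-environment models
  (shared main effect; block-diagonal environment-specific effects;
  homogeneous residual).
- **`hybridgp.evaluate`** — within-population, one-to-one and three-to-one
  transfer schemes, and CV1/CV2 multi-environment cross-validation with
  Pearson prediction accuracy.
- **`hybridgp.pipeline` / `hybridgp.cli`** — YAML-driven orchestration with a
  checksummed run manifest.

## CLI

Run the whole study from one config (see `examples/study.yaml`):

```bash
hybridgp run --config examples/study.yaml --out out/
```

Stage subcommands mirror the pipeline:

```bash
hybridgp simulate  --config examples/study.yaml --out out/
hybridgp qc        --genotypes out/genotypes.tsv --markers out/markers.tsv --out out/
hybridgp structure --codes out/Z.tsv --out out/
hybridgp trial     --phenotypes out/phenotypes.csv --scope across_env --out out/
hybridgp kinship   --codes out/Z.tsv --out out/Ka.tsv
hybridgp evaluate  --blues out/blues_per_env.csv --ka out/Ka.tsv \
                   --scheme cv2 --model GxE --reps 100 --folds 5 --seed 7 --out out/
```

All intermediates are plain text: genotype calls as TSV (`AA/Aa/aa/NA`) with a
marker sidecar (`marker, chrom, pos_cM`), phenotypes as long-format CSV
(`line, env, rep, block, yield`), Z/W code matrices and kinships as TSV,
evaluation results as tidy CSV plus a summary.

## Notes

- Every stochastic stage is seed-reproducible (per-operation substreams
  derived from the study seed); reruns produce byte-identical artifacts.
- Variance-component extraction defaults to the convention that reproduces the
  published heritability table (`convention="paper"`); the classical EMS rule
  is available via `convention="classical"`.
- Meiosis uses a no-interference model (Poisson crossover counts on the cM
  map); haplotype-based imputation is out of scope and replaced by documented
  simple imputers.
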