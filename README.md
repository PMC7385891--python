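# semgwas

Multi-trait multi-locus structural equation models for genotype–phenotype
association and genomic trait prediction.

The model couples a measurement part (latent factors loading on correlated
phenotypes) with a structural part (a directed acyclic graph among the
factors) and attaches SNPs either to factors (pleiotropic effects, matrix Π)
or directly to traits (single-trait effects, matrix K):

```
eta = B eta + Pi g + eps
p   = Lambda eta + K y + delta
```

Ordinal variables — genotype codes and categorical traits — are handled
through a latent-normal threshold model: sample covariances are replaced by
polychoric/polyserial correlations for maximum-likelihood steps, and by
truncated-normal data augmentation inside the Gibbs sampler.

## What the package does

| stage | module | summary |
|---|---|---|
| data simulation | `semgwas.synthetic` | generative models with known truth, Hardy-Weinberg SNPs, ordinal discretization |
| data preparation | `semgwas.io` | VCF / table genotypes, MAF > 3% and call-rate > 90% filters, category merges, log + z-score transforms |
| ordinal statistics | `semgwas.ordinal` | threshold estimation, polychoric/polyserial correlation, hybrid correlation matrices with PSD repair |
| model core | `semgwas.model` | implied covariance, Wishart log-likelihood, ML fitting, Wald tests |
| structure learning | `semgwas.structure` | parallel analysis, factor analysis with the 0.5 attribution rule, greedy acyclic search over factor edges |
| SNP selection | `semgwas.selection` | Wishart-density candidate scoring, breadth-first DAG traversal, redundancy filtering |
| Bayesian estimation | `semgwas.gibbs` | six-step Gibbs sweep with data augmentation, Gelman-Rubin and effective-sample-size diagnostics |
| prediction | `semgwas.predict` | conditional-mean trait prediction, k-fold cross-validation, sliding-window congruence, peak-vs-hit permutation test |

Four model configurations are supported: `zero`/`connected` (without/with the
structural matrix B) crossed with `base`/`extended` (factor SNPs only, or
factor plus trait SNPs).

## Command line

Every subcommand writes its outputs plus a `manifest.json` (seeds, versions,
parameter counts) into the `--out` directory.

```bash
semgwas simulate --seed 1 --n-samples 500 --n-factors 2 \
    --traits-per-factor 3,3 --snps-per-factor 3,3 --b-edges 0-1:0.5 --out sim
semgwas prepare  --vcf sim/genotypes.vcf --phenotypes sim/phenotypes.tsv --out prep
semgwas build    --vcf prep/genotypes.vcf --phenotypes prep/phenotypes.tsv \
    --model-type connected-base --out build
semgwas fit      --vcf prep/genotypes.vcf --phenotypes prep/phenotypes.tsv \
    --model build/model.json --chains 5 --length 2000 --out fit
semgwas predict  --vcf prep/genotypes.vcf --model fit/fitted_model.json --out pred
semgwas cv       --vcf prep/genotypes.vcf --phenotypes prep/phenotypes.tsv \
    --k 20 --seed 1 --out cv
semgwas congruence --positions positions.tsv --chrom-lengths 1:5000000 --out cong
```

## Notes on conventions

- Identification: the first attributed trait of each factor has its loading
  fixed at 1; factor error variances stay free.
- Wishart likelihood: `(n-1) S ~ Wishart(df = n-1, scale = Sigma)`, so
  `E[S] = Sigma`.
- The coefficient of determination reported by the prediction metrics is the
  squared Pearson correlation.
- Congruence windows are 0-based half-open `[start, start + window)` with
  starts on multiples of the step.
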