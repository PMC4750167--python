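# bayesqtl

Bayesian whole-genome regression for traits with a large-effect QTL:
spike-and-slab mixture models (BayesB, BayesC) against equal-variance
ridge models (BayesC0 and the marker-effects form of GBLUP), compared on
three tasks that matter in breeding programs —

1. **QTL detection** by the posterior genetic variance of 1-Mb genomic
   windows,
2. **genomic prediction** of phenotype in later generations (accuracy and
   its persistence as the validation generation moves away from training),
3. **shrinkage bias** of the top region's estimated effect, measured as
   the regression of hatch-corrected phenotype on predicted merit.

The intended users are quantitative geneticists and breeding-program
analysts.  Because real datasets of this kind (closed commercial layer lines
genotyped on medium-density chips) are proprietary, the package includes a
forward simulator of such populations — discrete generations of a few
hundred birds, hatch-within-generation fixed effects, chip-like linkage
disequilibrium built by meiosis through a small-Ne warm-up, and one
planted QTL carrying a large fraction of genetic variance — so every
method is exercised against known truth.

## The models

All models fit, by single-site Gibbs sampling,

```
y_i = Σ_k Xf_ik β_k + Σ_j x_ij α_j + e_i,   e_i ~ N(0, σ²_e)
α_j = 0                 with probability π
α_j ~ N(0, σ²_j)        with probability 1 − π
```

with dosages `x_ij` centered by `2p_j`.  BayesB (π = 0.99, a variance per
SNP, df 4/10) and BayesC (π = 0.99, common variance) are the mixtures;
BayesC0 (π = 0) fits every SNP with a common estimated variance, and the
GBLUP variant (π = 0, df 100/100) pins that variance at its prior scale,
which is equivalent to an animal model with the genomic relationship
matrix `G = XX'/Σ2p_jq_j`.  Windows are labelled `chrom_Mb` with
`Mb = floor(bp/10⁶)`; a window's `%Var` is the posterior mean share of
genetic variance carried by its SNPs' genomic values.  See
`docs/methods.md` for the full account.

## Worked example

```python
from bayesqtl import (SimulationConfig, simulate_population, qc_filter,
                      build_model_data, run_chain, MCMCConfig,
                      summarize_windows)

cfg = SimulationConfig(seed=1)      # 8 generations, 2,324 birds, 3,000 markers,
pop = simulate_population(cfg)      # QTL with 25 % of genetic variance at chr1:78.5 Mb
panel, removed = qc_filter(pop.genotypes, pop.pedigree)
print(f"panel after QC: {panel.n_snps} SNPs ({len(removed)} removed)")

data = build_model_data(panel, pop.phenotypes.for_generations(range(1, 8)))
for model in ("bayesB", "gblup"):
    fit = run_chain(data, model, mcmc=MCMCConfig(n_iter=6000, burn_in=1000, seed=7))
    top = summarize_windows(fit).iloc[0]
    print(f"{model:7s} top window {top['label']}: "
          f"{top['pct_var']:.1f} % of genetic variance (p>0 = {top['p_gt0']:.2f})")
print(f"planted QTL window: {pop.true_window[0]}_{pop.true_window[1]}")
```

prints

```
panel after QC: 1940 SNPs (1060 removed)
bayesB  top window 1_78: 36.7 % of genetic variance (p>0 = 1.00)
gblup   top window 1_78: 8.8 % of genetic variance (p>0 = 1.00)
planted QTL window: 1_78
```

Both models place the top window at the planted QTL when trained on seven
generations, but the mixture model attributes to it a share of genetic
variance close to the planted 25 % while the equal-variance model spreads
the same signal across the genome — the dilution that makes large QTL
hard to see, and hard to exploit, under ridge-type priors.

The same analyses run from the shell:

```
bayesqtl simulate --config sim.yaml --out-dir pop/
bayesqtl qc --genotypes pop/genotypes.raw --map pop/map.tsv --pedigree pop/pedigree.tsv --out-dir qc/
bayesqtl fit --model bayesB --genotypes qc/genotypes.raw --map qc/map.tsv \
             --phenotypes pop/phenotypes.tsv --chain 35000 --burnin 5000 --out-dir fit/
bayesqtl gwas-windows --fit fit/ --out windows.tsv
bayesqtl run --config pipeline.yaml --seed 1 --out-dir results/   # whole pipeline
```

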