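# bayesbpi

Bayesian whole-genome regression for genomic prediction with
**locus-specific mixture priors** (BayesB-π), plus the standard baselines
(GBLUP, BayesA, BayesB), a trait-architecture simulator, and a repeated
cross-validation evaluation harness.

## Who this is for

Animal and plant breeders (and quantitative geneticists generally) who
predict genomic estimated breeding values (GEBVs) from SNP panels.  The
classic BayesB sampler assumes every marker has the same prior probability
π (usually 0.95) of being non-effective — ignoring what the data say about
the trait's genetic architecture.  Here π becomes a per-marker quantity
derived from single-marker ANOVA in the training population:

ω_i = −log₁₀(p_i),  π_i = (max ω − ω_i) / (max ω − min ω)

so markers in strong marginal association (e.g. a DGAT1-like major gene)
are proposed into the model far more often than the genome-wide
background.  On traits governed by large-effect QTL this raises prediction
accuracy relative to constant-π BayesB; on purely polygenic traits GBLUP
remains competitive.

## Models

* **GBLUP** — y = 1μ + u + e with u ~ N(0, σ²ᵤG); G is VanRaden's
  WW'/(2Σp_jq_j); variance components by REML.
* **BayesA/B/B-π** — y = 1μ + Σ w_j g_j + e with g_j ~ N(0, σ²_gj) and
  σ²_gj ~ x⁻²(ν = 4.234, S = 0.0429), plus (BayesB/B-π) a point mass at 0
  with probability π (constant or the per-marker vector above).  Variance
  and effect of each locus are updated jointly by Metropolis-Hastings with
  the mixture prior as proposal, so acceptance is a pure marginal-likelihood
  ratio.

All four are scikit-learn style estimators (`fit(X, y)` / `predict(X)` /
`get_params`) over 0/1/2 genotype matrices, so they compose with sklearn
model selection; cross-validating `BayesBPi` automatically recomputes π
inside each training fold with no leakage from held-out individuals.

## Worked example

```python
import bayesbpi as b

# one major QTL carrying 30% of the genetic variance, h2 = 0.5
ds = b.simulate_dataset(b.preset("mfp", 500, 300, seed=11))
X, y = ds.genotypes.codes, ds.phenotypes.values[:, 0]

# the locus-specific prior: the most significant marker gets pi = 0
prior = b.locus_pi_from_data(ds.genotypes, y)

# 5-fold CV x 2 repeats, three methods (short chains for the example)
plan = b.make_cv_plan(500, 5, repeats=2, seed=0)
chain = dict(n_iterations=500, burn_in=100, mh_cycles=5, seed=0)
methods = {"gblup": b.GBLUP(),
           "bayesB": b.BayesB(**chain),
           "bayesBpi": b.BayesBPi(**chain)}
report = b.run_crossval(X, y, methods, plan)
print(report.aggregate()[["method", "accuracy_mean", "accuracy_se"]].round(3))
```

Output:

```
  method  accuracy_mean  accuracy_se
   gblup          0.395        0.017
  bayesB          0.528        0.015
bayesBpi          0.538        0.016
```

Accuracy is the Pearson correlation between held-out GEBVs and responses,
averaged over the 10 validation folds (± SE).  On this major-QTL trait the
Bayesian variable-selection methods clearly beat GBLUP, and the
locus-specific prior adds a further gain over constant-π BayesB of
β = (0.538 − 0.528)/0.528 × 100 = 1.83%.  The ANOVA stage pins the true
major QTL: `prior.pi` is exactly 0 at the simulated causal locus (`snp91`
here).

## Command line

```sh
bayesbpi simulate  --preset mfp --n-individuals 500 --n-markers 1000 --seed 1 --out run/
bayesbpi gwas-pi   --genotypes run/genotypes.tsv --phenotypes run/phenotypes.tsv --out pi/
bayesbpi predict   --genotypes run/genotypes.tsv --phenotypes run/phenotypes.tsv \
                   --method bayesBpi --out pred/
bayesbpi crossval  --genotypes run/genotypes.tsv --phenotypes run/phenotypes.tsv \
                   --methods gblup,bayesB,bayesBpi --k 5 --repeats 20 --out cv/
```

Every output directory contains the resolved configuration, a log with
seeds, and input checksums, so any run can be reproduced from its outputs.
Genotypes are read in a simple tab-separated dialect or PLINK `--recode A`
raw format.

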