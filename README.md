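# prrtest

Differential-abundance testing for microbiome count tables with the
**permutation of regressor residuals (PRR) test**, applicable to any of eight
(zero-inflated, overdispersed) count-regression families.

## The problem

Amplicon and metagenomic studies summarize each sample as a vector of taxon
counts whose totals (library sizes) vary by orders of magnitude for technical
reasons, and whose per-taxon distributions are heavily overdispersed and
zero-inflated.  Differential-abundance analysis fits a regression per taxon
and asks whether a covariate of interest (a diet group, an exposure gradient)
is associated with the counts while adjusting for nuisance covariates.  The
standard likelihood-ratio test (LRT) is only calibrated when the count model
is right; on real microbiome data a misspecified family can reject most taxa
that carry no signal at all.  A permutation test fixes the calibration but
plain permutation of the outcome cannot adjust for covariates in small
samples.  The PRR test combines the two: keep the regression, permute a
residualized version of the covariate of interest.

## The method

For taxon $j$ with counts $Y_{ij}$, library sizes $s_i = \sum_j Y_{ij}$, a
count-component design $X = (X^*, X^\dagger)$ and a zero-component design
$Z = (Z^*, Z^\dagger)$ (interest / nuisance blocks), the per-taxon likelihood
is $L_j = \prod_i f(Y_{ij} \mid X_i, Z_i, \bar\alpha, \bar\beta)$ where $f$
is one of

|                | not overdispersed | overdispersed  |
|----------------|-------------------|----------------|
| not zero-infl. | Poisson, Binomial | NegBin, BetaBin |
| zero-inflated  | ZIPoisson, ZIBinomial | ZINegBin, ZIBetaBin |

Poisson-type families use a log link with an additive $\log s_i$ offset;
Binomial-type families draw $Y_{ij}$ from $s_i$ trials with a logit link.
Zero-inflated families mix the base density with a point mass at zero whose
probability is $\operatorname{logit}^{-1}(Z_i\bar\beta)$.  The null
hypothesis is $\bar\alpha^* = 0,\ \bar\beta^* = 0$.

The test proceeds in three stages:

1. replace $X^*$ by its least-squares residual
   $\tilde X = X^* - X^\dagger\hat\Sigma$,
   $\hat\Sigma = \arg\min_\Sigma \lVert X^* - X^\dagger\Sigma \rVert^2$
   (likewise $\tilde Z$); the maximized likelihood is unchanged, but the
   residuals are uncorrelated with the nuisance covariates;
2. for $b = 1,\dots,B$ permute the rows of $\tilde X$ (and $\tilde Z$, with
   the same permutation), refit, and convert each likelihood-ratio pivotal
   against the nuisance-only fit into a $\chi^2_{p+s}$ p-value $p_{j,b}$,
   where $p$ and $s$ count the interest columns of the two components;
3. report both the observed LRT p-value $\hat p_j$ and the permutation
   p-value $p_j = \tfrac1B \sum_b \mathbb I(p_{j,b} < \hat p_j)$.

Because the permuted pivotals are exchangeable with the observed one under
the null, $p_j$ is calibrated *regardless of whether the count model fits* —
that is the point of the method.

## Worked example

```bash
prrtest simulate --n-samples 100 --n-taxa 40 --seed 3 --outdir demo
prrtest test --counts demo/counts.tsv --covariates demo/covariates.tsv \
    --family Poisson --family ZINegativeBinomial -B 200 --seed 3 \
    --out demo/results.tsv
prrtest evaluate --results demo/results.tsv --truth demo/truth.tsv
```

which prints (taxa simulated with a +100% diet effect in 10% of taxa per
group, counts overdispersed and zero-inflated):

```
            family test_type  power   fpr  power_at_0.05  auc_at_0.10
           Poisson    loglik  0.917 0.821          0.333        0.357
           Poisson    llperm  0.333 0.036          0.333        0.298
ZINegativeBinomial    loglik  0.333 0.000          0.417        0.417
ZINegativeBinomial    llperm  0.333 0.000          0.417        0.396
```

Read: the plain Poisson LRT (`loglik`) rejects 82% of the taxa that carry
**no** signal — worthless calibration on this kind of data — while the same
family under the PRR test (`llperm`) sits near the nominal 5% and still
detects a third of the truly affected taxa.  The zero-inflated negative
binomial fits the data better (far smaller LRT inflation here).  With only
40 taxa the rates are coarse (28 null taxa per cell); the acceptance run
below averages hundreds of null taxa over repetitions.

`prrtest replicate` runs the full scaled-down model-comparison harness
(all 8 families × both test types, repeated with per-repetition seeds) and
writes the summary as mean (±se) rows; `--dry-run` prints the plan.

The same operations are available as library functions
(`prrtest.run_prr_test`, `run_prr_table`, `build_experiment`,
`compute_metrics`, `run_experiment`).

## Layout

- `src/prrtest/models.py` — the eight likelihoods and honest ML fitting
- `src/prrtest/prr.py` — residualization, permutation scheme, the test
- `src/prrtest/simulate.py` — synthetic study generator with known truth
- `src/prrtest/evaluate.py` — FPR/TPR, power@0.05, partial AUC
- `src/prrtest/io.py`, `experiment.py`, `cli.py` — formats, harness, CLI
- `docs/methods.md` — modelling choices, parameterizations, limitations
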