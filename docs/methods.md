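# Methods

## Model

For sample $i$ and taxon $j$ the count $Y_{ij}$ follows one of eight
families: {Poisson, Negative Binomial, Binomial, Beta-Binomial} with or
without zero inflation.  The per-taxon likelihood factorizes over samples,
$L_j = \prod_i f(Y_{ij}\mid X_i, Z_i, \bar\alpha, \bar\beta)$, with a
count-component design $X$ (log link plus `offset(log s_i)` for
Poisson-type families; logit link with $s_i$ trials for Binomial-type
families, where $s_i$ is the library size) and, for zero-inflated families,
a logistic zero component on $Z$:
$f(y) = \pi\,\mathbb I(y{=}0) + (1-\pi)\,g(y)$,
$\operatorname{logit}\pi_i = Z_i\bar\beta$.

Parameterizations match the conventions of the R count-regression
ecosystem: Negative Binomial with mean $\mu$ and size $\theta$
(variance $\mu + \mu^2/\theta$); Beta-Binomial with mean probability $p$
and overdispersion $\rho\in(0,1)$, i.e. Beta shapes
$a = p(1-\rho)/\rho$, $b = (1-p)(1-\rho)/\rho$.  The link for the zero
component is logistic; nothing in the mixture forces that choice, but it is
what every widely used zero-inflated regression implementation does and it
makes the zero component a plain logistic regression in the no-covariate
limit.

## Fitting

Auxiliary parameters are optimized on unconstrained internal scales
($\log\theta$, $\operatorname{logit}\rho$) so the optimizer never touches a
natural-domain boundary.  The plain Poisson and Binomial families are fit
by Newton (IRLS) iterations with step halving; the other six use L-BFGS-B
with analytic gradients followed by up to five Newton polish steps on a
finite-difference Hessian of the analytic gradient, restricted to
coordinates not pinned at the internal box ($|$coefficient$| \le 30$,
$|$internal aux$| \le 16$).  One fallback restart from perturbed starting
values precedes any declaration of non-convergence.

Starting values matter for these likelihoods (the Beta-Binomial in
particular can be hard to evaluate far from its optimum): the mean
component starts from an IRLS pass of the corresponding plain family, the
zero-component intercept from the logit of the observed excess of zeros
over what the fitted base density predicts, and the dispersion parameters
from method-of-moments estimates.

Convergence is reported honestly and checked by the caller:

* the flag is false when the iteration cap was reached, when the projected
  gradient inf-norm exceeds `1e-6 * max(1, |loglik|)`, or when an auxiliary
  (dispersion) parameter sits at its internal boundary.  Dispersion
  parameters running away silently are a known failure mode of off-the-shelf
  negative-binomial fitters, hence the explicit guard.
* the tolerance is relative to the magnitude of the log-likelihood because
  the gradient of a summed log-likelihood is extensive — a fixed absolute
  tolerance would spuriously fail large or high-count datasets and pass tiny
  ones.
* a *regression coefficient* pinned at the $\pm 30$ box is reported in the
  fit messages but does not fail the fit.  This happens when a covariate
  (quasi-)separates the zeros: the likelihood then increases toward a
  supremum at infinite coefficients along an asymptotically flat direction,
  and the value at the box edge equals that supremum to working precision.
  Treating such fits as failures would discard exactly the permutations in
  which the shuffled residuals landed on a separating configuration, biasing
  the permutation null.

## The PRR test

Stage 1 replaces the interest block $X^*$ by its least-squares residual
$\tilde X = X^* - X^\dagger\hat\Sigma$ against the nuisance block (same for
$Z^*$).  Because $(\tilde X, X^\dagger)$ spans the same column space as
$(X^*, X^\dagger)$, the maximized likelihood is unchanged — asserted as a
test invariant to $10^{-6}$.  A categorical covariate of interest with $m$
levels contributes $m-1$ treatment-coded columns that are residualized and
permuted as a block.

Stage 2 draws $B$ uniform row permutations (default $B = 1000$,
resolution $10^{-3}$; the scaled-down experiments use $B=200$); one index
vector per iteration is applied to both $\tilde X$ and $\tilde Z$.  Each
permuted fit is compared against the nuisance-only (reduced) fit through
the likelihood-ratio pivotal, $p_{j,b} = \chi^2_{d}\{2(\ell_b -
\ell_{\text{red}})\}$ with $d$ = number of interest columns across both
components ($p + s$); the observed $\hat p_j$ uses the unpermuted residuals
in the same way.  The degrees of freedom count only the constrained
(interest) parameters — the difference in parameter count between the
nested models — not the full column count of $X$.

Stage 3 reports $p_j = \frac1B\sum_b \mathbb I(p_{j,b} < \hat p_j)$ with a
strict inequality.  An add-one smoothed estimator
$(1 + \#\{p_b \le \hat p\})/(1+B)$ is available behind a flag for
downstream FDR procedures that cannot tolerate exact zeros; it is not the
default.  Since the $B{+}1$ pivotals are exchangeable under the null, the
rejection probability at $\gamma$ is $\lfloor \gamma B\rfloor{+}1$ over
$B{+}1$ ($\approx 0.0498$ at $\gamma=0.05$, $B=200$) whatever the count
model — the calibration the test exists to provide.

Permutation fits that still fail after the fallback restart are dropped and
counted; if more than 10% of the $B$ iterations fail the taxon is reported
as failed rather than silently renormalized.  All-zero taxa are skipped
with a reason (no family carries information about them).  Warm starts
(reduced fit → observed fit → permutation fits) keep the refits cheap and
deterministic.

## Synthetic data

The generator stands in for a real 16S count table (on the order of 150
samples × 500 taxa, counts overdispersed with variance tens of times the
mean and zero-inflated, library sizes spread over orders of magnitude).
The base table draws $Y_{ij} \sim \text{ZINB}(\mu_j f_i, \theta_j, \pi_j)$
with per-taxon means log-uniform on [1, 100], dispersions uniform on
[0.1, 2], zero-inflation uniform on [0, 0.6], and log-normal library-size
factors ($\sigma = 0.5$).  A sample whose row comes out all zero receives
one pseudo-count so that library-size offsets stay defined.

Signal injection:

* **diet** — four equiprobable groups; each group has its own independent
  random 10% of taxa; within a group's DA taxa, that group's samples get
  the effect (default multiplier 2.0 = +100%).
* **counts mode** — non-zero counts are multiplied and rounded
  half-to-even (unbiased; a +25% effect on odd counts is fractional);
  zeros stay zero.
* **counts-and-zeros mode** — first the taxon's non-zero *status* is
  redrawn for every sample from its odds (baseline odds = #nonzero/#zero;
  affected samples' odds are multiplied by the effect), with non-zero
  draws taking values sampled without replacement from the taxon's
  original non-zero pool; the count multiplication is then applied to the
  result.  The pool is over-demanded by construction whenever the
  multiplier exceeds one (baseline demand alone matches the pool in
  expectation), so depletion — surplus draws resolved to zeros, chosen
  uniformly — is part of the scheme, not an edge case: the values are
  conserved and only shuffled toward affected samples.
* **confounders** (optional) — urbanization is assigned with
  P(low | diet) = 0.8/0.6/0.4/0.2 for meateater/fisheater/vegetarian/vegan
  (with uniform diet groups this yields the fixed joint table whose
  marginals are 50/50), and age decades are drawn conditionally on diet
  (vegans skew young; no vegan reaches 60), uniformly within the decade
  over [20, 69].  Urbanization carries its own 10% of taxa at +200%
  applied in the high group; age carries its own 10% with a per-sample
  multiplier ramping linearly from ×1 at age 20 to ×5 at age 69, applied
  to counts (and to the zero-odds in counts-and-zeros mode).  Applying the
  urbanization multiplier in both groups would cancel the contrast, so it
  is applied on one side.

Library sizes are recomputed after injection (they are the row sums by
definition).  What the generator does **not** emulate: phylogenetic or
co-occurrence correlation between taxa, compositional closure (taxa are
drawn independently given the library factor), batch effects, and the
possibility that real "null" taxa carry residual signal.  Passing tests
therefore demonstrate calibration and power under realistic marginal count
behaviour, not under every dependence structure real data can show.

## Evaluation

FPR and TPR use strict `p < γ` at γ = 0.05 over the truly-null and
truly-DA taxa respectively; taxa whose test failed are excluded from both
denominators rather than imputed.  `power@0.05` re-thresholds at the
largest cutoff whose empirical FPR stays ≤ 0.05 (ties resolved toward the
smaller threshold — conservative and deterministic).  `AUC@0.10` is the
trapezoidal partial ROC area up to FPR 0.10 divided by its maximum 0.10,
so chance scores 0.05 and a perfect ranking 1; a McClish-standardized
variant (chance ↦ 0.5) is available behind a flag because published
partial-AUC tables are often on that scale.  Repetition summaries report
mean ± standard error (ddof = 1) formatted to two decimals.

## Scaled-down experiment sizes

The packaged experiments and the acceptance script run at desk scale,
chosen so a full run completes in minutes on one CPU while keeping enough
null taxa for the FPR estimates to resolve the ±0.02 bands: n = 100
samples, 100 taxa for the Poisson family and 50 for the zero-inflated
negative binomial / beta-binomial families, B = 200 permutations, 5
repetitions with per-repetition seeds `seed + r`.  At these sizes each FPR
estimate averages roughly 300 (Poisson) or 160 (ZI families) null-taxon
decisions.

## Known limitations

* The permutation stage refits the model B times per taxon; the
  zero-inflated beta-binomial is the slowest family (~8 ms per warm-started
  fit at n=100).
* The test assumes samples are exchangeable under the null given the
  nuisance covariates; stratified or restricted permutation schemes are out
  of scope.
* Quasi-separation in the zero component means some zero-inflated
  likelihoods have no finite maximizer; the compact internal parameter box
  makes the reported maxima well defined (see Fitting).
* p-values are reported raw across taxa; Benjamini–Hochberg adjustment is
  offered only as an explicit post-processing step, never applied silently.
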