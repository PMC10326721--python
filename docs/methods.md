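# Methods

## Model

Counts are modeled as a Poisson-log-normal generalized linear mixed
model.  For gene g = 1..G, sample i = 1..N and preparation j (mRNA or
RPF),

    y_gij ~ Poisson(lambda_gij)
    log lambda_gij = x_ij' beta_g + u_gi + o_ij
    u_gi ~ iid N(0, sigma_u^2)

The design row `x_ij = (1, I(treatment), I(RPF), I(both))` produces the
2 x 2 table of log-scale cell means: beta_g0 (control mRNA),
beta_g0 + beta_g1 (treatment mRNA), beta_g0 + beta_g2 (control RPF),
beta_g0 + beta_g1 + beta_g2 + beta_g3 (treatment RPF).  Log
translational efficiency is the RPF-minus-mRNA contrast within a
condition, so beta_g3 is the between-condition log-TE change and the
null hypothesis of no differential translation is beta_g3 = 0.  The
lognormal random effect u_gi, shared by the mRNA/RPF pair from one
biological sample, encodes the pairing and soaks up overdispersion
relative to Poisson.

The interaction has a spike-and-slab prior, beta_g3 = (1 - D_g) W_g
with D_g ~ Bern(pi0) (D_g = 1 means null) and W_g ~ N(mu_b3, s2_b3).
The remaining coefficients have hierarchical Gaussian priors
beta_gp ~ N(mu_bp, s2_bp), p = 0..2.  Conjugate hyperpriors close the
hierarchy: inverse-gamma (shape alpha, rate gamma) on sigma_u^2 and
each s2_bp, N(0, sigma2_mu) on each mu_bp, Beta(a0, b0) on pi0.

Offsets o_ij default to zero (the bare model).  An optional per-column
log offset is available (user-supplied, or computed as log of the
column total over the geometric mean of column totals) for libraries of
very unequal depth; it is off by default so the fitted model is exactly
the one above.

### Default hyperparameters

The hyperprior constants are weakly informative and configurable:
shape 2 / rate 1 for every inverse-gamma (prior mean variance 1, on the
squared natural-log scale), sigma2_mu = 100 (diffuse), Beta(1, 1) on
pi0.  Nothing in the defaults encodes the expected null fraction; pi0
is learned from the data.

## Variational approximation

The posterior is approximated by a factorized distribution

    q(theta) = q(phi) prod_g q(D_g) q_g(kappa_g | D_g)

where phi collects the global parameters (mu_bp, s2_bp, sigma_u^2,
pi0) with Normal / inverse-gamma / Beta factors, q(D_g) is Bernoulli
with null probability p_g, and the per-gene block over
kappa_g = (beta_g0, beta_g1, beta_g2, W_g, u_g1..u_gN) is a full
multivariate Gaussian *conditional on the indicator*: one Gaussian of
dimension 4 + N given D_g = 0 (non-null; the slab W_g enters the
linear predictor), and one of dimension 3 + N given D_g = 1 (null; the
slab decouples and its conditional factor is the prior matched to the
current hyperparameter moments, available in closed form).

Conditioning the gene block on the indicator is deliberate.  With a
single Gaussian shared by both branches, the coordinate-ascent fixed
point for q(D_g) degenerates: the expected-log-likelihood contrast
between branches grows linearly with counts while the only interior
force is the Bernoulli entropy (at most ln 2), so p_g collapses to
0 or 1 for all but exactly tied genes.  Hard indicators destroy the
calibration of the posterior null probabilities that the Bayesian FDR
rule depends on.  The branch-conditional family keeps, in the q(D_g)
update, the difference of per-branch *free energies* (expected
log-joint plus Gaussian entropy), which contains the evidence (Occam)
penalty for the extra slab dimension; on single-gene instances with
fixed hyperparameters the resulting p_g agrees with the exact
posterior to two decimal places.

### Updates

Global and indicator factors are conjugate and updated in closed form:

* q(sigma_u^2): inverse-gamma with shape alpha_u + GN/2 and rate
  gamma_u + (1/2) sum E[u_gi^2];
* q(s2_bp): shape alpha_bp + G/2, rate gamma_bp +
  (1/2) sum_g E[(beta_gp - mu_bp)^2] (the slab W_g for p = 3); the
  expectations mix the two branches with weights (p_g, 1 - p_g);
* q(mu_bp): Normal with precision 1/sigma2_mu + G E[1/s2_bp];
* q(pi0): Beta(a0 + sum p_g, b0 + sum (1 - p_g));
* q(D_g): p_g = logistic( E[ln pi0] - E[ln(1 - pi0)] +
  FE_null(g) - FE_alt(g) ), the FE's being the branch free energies.

The Gaussian blocks are not conjugate to the Poisson likelihood and are
updated by non-conjugate variational message passing.  Writing the
factor in natural-parameter form (precision-times-mean, -1/2 precision)
the fixed-point map simplifies, for a Gaussian N(m, S) and objective
F(m, S) = E_q[ln p(y, theta)], to

    S_new^-1 = -2 dF/dS        m_new = m + S_new dF/dm.

For the Poisson terms, E_q[exp(eta)] is the Gaussian
moment-generating-function evaluation exp(a'm + a'Sa/2) with the
observation's selector vector a, so

    S_new^-1 = sum_k w_k a_k a_k' + R
    dF/dm    = sum_k (y_k - w_k) a_k - R (m - mu_bar)

with w_k the expected rates, R the diagonal of expected prior
precisions (E[1/s2_bp], E[1/sigma_u^2]) and mu_bar the expected prior
means.  The proposed precision is a sum of positive-semidefinite
rank-one terms plus a positive diagonal, hence always positive
definite.  At a fixed point the update reproduces the mode and
curvature of the Laplace approximation to the conditional posterior up
to the (small) smoothing induced by a'Sa/2; this is verified against a
numerical-optimization oracle in the tests.

Steps are damped on the natural-parameter scale,
lambda <- (1 - rho) lambda_old + rho lambda_new with rho = 0.5 by
default; a convex combination of positive-definite precisions remains
positive definite, so damping cannot break the factor invariants.

### Outer loop, ELBO and convergence

One iteration updates all gene blocks (both branches), then all
indicators, then the global factors, and finally evaluates the ELBO
E_q[ln p(y, theta)] - E_q[ln q(theta)], which is available in closed
form for these families.  Conjugate updates cannot decrease the ELBO;
NCVMP steps carry no such guarantee, so if an iteration ends below the
previous ELBO (beyond 1e-8 relative) it is re-run from the previous
state with halved damping, which restores monotonicity in the limit.
In practice backtracking almost never triggers, and the shipped test
suite checks monotonicity to 1e-6 relative across 50 jittered
initializations.

The loop stops when the absolute ELBO change falls below the tolerance
(default 1e-4, plus a 1e-8 relative term) or after max_iterations
(default 100); hitting the cap flags the result as non-converged
without raising.  Typical fits (2000 genes, 4-16 samples) converge in
20-40 iterations, about a second on one CPU.

### Initialization and numeric guards

Gene-block means start from log(count + 0.5) cell averages mapped to
the coefficients; sample effects start at zero with variance 0.25 so
the random-effect scale can adapt either way; coefficient variances
start at 0.05.  Hyperparameter factors are moment-matched to the
spread of the initial coefficients; p_g starts at the prior mean of
pi0.  Initialization is deterministic; an optional seed-controlled
Gaussian jitter (init_jitter_sd) supports multistart diagnostics.  All
exp() arguments inside expected rates are clipped at 30 natural-log
units (configurable) with a logged warning; the same clipped value is
used in updates and ELBO so the objective stays consistent.

## Multiple testing

Given posterior null probabilities p_1..p_G, rejecting when p_g < c
has estimated Bayesian FDR equal to the mean p_g over the rejected
set; the level-alpha threshold c* is the supremum of admissible c,
located by scanning the running means of the sorted probabilities.
The inequality is strict, so genes tied exactly at c* are not
rejected.  An optional effect-size filter keeps only genes with
|posterior mean TE change| above a log2-scale cutoff (0.5 is
conventional); it is applied after thresholding and the FDR is not
recomputed, so the reported level refers to the unfiltered rule.
Effects are reported on both the natural-log model scale and the log2
reporting scale (conversion ln 2).

## Simulators

Three generating schemes with recorded ground truth:

* **A (Poisson)** — exactly the fitted model.  Defaults:
  beta_g0 ~ N(5, 1) (natural-log scale, i.e. baseline counts around
  150), beta_g1, beta_g2 ~ N(0, 0.5^2), slab W_g ~ N(0, 0.75^2),
  pi0 = 0.8, sigma_u = 0.35.  These constants are the package's
  stand-ins for what one would estimate from a real paired dataset,
  and are fully configurable.
* **B (negative binomial)** — same mean structure, NB emission with
  gene dispersions drawn from LogNormal(ln 0.1, 0.5^2) (or a
  user-supplied pool), standing in for empirical dispersion estimates.
* **C (fold-change perturbation)** — separate baseline mRNA and RPF
  means per gene from a negative binomial (mean 200, dispersion 0.3);
  multiplicative fold changes from a shifted gamma (shape 0.6, scale
  0.5, shift 1.5, so every change is at least 1.5-fold and the mean is
  1.8) applied to the treatment means of three disjoint random subsets
  (mRNA only, RPF only, both; 10% of genes each); a shared lognormal
  sample effect multiplying each mRNA/RPF pair; NB emission with
  dispersion phi(mu) = 0.1 + 1/mu.  A gene is labeled a true DTG
  exactly when its RPF:mRNA ratio differs between conditions: the
  mRNA-only and RPF-only subsets are DTGs, and the "both" subset with
  one shared fold change is null (an option draws the two fold changes
  independently, which makes those genes DTGs instead).

What the simulators do *not* emulate: library-size differences between
columns (no offsets are simulated), zero inflation, gene-gene
correlation, positional/codon-level structure, and fold-change
distributions estimated from any particular organism.  Passing
benchmarks on these schemes therefore demonstrates correctness of the
inference machinery and calibration under the stated generative laws,
not performance guarantees on any specific real dataset.

## Benchmarking

`run_benchmark` simulates R replicate studies (seeds spawned from one
master seed), fits each, scores genes by 1 - p_g, and reports per-
replicate AUC (equal to the Mann-Whitney concordance statistic) plus
the realized false discovery proportion of the Bayesian FDR rule at a
grid of nominal levels.  Replicates with zero rejections contribute
FDR 0 to averages (configurable to "exclude").  ROC curves are
averaged vertically on a fixed 101-point FPR grid.  Reported spreads
are across-replicate standard deviations.

The shipped calibration experiment (also `scripts/acceptance.py`) uses
scheme A with 2000 genes, 2 replicates per condition and 20 simulation
replicates — sizes chosen so the full suite runs in minutes on one CPU
while leaving Monte-Carlo standard errors around 0.003 on the realized
FDR.  Representative results: mean realized FDR 0.048 at nominal 0.05
and 0.098 at nominal 0.10; mean AUC 0.907 (n = 2) rising to 0.945
(n = 4); sign agreement of the estimated TE change with truth above
95% among non-null genes.

## Known limitations

* **Two conditions only.**  The design machinery is written around the
  2 x 2 condition-by-preparation layout; richer designs would need new
  design-matrix construction but no change to the engine.
* **Small-panel hyperparameter bias.**  With very few genes (of order
  ten or fewer) the mean-field treatment of the hyperparameters —
  effectively point-massing the slab variance, pi0 and sigma_u^2 —
  biases p_g toward over-confident values relative to the exact
  posterior, because the exact posterior averages over strong
  dependence between those hyperparameters and the indicators.  The
  test suite quantifies this against a long-run MCMC reference on a
  3-gene instance (where the discrepancy is visible) and verifies that
  at realistic panel sizes (hundreds to thousands of genes) the
  posterior probabilities are calibrated well enough for the realized
  FDR to track nominal levels.
* **Posterior effect shrinkage.**  Estimated TE changes are shrunk
  toward zero by the hierarchical prior and by averaging over the
  null indicator; rankings and decisions are calibrated, but effect
  magnitudes are conservative, increasingly so for genes with high
  null probability.
* **No normalization by default.**  The bare model has no library-size
  term; the optional depth offset should be enabled when column totals
  differ by large factors.
* Batch (full-data) updates only; no stochastic/minibatch variant.
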