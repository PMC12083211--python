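# Methods

## Model

`gshlm` estimates a two-level random-intercept hierarchical linear model
(HLM) in which the outcome and a vector of continuous *cluster-level*
covariates may be missing, and the partially observed covariates may carry
interaction effects:

    Y_ij = b0 + bC' C_j + bX' X_ij
           + sum_s bXC_s' (X_ij * C_sj)
           + sum_{s<t} bCC_st C_sj C_tj
           + u_j + e_ij,
    u_j ~ N(0, tau),  e_ij ~ N(0, sigma2),

for unit i = 1..n_j in cluster j = 1..J.  `X_ij = (x1_ij, x2_j)` collects the
fully observed level-1 and level-2 covariates.  The partially observed
covariates follow a joint normal covariate model given the known level-2
covariates,

    C_j | x2_j ~ N(W_j alpha, T),   W_j = I_p (x) (1, x2_j'),

and the missingness is assumed missing at random (MAR).  The joint model
factorizes as prod_ij f(Y|C,X,u) * prod_j f(u|tau) f(C|x2) * priors, which is
what makes every full conditional available in closed form.

Because C enters Y nonlinearly (products C_s C_t and X C_s), the joint
distribution of (Y, C) is *not* multivariate normal even though each
factor is.  Chained-regression (FCS) imputation, or Metropolis proposals
with a fixed variance, can therefore be incompatible with this joint model.
The point of the sampler here is that every missing value and every
parameter is drawn from its exact conditional under the one coherent joint
model above — compatibility by construction, no accept/reject step.

## The Gibbs cycle

Priors: flat on beta and alpha; tau, sigma2 ~ IG(a0 = 1, b0 = 0.5) written
so that the posterior rate is (sum of squares)/2 + 1/b0 (prior rate 2);
T ~ IW(V0 = p + 2, S0) with S0 the complete-case residual covariance of C on
(1, x2) (identity fallback when complete cases are scarce).

Each cycle updates, in order:

1. `u_j | .  ~ N(D_j^-1 s^-2 sum_i (Y_ij - Xrow'b), D_j^-1)`, `D_j = n_j/s^2 + 1/tau`
2. `tau | .  ~ IG(J/2 + a0,  sum_j u_j^2/2 + 1/b0)` (shape, rate)
3. `beta | . ~ N((X'X)^-1 X'(Y - u), s^2 (X'X)^-1)`
4. `s^2 | .  ~ IG(N/2 + a0,  sum e_ij^2/2 + 1/b0)`
5. missing `Y_ij` drawn from the posterior predictive `N(Xrow'b + u_j, s^2)`
6. `alpha | . ~ N((sum W'T^-1 W)^-1 sum W'T^-1 C_j, (sum W'T^-1 W)^-1)`;
   with the Kronecker structure of W the precision is `kron(T^-1, sum w_j w_j')`
7. `T | . ~ IW(V0 + J, S0 + sum (C_j - W alpha)(C_j - W alpha)')`
8. each missing `C_kj` from its exact univariate normal posterior, obtained by
   conditioning the covariate model (`C_kj | C_(-k)j ~ N(M_cond, T_cond)`) and
   completing the square over the n_j outcome likelihood terms:

       Delta_kj = 1/T_cond + sum_i mu2_ij^2 / s^2
       M_kj     = (M_cond/T_cond + sum_i mu2_ij (Y_ij - mu1_ij) / s^2) / Delta_kj

   where the linear predictor is split as `mu1_ij + mu2_ij C_kj` (mu1
   excludes C_kj, mu2 multiplies it).  Because the predictor is exactly
   linear in C_kj, the split is computed algebraically by evaluating it at
   C_kj = 0 and 1 rather than transcribing the coefficient-by-coefficient
   formula.  The scan is systematic, k = 1..p, and a value imputed for C_sj
   (s < k) is used immediately when C_kj is drawn; clusters are processed
   in index order (they are conditionally independent given theta, so the
   within-k updates are vectorized).

Two numerical choices to note.  The i-summation in Delta_kj is carried over
all n_j units: mu2 depends on i whenever level-1 covariates interact with
C_k; when they do not (as in all the simulation scenarios), mu2 is constant
within a cluster and the expression reduces to `n_j mu2^2 / s^2`.  Draws are
never clipped; Cholesky factorizations operate on the closed-form precision
matrices, and a failure surfaces as an error naming the cycle rather than a
silent repair.

## Chain management and engines

Defaults: 2,500 burn-in + 2,500 retained iterations, two chains.  Chain 1
initializes missing values by observed-case regression (C on (1, x2); Y on
the completed design), chain 2 by plain sample means; both then initialize
theta from a complete-data least-squares/moment fit.  No thinning is
applied.  Retained draws are theta = (beta, tau, sigma2, alpha, vech T);
random intercepts and imputed values can be stored behind
`SamplerConfig(store_extras=True)`.

Two interchangeable engines implement the identical cycle: a pure-Python
reference that composes the eight public step functions, and a
numba-compiled kernel (~30x faster) used by default for replication
studies.  The kernel draws the inverse Wishart by the Bartlett
decomposition since compiled code cannot call scipy; the test suite checks
the kernel against the reference engine, the step functions against
hand-derived conditional parameters, and the step-8 draw against numeric
grid integration of the one-cluster joint density.  The engines consume
randomness differently, so they reproduce each other statistically, not
draw-for-draw; each is deterministic given its seed.

## Convergence diagnostics

* Geweke Z per chain: two-sample Z between the first 20% and last 50% of
  the retained draws, with segment variances estimated by a Bartlett-window
  spectral density at zero (window width floor(sqrt(n)) — the standard
  choice; a calibration test guards it).
* PSRF across the two chains: the classic Gelman-Rubin estimator
  sqrt(((n-1)/n W + B/n)/W) on full chains, no splitting or
  rank-normalization, matching the original criterion it implements.

A fit is declared converged when all HLM parameters (fixed effects, tau,
sigma2) satisfy the criterion; PSRF < 1.1 is the recommended rule.  Testing
seven parameters at the 5% level makes the Geweke criterion reject ~30%
of the time even at stationarity (1 - 0.95^7 = 0.30), which the diagnostics
report makes visible rather than hiding.

## Synthetic-data generator

The generator reproduces the replication study's four scenarios; its
defaults are the study conditions, not tuning knobs.  All scenarios use
X_j ~ N(2, 1), every HLM coefficient 1, tau = 4, sigma2 = 16, and n_j = 4
units per cluster (J = 36 "small" or J = 200 "large"):

* `correct` — C1 ~ N(0.75 + 0.7 X, 1.25), C2 ~ N(-0.5 + X, 1) with
  conditional covariance -0.5; Y mean 1 + C1 + C2 + X + C1 C2.
* `lognormal` — C1 ~ logNormal(0.5 + 0.1 X, varlog 0.2), i.e. mean ~2.24,
  variance ~1.17, skewness ~1.6, violating the covariate normality the
  sampler assumes.  (Reading the second parameter as the log-scale *sd*
  would give skewness 0.69, inconsistent with the intended shape; the
  variance reading matches the N(mean, variance) convention used
  throughout.)  C2 ~ N(1 + 0.1 C1 + 0.3 X, 1).
* `mnar` — data as in `correct`, but C1 and C2 are deleted with
  logit(p_j) = d0 + d1 C1_j evaluated at the *pre-deletion* C1
  (d = (-5, 1.3) for C1, (-10.5, 3) for C2): missing not at random.
* `extra` — Y mean adds C1 X + C2 X, two additional partially observed
  interactions.

MAR deletion draws one probability per cluster from
logit(p_j) ~ N(c0 + c1 X_j, delta) with delta a variance (Y: c0 = -1.9,
c1 = 0.1, delta = 1; C1: 0.8, -1.5, 0; C2: -2.8, 0.5, 0).  Cluster-level
covariates are deleted for the whole cluster; outcome cells are deleted
independently within the cluster at the shared p_j.  These settings produce
marginal missing fractions of about 19% (Y), 17% (C1) and 15% (C2) — the
study describes all of them as "approximately 20%".  Y is generated through
explicit u_j and e_ij draws (distributionally identical to the collapsed
N(mean, tau + sigma2) form) so random-effect recovery is testable, and
deleted values are retained behind the masks so estimates can be scored
against the truth.

What the generator does *not* emulate: unbalanced cluster sizes (supported
by the sampler, fixed at n_j = 4 in the study), categorical or level-1
partially observed covariates, and any missingness in X.  Passing tests
therefore demonstrate correctness under these stylized conditions, not
robustness on arbitrary real data.

## Replication harness and metrics

`run_study` repeats simulate -> (benchmark fit) -> delete -> Gibbs -> score,
with replicate r seeded as base_seed + r and chain seeds derived from it.
Per parameter it reports

* %bias = (mean point estimate - truth) * 100 / truth (posterior mean as
  the point estimate; absolute bias with a flag when truth = 0),
* ASE = mean of per-replicate posterior sds / standard errors,
* ESE = sd of the point estimates across replicates (denominator R - 1),
* coverage = fraction of replicates whose 95% interval contains the truth
  (equal-tailed 2.5/97.5 percentile credible intervals; Wald for the
  benchmark),

plus per-criterion convergence rates, with all replicates included
(converged or not) as the study found the two sets indistinguishable.
The Monte-Carlo SE of every %bias entry is reported alongside: with the
intercept's per-replicate sd around 1.9 (truth 1), %bias estimates carry
~8 points of noise even at R = 500, and comparisons are only meaningful
within ~2 such SEs.

The complete-data benchmark (CDML) is a random-intercept mixed model fit by
statsmodels MixedLM on the pre-deletion data.  It uses REML by default: under
straight ML the tau estimator at J = 36 with five fixed effects is biased
roughly -25% (no degrees-of-freedom correction, plus boundary pile-up at
tau = 0), whereas the REML benchmark is near-unbiased — the behaviour of the
standard mixed-model software this column emulates; `reml=False` remains
available.  Fixed-effect SEs come from the mixed-model fit; SEs for
(tau, sigma2) come from a finite-difference observed information of the
closed-form (restricted) likelihood, because MixedLM reports
variance-parameter uncertainty on a transformed scale.

## Problem sizes

Replication runs in the test suite and the acceptance script use reduced
scale chosen as a deliberate design point: 500 burn-in + 1,000 retained
iterations and R = 200 (large-sample coverage/convergence studies) or
R = 500 (small-sample %bias studies) replicates, against the original
2,500 + 2,500 and R = 1,000-5,000.  The large-sample study runs two chains
per replicate (PSRF needs a pair); the small-sample %bias studies run one
chain per replicate, since the sampling distribution of a pooled-chain
posterior mean and a single-chain posterior mean coincide.  At these scales
every check is tolerance-matched to its own Monte-Carlo error rather than
to the published table's nominal precision.

## Known limitations

* Random intercept only (no random slopes); two-level structures only.
* Partially observed covariates must be continuous and cluster-level;
  level-1 covariates and X must be fully observed.
* The covariate model is joint normal; the lognormal scenario quantifies
  the bias a moderate violation induces (intercept ~ +11%, main effects
  ~ -7 to -9% at J = 36) rather than removing it.
* MNAR robustness is probed under a single logit-in-C1 mechanism; other
  violations are out of scope.
* The Geweke windows (20%/50%) and the Bartlett spectral window are fixed
  conventions, not estimated.
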