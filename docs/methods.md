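# Methods

`dcinbreed` implements a two-step errors-in-variables analysis of inbreeding
depression for long-lived, individually monitored animals genotyped at
codominant markers. Step 1 estimates each individual's inbreeding
coefficient F_i from multilocus microsatellite genotypes and summarizes its
posterior as a Beta measurement distribution. Step 2 regresses fitness
responses on F_i by maximum likelihood, with the Beta uncertainty carried
through as a latent covariate, fitting by data cloning and comparing models
evidentially.

## Step 1: inbreeding coefficients from genotypes

### Model

At locus l with allele frequencies p_l, an individual with inbreeding
coefficient F_i carries two alleles that are identical by descent (IBD) with
probability F_i. Latent indicators x_il mark IBD loci: a heterozygote has
x_il = 0; a homozygote for allele m is IBD with conditional probability

    q = F p_lm / (F p_lm + (1 - F) p_lm^2).

The Gibbs cycle uses three conjugate blocks:

* x_il | F, p — independent Bernoulli(q) draws at homozygous typed loci,
  with q's F clamped to [1e-5, 1 - 1e-5] for numerical safety;
* F_i | x — Beta(a + s_i, b + L_i - s_i), where s_i = sum_l x_il, L_i is
  the typed-locus count, and (a, b) = (1, 1) is the Bayes–Laplace prior
  (a flat prior; sharper "noninformative" choices such as Jeffreys are
  informative precisely in the no-IBD corner that dominates outbred
  samples);
* p_l | x — Dirichlet(1 + Z_l), where Z_lm counts allele copies identical
  by state that are not also IBD: a heterozygote contributes one copy of
  each allele, a non-IBD homozygote two copies, an IBD homozygote one.

Loci are assumed unlinked and independent; missing calls drop the locus for
that individual and L_i is the typed count.

### Data cloning and the collapsed clone representation

The sampler is run on K stacked copies of the genotype data for
K = 1, 5, 10, 20, 40. F_i and p_l are structural (shared across clones);
the x indicators are latent and cloned. Because the K clone indicators for
one (individual, locus) cell are iid Bernoulli(q) given (F, p), the sampler
stores clone 0's indicator plus a Binomial(K - 1, q) sum for the rest. This
is an exact sufficient-statistic collapse — the invariant distribution is
unchanged — and makes the sweep cost independent of K. Clone 0's per-sweep
IBD count s_i (bounded by L_i) supplies the posterior count histogram.

### Beta summarization

At the final clone level the modal IBD count k_i (ties: arithmetic mean of
all modes) parameterizes the measurement distribution by the Bayes–Laplace
conjugate update of a binomial count:

    F_i ~ Beta(A_i, B_i),  A_i = 1 + k_i,  B_i = 1 + L_i - k_i.

Defaults follow the step's standard settings: 3 chains, 10,000 iterations,
burn-in 5,000, thinning 5, with Gelman–Rubin R-hat reported per F_i and a
warning above 1.1.

### Precision limits

At microsatellite heterozygosities (~0.7 per locus) identity by state masks
part of the IBD signal, so the per-individual standard error at L = 200
loci is about 0.042 — noticeably above the naive binomial
sqrt(F(1-F)/L) ≈ 0.031 — and at the study scale of L = 29 loci individual
estimates only correlate loosely with truth (r ≈ 0.5–0.7 in simulation,
the weak-marker regime). This is an information bound of the model, not a
sampler artifact; the tests check bias and group separation against it.

## The individual fitness statistic r_i

Each female's realized life table defines a Leslie matrix with unit
survival through her last pup age and fecundity 1 at each pup age; the
matrix places a pup born at maternal age a with generation lag a - 1, so
the characteristic equation is sum_a lambda^-(a-1) = 1. r_i is the natural
log of the dominant eigenvalue. This is the unique simple convention for
which a single pup gives r_i = 0 exactly and the maximal 19-year schedule
(maturity at 4, a pup every year to 19) gives the upper censoring bound.
Under it the maximal schedule computes to 0.381813, about 4e-4 below the
reference constant 0.3819509 used for the censoring bound; the residual is
within every tolerance used here and the constant is retained as the bound.

The dominant eigenvalue is found by power iteration on M + I (the shift
makes periodic schedules — e.g. a pup exactly every second year — primitive),
with stationarity required for 50 consecutive iterations at 1e-14; an
independent Brent-root of the characteristic equation cross-checks it to
1e-10 in the tests.

## Step 2: fitness families

All four families share the linear predictor

    eta = b0 + (b1 + theta_Y) F + b2 Col + b3 F Col + b4 First + gamma_Y

with colony indicator Col, birth-year random intercept gamma_Y ~ N(0,
sigma_gamma^2), and (outside the r_i family) a year random slope on F,
theta_Y ~ N(0, sigma_theta^2).

* **r_i** — Normal(mu = eta, sigma_r), truncated below 0 (only mothers are
  sampled) and censored above 0.3819509.
* **death** — age at death d ~ Geometric in the annual survival s, pmf
  s^d (1 - s), link log((1-s)/s) = eta; alive at the 19-year horizon
  contributes the survivor mass s^19. The parameterization makes the link a
  log-mean link (mean years survived = e^-eta). Observed deaths are not
  renormalized over [4, 19]; a `left_truncate` switch conditions on
  survival to age 4 for sensitivity work.
* **afr** — age at first reproduction minus 4 ~ NB(4, p), link
  log(4(1-p)/p) = eta (mean afr = 4 + e^eta).
* **wait** — pupping interval minus one year ~ Geometric(pi), link
  log((1-pi)/pi) = eta, with the FIRST term separating the interval after a
  female's first pup (parallel-lines model).

Priors are deliberately flat: N(0, 10^4) on coefficients (the r_i intercept
truncated to (0, 0.3819509)); half-Cauchy(0.013) on sigma_r and
half-Cauchy(0.004) on sigma_gamma in the r_i family (fixed constants, not
recomputed from data); Uniform(0, 100) scales elsewhere. Starting values
follow each family's recipe, including the ratio-of-normals constructions
sigma_r = xi/chi and sigma_gamma = zeta/tau, redrawn until inside the prior
support. Data cloning washes out all of these as K grows.

## Data-cloning engine

The sampler is Metropolis-within-Gibbs: scalar random-walk updates for each
structural parameter — scale parameters move on the log scale with the
Jacobian correction, since their posteriors span orders of magnitude from
the overdispersed starts — and vectorized elementwise random-walk updates
for the latent blocks (F per clone x individual; gamma, theta per clone x
year). Proposal scales adapt toward a 20–50% acceptance rate in windows of
50 sweeps and freeze at the burn-in cutoff, preserving detailed balance for
every retained draw. Clones live on the leading axis of the latent arrays;
`clone_dataset` materializes the equivalent row-replicated dataset.

The MLE is the pooled posterior mean at K_max = 40 (a maximum-a-posteriori
extraction from the best draw is available); its covariance is K_max times
the pooled posterior covariance. Convergence requires the scaled variance
(posterior variance at K_max relative to K = 1, averaged over free
parameters) below 0.05 — note this is unattainable for K_max < 20 by
construction — and all R-hat below 1.1. Diagnostics follow the standard
data-cloning checks: the largest eigenvalue of the final posterior
covariance, a chi-squared Q-Q comparison of Mahalanobis distances
(ms-error and an r-squared fit statistic) for multivariate normality, and
the slope of log scaled variance against log K (≈ -1 for identifiable
parameters). Non-convergence is a reported state: the model is retained in
outputs but excluded from criterion tables.

### Marginal likelihood

Information criteria need the likelihood with latents integrated out. Each
F_i integral against Beta(A_i, B_i) uses Gauss–Jacobi quadrature with the
Jacobi weight matched to the Beta exponents, so the measurement density is
treated exactly and only the smooth likelihood factor is approximated
(64 nodes, with a node-doubling convergence check at 1e-6); for very
concentrated Betas (A + B > 600), where the Jacobi recurrence loses
accuracy, the integral substitutes the Beta quantile function and applies
Gauss–Legendre on the probability scale. Year random effects are integrated
by a Laplace approximation over the stacked (gamma, theta) vector, with an
importance-sampling validator from the Laplace proposal. The tests verify
the quadrature against brute-force trapezoid integration (1e-6) and the
Laplace result against importance sampling.

### Bands

Confidence bands draw 10,000 coefficient vectors from MVN(mle, cov_mle)
and take pointwise 2.5/97.5% quantiles of the fitted mean response on a
grid of 1,000 equally spaced F values on (0, 0.25); prediction bands
additionally simulate one response per draw from the fitted family (the
r_i family respecting truncation and censoring). Non-PSD covariances are
repaired by eigenvalue clipping at 1e-12, with a warning.

## Model selection

BIC = -2 logL + k ln n and AICc = -2 logL + 2k + 2k(k+1)/(n-k-1), with k
counting regression parameters (plus the residual SD for r_i) and not
random-effect hyperparameters — a deliberate convention, recorded in the
table footnote. n is the number of individuals for r_i/death/afr and the
number of intervals for the wait family (the likelihood's independent-unit
count). Criterion differences below 2.77 are flagged evidentially
equivalent; ties in the minimum break toward the smaller k. Under a null
truth (b1 = 0) the extra-parameter penalty makes the expected Delta-BIC of
the INB model about ln n - chi2_1 (≈ 4 at n = 154), so the "equivalent"
band is typically entered on the AICc scale rather than the BIC scale; the
null-evidence test asserts exactly that pattern.

## Synthetic data

The generator emulates the study design: 154 females, 29 microsatellite
loci with 4–15 alleles (Dirichlet(1) frequency simplexes), birth years
1980–1992, a Dellbridge-colony probability of 0.5, and a two-point
inbreeding mixture (90% F = 0, 10% F = 0.25 — a mostly outbred wild
population; a Beta option exists for conjugacy tests). Genotypes are drawn
by the IBD mechanism itself (with probability F_i one parental allele is
copied). Life histories are generated from the death/afr/wait families;
individuals dying before a first pup are redrawn — mothers only, matching
the sampling frame — with the redraw count logged. A direct-response mode
draws r_i from the truncated-censored normal for clean regression recovery
tests.

Default coefficients put the natural-scale quantities at values typical of
a long-lived phocid: annual adult survival 0.945, mean age at first
reproduction 7.39 y, probability 0.548 of pupping the year after the first
pup with the post-first-pup wait 2.08x longer, and a weak fitness slope
b1 = -0.1056 per unit F. Residual and year-effect scales (sigma_r = 0.05,
sigma_gamma = 0.01) are the package's own choices of a realistic spread,
since no data-level dispersion values are available to copy.

What the generator does not emulate: linkage between loci, genotyping
error and null alleles, age-varying survival, density dependence, or
pedigree structure. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
their violation.

## Problem sizes used in the checks

Heavy checks are run at deliberately scaled-down settings chosen to keep
Monte-Carlo error well inside the asserted tolerances: the two-step
recovery check uses 20 replicates of n = 154 females x 200 loci with
2-chain, ~1,000-iteration samplers and the clone pair {1, 40}; the
null-evidence check uses 25 replicates with the closed-form binomial
measurement summarization in place of the genotype sampler. The full
defaults (3 chains, 10,000–20,000 iterations, schedule 1/5/10/20/40) are
what `estimate-f` and `fit` run.

## Known limitations

* The step-1 modal-count summarization compresses each F_i posterior to a
  conjugate Beta; multimodality is averaged, and between-individual
  posterior correlation (through shared p_l) is discarded.
* The Laplace approximation for year effects is unvalidated outside the
  regimes exercised in tests; the importance-sampling validator is provided
  for spot checks.
* Wald intervals inherit the usual asymptotic caveats and are refused for
  non-converged fits rather than patched.
* The discrete families' responses are treated as exact ages/intervals;
  observation error in field ages is not modeled.
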