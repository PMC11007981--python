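# Methods

## The problem

A cis-eQTL study tests, for each of N genes, whether any of the m_i SNPs
local to the gene is associated with its expression — a grouped-hypothesis
problem in which the gene-level null H_0i is the intersection of the m_i
per-SNP nulls. The packaged methods control the gene-level false discovery
rate (FDR) through an empirical-Bayes two-group mixture with a
random-effects model for causal effect sizes, rather than through p-value
combination or permutation of an extreme-value statistic.

## Model

Let Y_i (length n, residualized on covariates and standardized) be the
expression of gene i and X_j its standardized SNP dosage rows. The model
assumes:

* **A1** — under the gene-level alternative there is exactly one causal
  SNP in the group;
* **A2** — the causal position is uniform over the m_i SNPs;
* a two-group prior: P(H_0i) = pi0.

Under the null, Y_i ~ N_n(0, I). Given causal SNP j with correlation
beta, Y_i ~ N_n(beta X_j, (1 − beta²) I), which keeps the unconditional
variance of Y_i equal to 1. Effect-size heterogeneity across genes enters
through a random effect on the variance-stabilized (Fisher) scale:

    sqrt(n − 3) · atanh(beta) ~ N(0, sigma²).

The two estimable parameters are therefore `pi0` (prior null probability,
in [0, 1]) and `sigma` (SD of the Fisher-scale effect, ≥ 0; eQTL data
typically show sigma well above 2).

The gene-level local false discovery rate (lfdr) is the posterior null
probability; the SNP-marginal density p(X^{(i)}) cancels from its
numerator and denominator, so no model of SNP dependence is needed.

### Full-data route (REG-FDR)

The marginal alternative density f1(Y_i | X_j) integrates the conditional
Gaussian against the Fisher-scale prior over beta in (−1, 1). Substituting
t = sqrt(n−3)·atanh(beta) turns this into a Gaussian integral in t that we
evaluate by *posterior-centered* Gauss–Hermite quadrature (below).
(pi0, sigma) are estimated by EM over the latent null indicator and causal
index: the E-step yields per-gene posterior null probabilities and softmax
causal responsibilities; the M-step updates pi0 in closed form (mean
posterior null probability) and sigma by bounded 1-D search. The
observed-data composite log-likelihood is asserted non-decreasing at every
iteration (slack 1e-8 relative), and the fixed point matches a direct
two-parameter numeric maximization of the same objective (tested).

Because different genes' expression vectors are treated as independent
given genotypes, the objective is a composite likelihood; the estimates
remain consistent under cross-gene dependence.

### Summary-statistic route (Z-REG-FDR)

For each gene–SNP pair, z = sqrt(n−3)·atanh(r) with r the (partial)
Pearson correlation; z is approximately N(0, 1) under the per-pair null
and N(mu, 1) under the alternative with mu ~ N(0, sigma²), so the causal
z's marginal is N(0, 1 + sigma²). Under the additional assumption **A3**
(the conditional law of the non-causal z given the causal one is the same
under null and alternative) the group dependence cancels from both the
gene-level lfdr,

    lfdr_i = 1 / (1 + (1−pi0)/pi0 · (1/m_i) · Σ_k p1(z_k)/p0(z_k)),

and from the pseudo-likelihood
Σ_i log(pi0 + (1−pi0)·(1/m_i)·Σ_k p1(z_k)/p0(z_k)), which is maximized
over (pi0, sigma). Only z-statistics (indeed only |z|) are needed —
no raw data, no sample size beyond the transform, no LD information.

### Decision rule

Sort gene lfdr ascending and reject the largest prefix whose running mean
is ≤ the target level alpha (ties broken by original index; stable). The
running mean of the rejected set is its estimated FDR, so the rule spends
the full budget; the averaging identity FDR = E(lfdr | rejected) makes it
valid for the oracle and asymptotically for the plug-in fit.

## Numerical choices

* **Pseudo-likelihood maximization**: L-BFGS-B on (logit pi0, log sigma)
  with analytic gradients, box pi0 ∈ [1e-6, 1−1e-6], sigma ∈ [1e-4, 50];
  multi-start from (0.5, 1), (0.5, 3) and a method-of-moments start built
  from the |z| > 2 exceedance fraction and the mean z². The small-sigma
  ridge is flat (nulls and tiny effects are indistinguishable), hence the
  multi-start and a boundary warning when sigma lands on its lower bound.
  Objective tolerance 1e-9 (configurable). All mixture sums are log-space
  (per-gene log-sum-exp over SNPs).
* **Quadrature**: the random-effect integral is evaluated with
  Gauss–Hermite nodes centered, per gene–SNP pair, at the Gaussian-product
  mean t̂·sigma²/(1+sigma²) with scale sigma/sqrt(1+sigma²), where t̂ is
  the observed Fisher statistic. Centering on the prior alone
  under-resolves the ~unit-width conditional likelihood once sigma is
  large (relative errors around 1e-2 at sigma = 5 and a visibly distorted
  likelihood surface); posterior centering is exact to machine precision
  against a 400,001-point trapezoid reference at 41 nodes, and already
  ~1e-9 accurate at 21 nodes — the EM's inner sigma search exploits this
  with a reduced order (21) while likelihood evaluations use the default
  41. Both orders are configurable.
* **Standardization**: expression and genotype rows are z-scored with the
  population (1/n) convention after residualization, making beta a plain
  correlation and f0 = N(0, I) coherent; gene-level lfdr is then invariant
  to positive rescaling of dosages (tested).
* **Degenerate inputs**: monomorphic SNPs are dropped (the gene only when
  all its SNPs are), |r| = 1 pairs are dropped with a warning, missing
  dosages are mean-imputed per SNP at file ingestion, pi0 = 0 returns
  lfdr 0 with a warning, and sigma = 0 makes the two groups identical
  (lfdr ≡ pi0).
* **All-null data**: when pi0 = 1 generates the data, (pi0, sigma) is only
  set-identified — the boundary ridge {sigma = 0} ∪ {pi0 = 1} carries a
  single distribution — so fits may stop anywhere near that ridge. The
  meaningful guarantees, asserted in tests, are no likelihood gain over
  the pure-null model and zero discoveries.

## Synthetic data

Two generators supply data with exactly the structure the model assumes;
their defaults are the published study conditions.

* **Direct-z AR(1)** (N = 10,000 genes, m = 30 SNPs/gene, pi0 = 0.2,
  rho ∈ {0.1, 0.5, 0.8}): null genes are stationary AR(1) chains with
  N(0,1) margins; alternative genes draw a uniform causal position k and
  mu ~ N(0, sigma²), set z_k ~ N(mu, 1), and grow the chain outward with
  the *null* kernel z_{j±1} | z_j ~ N(rho·z_j, 1−rho²). This makes A3
  hold by construction (equivalently: the joint is the null AR(1) law
  shifted by mu·rho^{|j−k|}), which is also why fitted-estimator
  distributions are invariant in rho — a property the published
  operating characteristics exhibit. The per-gene SNP count is not stated in the source study;
  m = 30 is the package default (a "uniform" 10–100 sampler is provided),
  and measured estimator means shift by < 0.3% across m ∈ {1, …, 450}.
* **Genotype-conditioned expression** (N = 1,000 genes scaled, n = 83,
  m = 10): dosages come from a two-haplotype latent-Gaussian AR(1) field
  thresholded at a MAF drawn from (0.1, 0.5) — Hardy–Weinberg margins
  with LD decaying in distance — a synthetic stand-in for a real,
  covariate-adjusted genotype matrix. Expression follows the three-step
  scheme: Bernoulli null draw with P(null) = pi0, uniform causal SNP,
  beta from the Fisher-scale prior, rows N(beta·x_k, 1−beta²) or N(0, 1).

What the generators do **not** emulate: realistic allele-frequency
spectra and recombination structure, covariate confounding, cross-gene
expression correlation, multiple causal SNPs, and non-uniform causal
positions. Passing tests therefore certify the estimation and FDR
machinery under the model's own assumptions (plus LD violations of A3 via
the genotype scheme), not robustness to every feature of real tissue
data.

## Replicate studies and problem sizes

The packaged experiment runner uses 200 replicates per cell for the
direct-z study (the source used 1,000) and reports Monte-Carlo standard
errors so comparisons remain calibrated; 100 paired datasets for the
full-data vs summary agreement study; and 5 replicates with B = 400–500
permutations for the power comparison. `scripts/acceptance.py` runs 100
replicates per cell by default (flags expose the full sizes). Realized
FDR is reported as the mean false-discovery proportion across replicates
(the pooled variant is available from the per-replicate table).

## Known limitations

* The estimator here is near-unbiased at the published design points
  (e.g. mean sigma_hat 5.004 ± 0.003 at truth 5); the source reports
  slightly downward-biased means (4.9383) whose origin appears to be
  implementation detail of their optimizer rather than the model, so
  exact reproduction of those means is not expected.
* Permutation min-p shares one permutation stream across genes (standard
  eGene practice; documented trade-off of speed vs cross-gene
  independence of the null draws).
* Small-sample inference uses the sqrt(n−3) scaling without adjusting n
  for removed covariate degrees of freedom; with many covariates and
  small n the null variance of z is slightly off 1.
* p-value-only import cannot recover signs; this is harmless for the
  symmetric model but makes the summary file unsuitable for directional
  downstream analyses.
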