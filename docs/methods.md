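# Methods

## The model

`microstm` treats a 16S rRNA OTU table the way a topic model treats a
document collection: each sample (document) is a mixture of K latent
*topics* — subcommunities of co-occurring OTUs — and each topic is a
distribution over the OTU vocabulary.  The generative process for sample m
with covariate row x_m (P columns, intercept included) is

    eta_m ~ N(Gamma' x_m, Sigma)          eta in R^(K-1), eta_K = 0
    theta_m = softmax([eta_m, 0])         samples-over-topics
    z_{m,n} ~ Multinomial(theta_m)        per-read topic assignment
    w_{m,n} ~ Multinomial(beta_{z_{m,n}}) per-read OTU draw

Gamma (P x K-1) carries covariate effects on topic prevalence and Sigma
(K-1 x K-1) the between-topic covariance that plain Dirichlet mixed
memberships cannot represent.  The K-th topic is the logistic-normal
reference coordinate; all of Gamma and Sigma are expressed relative to it.

Assumptions worth keeping in mind: reads are exchangeable within a sample
(no spatial or phylogenetic structure), counts are multinomial given theta
and beta (overdispersion beyond the mixture enters only through the
logistic-normal), and the covariate design affects prevalence, not topic
content.

## Inference: semi-collapsed variational EM

Token-level assignments are collapsed analytically: given eta, the
per-sample log-likelihood is sum_v c_{mv} log(theta_m' beta_{.v}).  The
E-step maximizes this plus the Gaussian prior by batched Newton steps with
an analytic gradient and Hessian, and takes a Gaussian (Laplace-style)
variational posterior N(eta_hat_m, H_m^{-1}) at the mode.  Because the
per-sample objective can be multimodal, the Newton solver is run from two
deterministic starts — the zero vector and a count-projection start — and
keeps the better mode per sample.  This makes the converged eta a pure
function of (counts, beta, Gamma, Sigma), which is why refitting the
training samples reproduces theta exactly and held-out samples are scored
reproducibly.

The M-step updates beta by the collapsed responsibility rule
(beta_{kv} proportional to sum_m c_{mv} theta_{mk} beta_{kv} / pi_{mv}),
Gamma by ridge regression of eta_hat on X (prior sd `gamma_prior_sd`,
default 5; the intercept is unpenalized), and Sigma from the posterior
second moments.  Two regularizers keep Sigma proper:

* `sigma_prior_weight` (default 0.05) shrinks Sigma toward its diagonal,
  stabilizing it when M is small;
* `sigma_max` (default 16) caps Sigma's eigenvalues.  Without a scale
  bound the logistic normal degenerates — a topic absent from a sample
  drives its natural parameter toward -inf, the residual covariance grows,
  the weakened prior lets eta drift further, and Sigma diverges across EM
  iterations.  A log-odds standard deviation of 4 already spans topic
  frequencies from essentially 0 to essentially 1, so the cap is
  weakly informative.

Initialization is deterministic: NNDSVD-seeded NMF on the
relative-abundance matrix ("spectral" style) gives beta and starting eta;
a seeded Dirichlet draw is the fallback (`init="random"`).  Convergence is
declared when the relative change of the approximate evidence bound falls
below `rel_tol` (default 1e-5, cap 500 iterations); if the approximate
bound ever decreases beyond tolerance (possible, since the Laplace bound
is not exact), iteration stops there rather than recording the decrease.

Counts may be non-integral after 16S copy-number normalization; they are
used as fractional token weights in the sufficient statistics, never
rounded (rounding happens only where a downstream count model requires
integers).

## Topic-sample effects and OTU grouping

Effects of a covariate on topic prevalence are estimated by the method of
composition: draw theta from each sample's variational posterior, regress
each topic's logit-transformed frequency on X by OLS, draw the coefficient
vector from its asymptotic normal, pool the draws, and read the interval
off the empirical quantiles (default 95%).  This propagates both
topic-frequency and regression-coefficient uncertainty.  Frequencies are
clamped to [1e-6, 1-1e-6] before the logit.  Topics whose interval
excludes 0 are the "high-ranking" topics, grouped by sign.

OTUs are assigned to effect groups by posterior simulation: in each of R
outer iterations (default 1000), every sample contributes I theta draws
(default 100), tokens are simulated (z from theta, OTU from beta), and
each OTU's winning group — the group whose topics generated it most often,
ties broken uniformly at random — scores 1.  The frequency of winning
across iterations, F_n(g), feeds a strict threshold (default 0.99) to
extract group-defining OTU sets, whose summed relative abundances can then
be regressed on clinical covariates with a negative-binomial model
(log link, log library-size offset, permutation p-values with the add-one
estimator, Bonferroni across profiles).

## Functional prediction and the pathway interaction model

Within-topic gene content follows the reference-based route: beta rows are
mapped to integer pseudo-counts (round(10000 x beta), half away from
zero — the large constant keeps low-frequency OTUs from flooring to zero),
multiplied through a reference OTU x KO copy-number table, and collapsed
onto the KEGG three-level hierarchy.  Multi-mapped KOs contribute their
full count to every parent pathway; OTUs missing from the reference are
dropped with a logged coverage fraction.

Topic x pathway counts y_{k,c} are modeled as

    y_{k,c} ~ NB2(m_{k,c}, lambda),  log m = mu + b_k + b_c + b_{k,c}

with variance m + m^2/lambda, priors mu ~ N(0, 10), weights ~ N(0, 2.5),
lambda ~ half-Cauchy(0, 5).  The decomposition is identified only through
the priors — deliberate, since interest centers on the shrunk interaction
b_{k,c}.  The metagenomic variant adds a binary diagnosis coefficient and
a log library-size offset on per-sample observations.  Posteriors are
sampled by Hamiltonian Monte Carlo with analytic gradients; warmup runs in
two phases (step-size adaptation under an identity metric, then a
full-covariance mass matrix estimated from warmup draws, then step-size
re-adaptation).  The full-covariance metric matters precisely because the
prior-identified decomposition induces strong posterior correlations.
Split-Rhat and effective sample sizes come from arviz; a warning fires
when any Rhat exceeds 1.05.  Defaults are 4 chains x 1000/1000; the test
suite runs 2 x 250-800.  No maximum-likelihood fallback exists: with one
observation per cell the saturated interaction model has no stable MLE.

Validation against shotgun metagenomics uses the RMSE between the 16S and
metagenomic interaction matrices; the null distribution permutes topic and
pathway labels independently, refits, and recomputes the RMSE, with the
add-one p-value.  Exchangeability under permutation holds whatever the
MCMC budget, so null-calibration experiments may use short chains.

## Temporal dynamics

Topic correlations are computed over posterior theta draws pooled across
samples, which captures both Sigma and covariate-induced co-occurrence;
edges above the cutoff (default 0.05) define the graph and its connected
components define topic clusters ("misc" collects edgeless topics).
Cluster frequencies per day are linear images of theta draws (sum of
member topics), pooled across same-day samples, with central 80%
uncertainty bands; days without samples stay gaps.  A change day is a day
whose dominant cluster (argmax of the posterior mean, requiring at least
`min_dominance`=0.5; under-threshold days inherit the previous dominant)
differs from the previous day's.  For temporal data, the topic model
should be fit with a spline-on-day design (10 df is the package default
recommendation): with an intercept-only design the temporal structure is
forced into Sigma, inflating the posteriors of inactive topics and blurring
the correlation graph.

The conventional comparator is hierarchical clustering with Ward linkage
on Bray-Curtis dissimilarities (Lance-Williams update applied directly to
the non-Euclidean dissimilarity, the common ecology convention), with
optional geometric-mean library normalization followed by per-feature
centering and scaling.

## Synthetic data

The generators draw from exactly the structures above: `generate_stm_dataset`
from the logistic-normal topic model (beta from a sparse symmetric
Dirichlet, concentration 0.1, microbiome-like; log-normal library sizes,
median 1e4); `generate_pathway_counts` from the NB2 interaction model via
its gamma-Poisson mixture; `generate_gene_content` as a sparse copy-number
matrix under a nested three-level hierarchy; `generate_regime_timeseries`
as daily samples whose active topic cluster switches at planted days, with
a shared day-level activity term per cluster (this is what makes members
of a subcommunity rise and fall together — pure regime switching plus
compositional closure would leave same-cluster topics anti-correlated
within a regime), block-structured topics over disjoint OTU ranges, and a
reference "exposure" topic that spikes on the first switch day.

What the generators do **not** emulate: phylogenetic correlation between
OTUs, chimeras and sequencing error, taxonomic mis-annotation, uneven
primer efficiency, or real KEGG topology.  Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to violations of them on real surveys.

## Numerical choices and scaled-down study sizes

* beta is floored at 1e-12 and renormalized; mixture probabilities at
  1e-300 before logs.
* Newton E-steps stop at gradient sup-norm 1e-7 or 60 iterations, with
  eigenvalue-clamped (>= 1e-8) Hessian solves and backtracking line search.
* Pseudo-count rounding is half-away-from-zero.
* Permutation p-values use the add-one estimator (b+1)/(n+1).
* Argmax ties in the OTU grouping simulation break uniformly at random
  under the operation's seed.
* Every stochastic operation takes an explicit seed; the pipeline derives
  per-stage seeds from the global seed by hashing the stage name, so
  adding a stage never perturbs earlier streams.

The test suite and `scripts/acceptance.py` run the statistical studies at
deliberately modest sizes chosen to keep the full run in minutes on one
core: topic recovery at M=300/V=150/K=3 over 5 replicates, effect
calibration at M=150/V=80 over 20+10 replicates, interaction recovery at
K=5/C=8 over 10 seeds with 2 chains x 500, RMSE permutation at n_perm=20
(and 2 x 150 chains inside the null calibration), event detection over 10
150-day series.  These sizes are the package's reference study conditions;
larger runs only tighten the Monte-Carlo bands.

## Known limitations

* The Laplace-style bound is not a true lower bound, so the reported
  objective can in rare cases dip; iteration stops at the first dip.
* theta is reported as softmax(eta_hat), the posterior-mode push-forward,
  not the exact posterior mean of the logistic-normal (the difference is
  O(posterior variance), negligible at amplicon depths).
* With a single observed table per (topic, pathway) cell, the interaction
  posterior cannot beat the per-cell noise floor sd ~ 1/sqrt(lambda); at
  lambda = 10 that is ~0.32 on the log scale.  Interpret interaction point
  estimates accordingly; the 80% interval rule is the intended readout.
* Content covariates (covariates on beta), spectral selection of K, and
  MCMC inference for the topic model itself are out of scope.
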