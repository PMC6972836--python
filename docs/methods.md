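# Methods

## Model

Observed responses `y_ij` (site `i = 1..n`, species `j = 1..p`) are linked
to a shared linear predictor

    eta_ij = alpha_i + beta_j + z_i' theta_j,

with `z_i` in R^q (default q = 2) the latent ordination coordinates of site
`i` and `theta_j` the loadings of species `j`. Families:

* **binary** — `y_ij ~ Bernoulli(Phi(eta_ij))` (probit link);
* **poisson** — `y_ij ~ Poisson(exp(eta_ij))`;
* **negbin** — mean `mu = exp(eta)`, overdispersion `omega`, variance
  `mu + omega mu^2` (the mean/overdispersion parameterization, not the
  trials/probability one);
* **ordinal** — cumulative probit: a latent `z*_ij ~ N(eta_ij, 1)` is cut at
  ordered thresholds `c_1 < ... < c_{K-1}` into classes `1..K`. The latent
  variance is fixed at 1 for identifiability; K classes use K−1 cutoffs
  (class K iff `z* > c_{K-1}`).

Priors: `alpha_i ~ N(mu_alpha, V_alpha)`, `beta_j ~ N(mu_beta, V_beta)`
(defaults 0 and 1), `z_i ~ N(0, I_q)`, `theta_j ~ N(0, V_theta)` (default
identity), cutoffs standard normal with the ordering constraint, and
`omega ~ half-Cauchy(scale = sqrt(20))`. The half-Cauchy scale deserves a
note: it is sometimes described as having "variance 20", which a Cauchy does
not possess; we read it as squared scale 20.

### Identifiability and rotation

The likelihood sees `(Z, Theta)` only through `Z Theta'`, so any orthogonal
map applied to both leaves it unchanged. The conventional fix constrains the
leading q x q block of `Theta` to be lower triangular with positive diagonal
(for q = 2: `theta_11 > 0`, `theta_12 = 0`, `theta_22 > 0`).

We do **not** impose this constraint inside the Markov kernel. Sampling the
unconstrained model and rotating each retained draw to the constrained
representative (Gram-Schmidt on the first q loading rows, signs fixed
positive) targets the same family of identified functionals but mixes far
better: in the constrained chart, moving the orientation of the latent cloud
relative to the anchor species requires a coordinated move of every latent
row, and we measured split-Rhat up to 2.0 on latent coordinates and 85-90%
empirical coverage of nominal 95% intervals for in-chart sampling at
practical chain lengths. With post-hoc identification the identified draws
are functions of rotation-invariant geometry only, which single-block Gibbs
updates move freely (coverage 93%, Rhat <= 1.11 at a quarter of the
iterations). Every retained draw satisfies the constraints exactly.

## Samplers

* **binary/ordinal**: exact Gibbs with normal data augmentation. `z*_ij` is
  drawn from `N(eta_ij, 1)` truncated to the region its class implies; all
  remaining blocks are conjugate Gaussians. Cutoffs are drawn one at a time
  from standard-normal conditionals truncated to the interval allowed by the
  augmented data and neighbouring cutoffs, so ordering is preserved by
  construction. Truncated normals use inverse-CDF sampling in log-CDF space
  (`log_ndtr`/`ndtri_exp`) with the interval reflected onto the
  well-conditioned side — exact arbitrarily deep in the tails.
* **poisson/negbin**: random-walk Metropolis within Gibbs; site and species
  effects propose elementwise (target acceptance 0.44), latent-factor and
  loading rows propose as q-vectors (target 0.234), `omega` on the log scale
  with Jacobian. Scales adapt by Robbins-Monro during burn-in only, so the
  retained chain comes from a fixed kernel.
* Both samplers add generalized-Gibbs moves along the likelihood-invariant
  "ridges" the data cannot inform: translating all `z_i` while absorbing the
  shift into the species effects (exact Gaussian conditional), trading a
  constant between site and species effects (exact), and per-dimension
  scaling of `Z_k` against `Theta_k` (Metropolis with the multiplicative
  Jacobian `s^{n-p}`). These are cheap and remove the slow random walk along
  near-flat posterior directions.

Defaults: 20,000 iterations, 10,000 burn-in, thin 10 (>= 1,000 retained
draws). Initialization: effects and factors at 0, loading diagonal at 1,
`omega = 1`, cutoffs at normal quantiles of the empirical class frequencies.
Chains are bit-reproducible given (data, spec, settings incl. seed).

The probit Gibbs kernel was validated against a self-normalized
importance-sampling oracle on a 2 x 2 toy (posterior means and SDs of all
blocks within Monte Carlo error) and by prior-predictive calibration
(simulation-based-calibration ranks uniform; 95% HPD coverage of generating
latent factors ~93-95%). The count kernel was validated by parameter
recovery (overdispersion and latent structure) and its acceptance-rate
targets.

## Uncertainty summaries and the two width estimands

The headline scalar is the mean 95% HPD width of the latent factors: the
Chen-Shao minimal sorted-window interval per coordinate `z_ik`, averaged
over all n*q coordinates (and over replicates in simulation studies).

Two versions exist and differ materially:

* **identified widths** (`mean_hpd_width(chains)`) — marginals of the
  exactly identified draws. These include *orientation noise*: the
  identified frame is anchored to the first two species' loadings, whose
  posterior direction has O(1/sqrt(n)) uncertainty that does **not** shrink
  as species are added. Coverage statements about true latent factors use
  these (the identification map is a fixed function of each draw, so
  calibration arguments apply).
* **aligned widths** (`mean_hpd_width(align_rotation(chains))`) — each
  draw's configuration is Procrustes-rotated to the across-draw mean
  configuration (reference iterated twice). This measures the precision of
  sites' positions *relative to one another* — the thing an ordination is
  read for — and it decreases steadily with both n and p. The design tool
  reports aligned widths. Alignment is a data-dependent transformation, so
  aligned intervals are not used for coverage claims.

`anchor(chains, site)` subtracts the anchor site's draw-wise position,
making all positions distances from that site; anchoring is idempotent and
removes common translations (but not rotations).

2-D HPD regions: `kde` (Gaussian KDE, Scott bandwidth, highest-density
contour enclosing the nominal fraction of draws, polygons extracted from a
128 x 128 grid) or `normal_ellipse` (chi^2_2 radius; area
`pi * r2 * sqrt(det C)`). Rank-deficient clouds fall back to an interval
product with a warning. Convergence diagnostics (split-Rhat, ESS) are
delegated to ArviZ on the half-split chain.

DIC uses the mean-parameterization plug-in: the plug-in deviance is
evaluated at the posterior-mean linear predictors (plus mean omega/cutoffs),
because averaging the factors and loadings separately evaluates the
deviance at a point the posterior never visits (the low-rank product does
not commute with averaging) and produces meaningless negative pD.

## Synthetic communities and the design tool

`generate_community` draws `alpha_i ~ N(mu_alpha, sigma_alpha^2)`,
`beta_j ~ N(mu_beta, sigma_beta^2)`, latent factors and loadings elementwise
standard normal (the stored truth is the identified representative), then
samples responses from the chosen family; negbin generation uses a
gamma-Poisson mixture at the design's `omega`. Replicates use independent
streams keyed by (seed, replicate) and are bit-reproducible.

Rare-species augmentation appends `p_rare` species with
`beta ~ N(-4, 0.5^2)`: under the default site scale (`sigma_alpha = 1`) the
marginal occurrence probability of such a species is
`Phi(-4 / sqrt(1 + 1 + 0.25 + 2)) ~ 0.027` (site variance 1, augmentation
variance 1, effect variance 0.25, latent-term variance 2 at q = 2), and
about 65% are never observed across 20 sites. In the default simulation
scenarios the common-species effect scale is `sigma_beta = 0.5`, giving
species present at about half the sites on average.

`hpd_width_design` runs, per (n, p) cell and replicate: generate -> fit ->
aligned mean HPD width, and returns per-cell means and SDs; `fit_family`
lets count data be fit with the negative binomial, and `as_presence`
degrades generated counts to presence/absence so count and binary analyses
of identical communities can be compared. Replicate failures are counted,
not fatal. The scenario defaults (n = 20 sites; 50 replicates; rare spec
above) mirror standard published simulation designs; tests and the
acceptance script run 5-10 replicates of 5,000 iterations, which resolves
cell means to a few percent (across-replicate SD ~0.2-0.4).

What the generator does *not* emulate: phylogenetic or trait structure in
the loadings, spatial autocorrelation between sites, zero-inflation beyond
the rare-species mechanism, and observation effort differences. Passing
simulation checks therefore demonstrates correctness of the inferential
machinery under the model's own assumptions, not robustness to real-data
violations of them.

## Numerical choices and limitations

* HPD ties broken toward the smallest lower endpoint; a single interval is
  always returned (no disjoint HPD sets), which overstates width for
  multimodal marginals.
* The ordinal model keeps both free cutoffs and a free intercept-like site
  effect; they are jointly weakly identified and regularized by their
  priors. Empty classes are handled by the neighbouring-cutoff truncation.
* `exp(eta)` is clipped at `exp(20)` during generation to avoid overflow in
  extreme tails of the lognormal mean.
* Count-family MH mixes the latent blocks more slowly than the probit Gibbs;
  the ridge and alignment machinery keeps width summaries stable (5k vs 20k
  iteration runs agree within 1%), but tail quantiles of individual
  parameters need longer chains.
* Aligned widths are a post-hoc functional; their sampling distribution
  under repeated data is well behaved, but they should not be read as
  marginal credible intervals for a fixed parameterization.
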