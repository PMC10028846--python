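# Methods

This note documents the models and procedures implemented in `gomde`, the
parameter choices that matter, and what the simulation-based validation does
and does not establish.

## Topic model and Poisson NMF

Counts X (n cells × m features, UMI counts or binarized accessibility) are
modelled as `x_i· ~ Multinomial(s_i; π_i)` with `Π = L Fᵀ`, rows of L on the
simplex and columns of F summing to one.  Fitting goes through the
equivalent Poisson NMF model `x_ij ~ Poisson((H Wᵀ)_ij)`: the multinomial
likelihood is proportional to a product of independent Poissons, so the MLEs
of (L, F) follow from the MLEs of (H, W) by the rescaling
`t_k = Σ_j w_jk, f_jk = w_jk/t_k, l_ik ∝ h_ik t_k`, which reproduces
`H Wᵀ = diag(s′) L Fᵀ` exactly.

Two update rules are provided, both monotone in the Poisson log-likelihood:

* **EM** — the classical multiplicative updates
  `h_ik ← h_ik · Σ_j (x_ij/λ_ij) w_jk / Σ_j w_jk` (and symmetrically for W).
* **CD** — cyclic coordinate ascent over columns.  With the other factor
  fixed, the coordinates of one column are mutually independent, so a whole
  column is updated at once by a projected univariate Newton step with
  backtracking halving; the backtracking guarantees ascent, which the
  plain Newton step alone would not.

The default schedule is a prefit phase of EM updates followed by a
refinement phase of the requested method (1000 + 1000 iterations by
default).  Initialization is seeded random Gamma(1,1) entries rescaled to
the data's row totals; a custom-initialization hook accepts externally
computed starting values.  Acceleration by extrapolation and spectral
initializations are deliberately out of scope.

Convergence is diagnosed by the residuals of the Karush–Kuhn–Tucker
conditions: with `g = ∇(−loglik)`, interior coordinates (> 1e-10) report
|g| and boundary coordinates report max(0, −g).  Rates are floored at 1e-15
inside update rules only, never in reported log-likelihoods, so a support
violation is reported as −∞ rather than masked.

## The GoM DE model

For one gene, `x_ij ~ Poisson(s_i Σ_k l_ik p_jk)` with the membership
proportions known.  This is the standard two-group Poisson DE model when
K = 2 and memberships are binary, and otherwise generalizes it to partial
memberships.  Each rate has a Gamma(1 + ε, 1) prior; MAP estimation is
implemented as maximum likelihood on data augmented with K
pseudo-observations (count ε, exposure 1, identity memberships), optimized
by the same multiplicative updates with memberships fixed, vectorized over
all genes.  ε defaults to 0.1 — large enough to keep log rates finite for
topics with no counts, small relative to typical per-topic exposures
(it adds 0.1 counts against an exposure of 1).

Reported effect statistics (all base-2):

* pairwise LFC `log2(p_k/p_l)` against a chosen reference topic;
* LFC versus the constant-rate null model, whose MLE is `p_0 = Σx/Σs`
  (reported raw; the pseudocounted version is used internally);
* the **least extreme LFC**: the pairwise LFC against the comparison topic
  of minimal |LFC|.  "Least extreme" is read as minimum absolute value —
  a zero change beats a large one — with ties broken toward the lower topic
  index, applied per posterior sample.  It reduces to the standard LFC at
  K = 2.

## Posterior computation

Uncertainty is quantified by single-coordinate random-walk Metropolis on
`g_k = log p_k` under an improper uniform prior on the rates of the
augmented data: per step, one topic is chosen uniformly, a Gaussian step of
sd σ = 0.3 is proposed on the log scale, and the move is accepted with
probability `min(1, likelihood ratio × p*_k/p_k)`, the final factor being
the Jacobian of the log transform.  The chain starts at the MAP (so no
burn-in is applied by default; burn-in and thinning are available as
options) and runs ns = 10,000 steps by default (10× that for final
analyses).  Likelihood increments touch only cells with nonzero count and
nonzero membership in the proposed topic; the `−s·θ` term uses precomputed
per-topic exposures.  All randomness is pre-generated from a per-gene
`numpy` generator seeded by (base seed, gene index), so results are
bit-identical across thread counts and across the compiled (numba) and
pure-Python kernels.  Proposals that would produce a non-finite
log-likelihood are rejected.

The LFC statistic is evaluated at every sample and then averaged —
statistic-of-samples, never statistic-of-mean; for K ≥ 3 the two genuinely
differ because the comparison topic switches between samples.  Spread is
summarized by the smallest window of ⌈0.68·ns⌉ consecutive order statistics
(a 68% HPD interval; earliest window on ties) and converted to a standard
error asymmetrically: `se = mean − lower` when the mean is positive, else
`upper − mean`.  The one-sided rule deliberately ignores the tail away from
zero, preventing over-shrinkage of effects that are uncertain in magnitude
but clearly signed.  Infinite per-sample statistics (possible only for the
vs-null statistic with a zero null rate) are excluded and counted; genes
with > 1% exclusions, zero total counts, or unconverged MAP fits are
flagged, not dropped.

## Adaptive shrinkage

Across genes (separately per topic), estimates are stabilized by
empirical-Bayes shrinkage: `betahat_i | b_i ~ N(b_i, se_i²)` with prior
`b ~ Σ_g π_g Uniform(−a_g, a_g)` — symmetric uniform components on a
geometric grid, no point mass at zero.  The grid runs from min(se)/10 to
2·max|betahat| with ratio √2; the weights are fitted by EM on the marginal
likelihood with a flat Dirichlet prior (with no point mass there is no
null-biasing penalty to apply), and EM monotonicity is asserted at run
time.  Posterior means, exact second moments and tail probabilities follow
from truncated-Gaussian algebra; `lfsr = min{P(b ≥ 0), P(b ≤ 0)}`, s-values
are cumulative means of sorted lfsr, and posterior z-scores are posterior
mean over posterior sd.  Observations with non-finite inputs or zero
standard error pass through unshrunk and flagged.  HPD bounds are reported
pre-shrinkage.  A Gaussian-component family is available behind a flag but
unused in the core pipeline.

For the evaluation's no-shrinkage path, two-sided Gaussian p-values
`2Φ(−|betahat/se|)` are attached; this construction is an assumption (no
canonical definition exists for this path).

## Simulation generator

The generator emulates UMI counts from droplet scRNA-seq:

* size scales `s_i = 10^u, u ~ N(0, sd 0.2)` — combined with unnormalized
  rates this yields realistic cell totals (≈1,600 UMIs at the median);
* memberships: the number of nonzero topics K′ has probability ∝ 2^(−K′)
  over {1..K} (normalized — the only reading that yields a distribution),
  the K′ topics are drawn without replacement, and their proportions are
  Dirichlet(α) (a single topic gets proportion 1);
* rates: base `2^v, v ~ N(−4, sd 2)`; with probability 0.5 a gene is DE, in
  which case exactly one uniformly chosen topic's rate becomes `2^(v+e),
  e ~ N(0, sd 1)`;
* counts: independent Poisson draws with rates `s_i Σ_k l_ik f_jk`.

Presets: `k2-hard` (K=2, α=(0.01, 0.01), n=200; essentially two discrete
groups, ~98% of cells ≥99% in one topic), `k2-soft` (K=2, α=(1,1), n=200)
and `k6` (K=6, α=1, n=1000), all with m=10,000 genes.  Each stage draws
from an independent seeded stream, so changing m leaves s and L unchanged.
The generator does not emulate overdispersion, dropout beyond Poisson
sampling, batch effects, or membership-estimation error (memberships are
taken as known downstream) — so passing tests demonstrate correctness of
the inference under its own model, not robustness to real-data violations
of it.

## Evaluation harness

Rankings (lfsr, s-value, p-value, or the Kullback–Leibler baseline
`score_jk = min_{l≠k} f_jk log(f_jk/f_jl) + f_jl − f_jk`, zero comparison
rates floored at 1e-15 and flagged) are swept over all unique score values
and scored by power = TP/(TP+FN), FDR = FP/(TP+FP) (0 when nothing is
called), FPR = FP/(TN+FP).  Because the K-L score is unsigned, signed
evaluations restrict the candidate set: pairs carrying a negative-direction
true effect are removed, and optionally all pairs whose *estimated* LFC is
non-positive — with symmetric effects the latter removes roughly half of
all possible tests and puts signed and unsigned rankings on equal footing.
For the baseline comparison the K-L score consumes rates fitted *without*
pseudocounts: its known weakness — unregularized near-zero rate estimates
producing enormous divergences for uninformative genes — is part of what
the comparison measures, and ε-regularized rates would suppress it.

Two-seed concordance (Pearson correlations of post-shrinkage means and
z-scores between independent MCMC runs) is the standard check that ns is
large enough.  At ns = 10,000 on the scaled study conditions, posterior
means concordance exceeds 0.99 while z-score concordance plateaus near
0.98: the z denominator inherits the Monte Carlo noise of a single HPD
endpoint (≈7% at an effective sample size near 1,000), which the
uniform-mixture posterior sd can amplify near component truncation
boundaries.  Larger ns is the remedy (hence 100,000 for final analyses).

## Problem sizes used in the test suite

The validation suite runs the full pipeline at m = 2,000 genes per dataset
(presets otherwise unchanged) with ns = 10,000: one K2-soft dataset
analyzed twice for concordance and FDR control, five K6 replicates plus a
fully-null dataset for the ranking comparison and lfsr calibration.  Exact
oracles (closed forms, conjugate posteriors, numerical MAP optimization,
direct acceptance-probability evaluation) run at 3–5 cells.  These sizes
were chosen so the whole suite completes in minutes while every per-gene
quantity retains the full-scale statistical behavior (per-gene information
does not depend on m).

## Known limitations

* Overdispersed count models (negative binomial, Poisson log-normal) are
  not implemented; all extra-Poisson variation is attributed to rate
  differences.
* Membership proportions are treated as known constants; uncertainty in L
  is not propagated.
* The mixture-of-uniforms shrinkage family covers only symmetric,
  zero-centered priors (no half-uniforms, nonzero modes, or t likelihoods).
* Analytical (normal-approximation) standard errors are intentionally not
  offered: the Poisson likelihood in log-rate coordinates is too skewed for
  them at low expression.
* Model selection over K is out of scope; fit several K and compare.
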