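# gomde — grade-of-membership differential expression

Topic models (multinomial "grade of membership" models) are widely used to
find parts-based structure in single-cell RNA-seq and ATAC-seq count data:
each cell i gets membership proportions l_i1..l_iK over K topics, and each
topic k a vector of relative expression rates.  The hard part is
*interpreting* the topics.  `gomde` implements a differential-expression
analysis that does this while respecting partial memberships: instead of
comparing discrete groups of cells, it asks, gene by gene, how expression
changes with membership in each topic.

## The model

Counts follow the multinomial topic model, fitted through its Poisson NMF
equivalent:

    x_i1, ..., x_im ~ Multinomial(s_i; π_i),   Π = L Fᵀ,
    equivalently  x_ij ~ Poisson(λ_ij),        Λ = H Wᵀ,

with s_i the cell's total count.  For a single gene j, expression is modelled
as

    x_ij ~ Poisson(s_i θ_ij),   θ_ij = Σ_k l_ik p_jk,

where the memberships L are treated as known and p_j1..p_jK are unknown
per-topic rates with Gamma(1 + ε, 1) priors (ε = 0.1 by default).  A gene is
*distinctive* for topic k if its **least extreme log-fold change**

    LFCᵏ_le(j) = log2(p_jk / p_jl),   l = the topic ≠ k minimizing |LFC|

is large: the gene must differ from *all* other topics, not just one.
Posterior uncertainty in the l.e. LFC is quantified by a single-coordinate
random-walk Metropolis sampler on g_jk = log p_jk (the statistic is evaluated
per posterior sample and averaged), summarized by 68% highest-posterior-
density intervals and an asymmetric standard-error rule, and stabilized
across genes by empirical-Bayes adaptive shrinkage with a mixture-of-uniforms
prior, yielding shrunken LFCs, posterior z-scores, local false sign rates
(lfsr) and s-values.

The package also ships the simulation generator used to validate the stack
(known memberships, known DE truth) and a benchmark harness (power / FDR /
FPR curves, a Kullback–Leibler divergence baseline ranking, two-seed
concordance checks).

## Worked example

Simulate a small dataset with two topics and mixed memberships, run the GoM
DE analysis with the true memberships, and look at one strongly perturbed
gene:

```python
import numpy as np
from gomde import GoMDEOptions, de_analysis, preset_config, sim_dataset

truth = sim_dataset(preset_config("k2-soft", seed=5, m=500))
res = de_analysis(truth.counts, truth.L_true, GoMDEOptions(ns=10_000, seed=1))

j = int(np.argmax(np.abs(truth.de_effect)))        # most perturbed gene
k = int(truth.de_mask[j].argmax())
print(f"gene {j}: true effect {truth.de_effect[j]:+.2f} log2 units in topic {k+1}")
print(f"  posterior mean l.e. LFC {res.postmean_lfc[j, k]:+.2f} "
      f"[{res.hpd_lower[j, k]:+.2f}, {res.hpd_upper[j, k]:+.2f}] 68% HPD")
print(f"  shrunk LFC {res.shrunk_lfc[j, k]:+.2f}, z = {res.zscore[j, k]:.1f}, "
      f"lfsr = {res.lfsr[j, k]:.2e}")
```

Output:

```
gene 342: true effect +3.04 log2 units in topic 1
  posterior mean l.e. LFC +2.29 [+2.06, +2.57] 68% HPD
  shrunk LFC +1.85, z = 20.0, lfsr = 0.00e+00
```

The gene was simulated with an 8-fold higher rate in topic 1; the analysis
recovers a large positive least-extreme LFC with a tight interval (the point
estimate is attenuated relative to the generative value because the gene's
counts are finite and memberships are mixed), and after shrinkage the
effect's sign is established essentially without doubt (lfsr ≈ 0).  The same
analysis is available from the shell:

```sh
gomde simulate --preset k2-soft --seed 5 --genes 500 --out-prefix sim/
gomde de --counts sim/counts.mtx --loadings sim/L_true.tsv \
         --ns 10000 --seed 1 --out results.tsv
gomde eval --results results.tsv --truth sim/truth.tsv --stat lfsr \
           --restrict-positive --out curve.tsv
```

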