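# Methods

## The measurement model

A gene is observed as n paired, non-negative summary expression values
(Gᵢ, Rᵢ): test- and reference-channel signal from the same assay.  In a
competitive hybridization the two samples' targets compete for the same M
probe molecules, so the test-channel signal is naturally modelled as
Y ~ Binomial(M, p) with M = G + R the pair total and p the fraction of
available target coming from the test sample.  This motivates two summaries
of relative expression:

* per-pair proportions pᵢ = Gᵢ/(Gᵢ+Rᵢ), averaged to p̄ (each pair weighted
  equally);
* the pooled ML proportion p̂ = ΣG/Σ(G+R) (pairs weighted by total signal —
  p̂ is exactly the (G+R)-weighted mean of the pᵢ and equals p̄ when pair
  totals are equal).

The classical mean log₂-ratio r̂ is kept as the comparator.  The two scales
are deterministically linked for a single pair by the logistic law
p = 2ʳ/(1+2ʳ); the proportion is simply a bounded reparametrisation of fold
change that remains defined at zero.

## Undefined values and missing policies

A per-pair proportion is undefined only at the 0/0 pair; a per-pair
unshifted log-ratio is undefined when *either* channel is zero (covering
both the division-by-zero and the log-of-zero pathologies with one rule).
Two aggregation policies are provided:

* `gene-missing` — any undefined pair voids the gene's statistic (default
  for ratio statistics; the gene is counted as non-significant downstream);
* `drop-pairs` — undefined pairs are removed and the statistic is formed
  from the rest (default for proportion statistics; a gene is untestable
  only when every pair is 0/0).

Whether single-channel zeros should also void proportion statistics is not
settled by the method itself; the policies are therefore arguments, not
constants.  Note one deliberate asymmetry: on real data the proportion
pipelines default to `drop-pairs` (preserving genes is the method's point),
but `table1_grid` and the acceptance script run *all* per-pair statistics
under `gene-missing`, because the reference simulation's printed operating
characteristics (in particular the Poisson-column proportion-t power) are
only reproduced when a simulated dataset containing any 0/0 pair is
classified missing for every statistic alike.

## Test statistics

All tests are two-sided at working level α; degenerate zero-spread cases
resolve deterministically (statistic 0 and p = 1 when centred on the null,
±∞ and p = 0 otherwise), and statistics that cannot be formed return a
missing outcome that is never significant.

* **Proportion t** (`tprop`): t = (p̄ − 0.5)/(s/√n′), df n′ − 1, with s the
  sample standard deviation (ddof 1) of the contributing per-pair
  proportions and n′ their count.  Nothing binomial is assumed — only a CLT
  on bounded per-pair proportions — which is why this statistic holds its
  size under every generating family in the benchmark.
* **Binomial z** (`zprop`): z = (p̂ − 0.5)/√(v/M) with v = 0.25 (null
  variance, default) or v = p̂(1−p̂) (plug-in).  The two modes are nearly
  indistinguishable at realistic M; both are kept because the derivation
  admits either.  Applied to continuous intensities the test treats M = Σ(G+R)
  as a binomial denominator, which grossly understates replicate variance —
  the benchmark's exponential column (rejection 0.975 under the null) is the
  quantitative form of that warning.
* **Ratio t** (`ratio`, `ratio+c`): one-sample t of per-pair log₂-ratios
  against 0, optionally after adding a pseudocount c to *both* channels
  (symmetric, so the null r = 0 is preserved at fold change 1).
* **Welch two-group**: for control-vs-treatment designs each array
  contributes one per-pair statistic (proportion or log-ratio) and groups
  are compared with the unequal-variance t-test (Welch–Satterthwaite df;
  delegated to scipy).
* **Poisson LRT**: for per-lane counts under equal exposure,
  LRT = 2[Σx·ln(λ̂₁/λ̂₀) + Σy·ln(λ̂₂/λ̂₀)] with condition means λ̂₁, λ̂₂ and
  pooled mean λ̂₀, convention 0·ln 0 = 0, referred to χ²₁.  No library-size
  offsets are applied (the benchmark fixes constant library sizes); data
  needing normalisation should be scaled upstream.
* **Intervals**: Agresti–Coull in its general z²-augmentation form with
  endpoints clipped to [0, 1]; and the conjugate Beta(y+a, M−y+b) posterior
  with equal-tailed credible intervals, which at a flat prior and large M
  agrees with Agresti–Coull to well under a percentage point.

Multiplicity control offers a fixed Bonferroni threshold α/K (strict
inequality), Bonferroni-adjusted p-values, and Benjamini–Hochberg step-up
FDR (statsmodels backend).  Missing p-values are excluded from the
multiplicity count m, matching how unanalysable probes are simply absent
from a ratio analysis.

## The simulation engine

`rejection_study` draws one gene per replicate (the quantity of interest is
a per-statistic rejection proportion, not a genome-wide analysis), applies
every requested method to the *same* simulated data within a replicate
(paired comparison, lower between-method Monte-Carlo noise), and reports
rejections/reps with the binomial Monte-Carlo standard error
√(p(1−p)/reps).  Replicates with unformable statistics stay in the
denominator as non-rejections.  One seeded generator drives each study;
grid cells derive child seeds from the base seed, so reports are
byte-reproducible.

Generating families and their defaults (chosen to emulate the stated
platforms; fold change c ≥ 1, c = 1 the null):

| family      | reference channel    | test channel            | emulates                      |
|-------------|----------------------|-------------------------|-------------------------------|
| exponential | Exp(rate 1/4000)     | c × Exp(rate 1/4000)    | 16-bit cDNA scanner intensity |
| poisson     | Poisson(3)           | c × Poisson(3)          | low-coverage sequencing counts|
| binomial    | R = M − G            | G ~ Binomial(M=10⁴, p_c)| competitive hybridization     |
| normal      | N(5, 1) trunc. at 0  | N(5c, 1) trunc. at 0    | normalised array intensities  |

Notes on two of these:

* The binomial family couples the channels through the pair total
  (G + R = M exactly), and the fold change maps to the success probability
  p_c = c/(c+1) — fold changes 2, 3, 4, 5 are probabilities 2/3, 3/4, 4/5,
  5/6.  Independent binomials would not respect the hybridization model.
* The Poisson fold change **scales the draws** (test = c·X, X ~ Poisson(λ)),
  analogously to the exponential family, rather than drawing
  Poisson(c·λ).  Both give a test mean of cλ, but scaling preserves the
  test-channel zero frequency e^{−λ}; with Poisson(cλ) zeros all but vanish
  at c = 3 and the reference operating characteristics of the ratio and
  shifted-ratio statistics (power 0.116 / 0.757 / 0.943 at λ = 3, n = 20)
  are unreproducible.  Normal truncation is by redraw; at the default
  μ/σ = 5 the truncated mass is < 3×10⁻⁷ and the family is effectively an
  untruncated Gaussian.

`make_fixture` builds a labelled K × n matrix: a chosen fraction of genes at
fold change c, the rest null, then optional zero-inflation replacing each
cell independently with an exact zero.  It emulates the zero-richness and
effect sparsity of real expression matrices but none of their correlation
structure, normalisation artefacts, or intensity-dependent variance — a
green end-to-end test therefore establishes the statistics' contracts and
calibration under independence, not performance on any real platform.

## Numerical choices

* Sample standard deviations use ddof 1 everywhere.
* t/normal/χ² tail probabilities go through `scipy.special` (`stdtr`,
  `ndtr`, `chdtrc`) — exact CDFs, cheap enough for 10⁵ per-replicate calls.
* LRT values are floored at 0 against floating cancellation.
* `proportion_to_ratio` rejects p ∈ {0, 1} (conceptually ±∞) rather than
  returning infinities; `ratio_to_proportion` is computed as 1/(1+2^{−r})
  to avoid overflow.
* Ties at the significance boundary: rejection requires strictly
  p < α (equivalently |statistic| > quantile), also at adjusted thresholds.
* Input validation is strict: negative or non-finite expression values are
  errors, not missing data; zeros are data.

## Known limitations

* No empirical-Bayes variance moderation and no overdispersion modelling;
  the package deliberately covers the plain statistics only.
* The Poisson LRT assumes equal exposure per lane; unequal library sizes
  must be handled upstream.
* The two-group Welch path assumes one pair per array per gene; designs
  with technical replicates per array are out of scope.
* Difference-of-two-proportions Bayesian inference is not implemented; the
  beta posterior covers the one-proportion case.
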