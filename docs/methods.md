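# Methods

## The partition model

The model treats differential methylation between a case and a control
condition as a genome-wide partition problem.  Each CpG locus carries a
latent label `I_i ∈ {0, 1, 2}`: equal- (`p_i1 = p_i2`), hypo-
(`p_i1 < p_i2`) or hyper-methylated (`p_i1 > p_i2`), where `p_ik` is the
true methylation proportion of locus `i` in condition `k`.  Methylated read
counts are `Binomial(C_ijk, p_ik)` given per-replicate coverage — i.e. the
model assumes no replicate-to-replicate variation in the true proportion
within a condition (see *Limitations*).

Conjugacy is used aggressively: Beta priors on the proportions (a single
shared proportion for group 0; a truncated product prior
`2 f(p_1) f(p_2) 1{p_1 < p_2}` for group 1 and its mirror for group 2)
integrate out analytically.  Each locus then contributes one closed-form
marginal factor per hypothesis; the directional factors contain the order
probability `P(X < Y)` of two independent Beta posteriors, the directional
evidence term.  The equal-group prior formally places its mass on the
diagonal `p_1 = p_2`; the implementation follows the evident intent — one
shared proportion — which the collapsed form (pooled counts across both
conditions in a single Beta function) confirms.

The label vector has a multinomial prior with Dirichlet-distributed group
probabilities, collapsed to a Dirichlet-multinomial:
`p(I) = B(k0+l0, k1+l1, k2+l2) / B(k0, k1, k2)`.  This is the only term
that couples loci, and it is what lets sparse directional evidence at one
locus be weighed against genome-wide group abundances.

The truncation constant in the directional priors is written as 2, the
exact normalizer when the two Beta factors are exchangeable (`α = β` or,
more generally, symmetric laws).  For `α ≠ β` the exact normalizer would be
`1 / P(p_1 < p_2)` under the untruncated product prior; the constant 2 is
kept as stated because (a) the default is the uniform prior where the two
coincide and (b) a constant factor common to all loci in a group only
shifts the marginal by a label-independent amount when group sizes change,
which the Dirichlet-multinomial prior already parameterizes.

### Hyperparameters

| parameter | meaning | default |
| --- | --- | --- |
| `alpha1, beta1` | Beta prior, equal group | 1, 1 |
| `alpha2, beta2` | Beta prior, hypo group | 1, 1 |
| `alpha3, beta3` | Beta prior, hyper group | 1, 1 |
| `k0, k1, k2` | Dirichlet prior on group probabilities | 1, 1, 1 |

All defaults are non-informative; all nine must be strictly positive.

## Sampling

The posterior over label vectors is explored by Metropolis–Hastings with a
half/half mixture of two kernels: *relabel* (uniform non-empty group →
uniform locus within it → uniform alternative label) and *exchange*
(uniform unordered pair of distinct non-empty groups → one uniform locus
from each, labels swapped).  Restricting selection to non-empty groups
avoids void proposals; the exact Hastings ratio under these selection rules
accompanies every move (it is identically 1 for exchanges, whose selection
probabilities are symmetric).  When fewer than two groups are occupied a
relabel move is forced, with the ratio adjusted accordingly.  Ergodicity is
immediate: relabel moves alone connect any two label vectors.

Per-locus marginal factors are cached once, so a proposal costs O(1): two
(relabel) or four (exchange) cache lookups plus a table-lookup change in
the Dirichlet-multinomial term.  A *sweep* is `L` proposals; the chain
records one membership snapshot per post-burn-in sweep into per-locus
frequency counters (3 integers per locus, no full chain storage unless
trace mode is on).  Defaults: 2000 sweeps, 50 % burn-in, random-uniform
initialization, seed 0.  The random stream order per proposal is fixed
(move type, group(s), locus/loci, target label, acceptance uniform), so a
seed pins the entire chain bit-for-bit.

Calls take the highest-frequency label; exact ties involving the equal
group, or between hypo and hyper, resolve to equal — no directional claim
without a strict winner.

### Validation strategy and its noise floor

Two independent oracles check the sampler:

1. **Exact enumeration** (`enumerate_exact_posterior`) sums all `3^L`
   states for small `L`.  A frequency estimate from `n` recorded sweeps
   carries Monte-Carlo standard error `sqrt(p(1−p) τ / n)` (`τ` = sweep-
   level autocorrelation), so a deterministic assertion at tolerance `t`
   requires fixtures whose posterior entries satisfy `p(1−p) τ / n ≤
   (t/3)²`.  At the default 1000 recorded sweeps and `t = 0.02` this bounds
   the admissible entries away from mid-range; the packaged six-locus
   agreement fixture is therefore built from clearly directional loci
   (entries ≥ 0.95).  Mid-entropy posteriors are validated separately with
   a 50 000-sweep chain at a tolerance matched to that chain's noise.
2. **Stationarity in total variation**: on a three-locus fixture the
   empirical joint distribution over all 27 states from one million
   proposals must match the enumerated posterior within TV 0.01.  This
   test is sharp: deliberately corrupting the Hastings ratio moves the TV
   distance an order of magnitude above the threshold.

## Baselines

* **Pooled z-test**: reads are pooled within each condition; the standard
  two-proportion z statistic with pooled variance gives a two-sided normal
  p-value.  A pooled proportion of exactly 0 or 1 is flagged degenerate
  (p = 1).
* **Logistic regression**: a per-locus binomial GLM
  `logit(p) = β₀ + β₁·condition` fitted by IRLS (statsmodels), Wald test on
  `β₁`.  Under perfect separation the Wald statistic degenerates and the
  test falls back to the likelihood-ratio test against the intercept-only
  model.  The GLM is the plain binomial model with a condition indicator —
  no overdispersion correction — and an optional ≥10-reads-per-sample
  pre-filter mirrors common practice for this comparator (off by default).
* **q-values**: Storey's estimator with a single λ = 0.5
  (`π̂0 = min{1, #{p > λ} / ((1−λ) m)}`, floored at 1/m), monotonized over
  the sorted p-values.  Forcing `π0 = 1` reproduces Benjamini–Hochberg
  exactly, which doubles as a cross-check.  A spline-smoothed π0 was
  deliberately not implemented; at the locus counts this package targets
  the single-λ estimate is stable and keeps the dependency surface small.
* **Direction**: a baseline discovery is oriented by the sign of the
  pooled difference `d̂ = p̂_case − p̂_control`; `d̂ = 0` cannot be oriented
  and yields no directional call.

Both baselines operate locus by locus with no information sharing — the
contrast that motivates the partition model.

## Synthetic data

The generator mirrors a case-control RRBS benchmark: labels are drawn
i.i.d. from group fractions, true proportions from per-group pools, coverage
per replicate, counts `Binomial(C, p)`.

* **Group fractions**: the effect-size tuning parameter γ controls both
  effect size and abundance through the labelling rule (|d̂| < 0.005 equal,
  d̂ > γ hyper, d̂ < −γ hypo, the band between excluded).  Presets pin the
  two printed anchors: γ = 0.01 → 43.28 % hypo / 29.44 % hyper; γ = 0.2 →
  5.9 % / 4.6 % (the packaged default).
* **Pools**: empirical pools (a user-supplied table of per-locus proportion
  estimates, partitioned by the γ rule) replicate a
  resampling-from-real-data design; the packaged default is parametric —
  the equal-group pool is a bimodal Beta mixture (modes near 0.08 and 0.92,
  a light mid component), the canonical shape of RRBS methylation levels,
  and the directional pools are independent Betas for the two conditions
  with concentration 20 (sd ≈ 0.09 at mean 0.2, comparable to the spread
  of group-level RRBS estimates), resampled until the group's order
  constraint holds.
* **Coverage**: 1 + Poisson(mean 20) by default (RRBS-like, never zero);
  an empirical coverage table or a constant are accepted.
* **Subject effect**: optionally, per-replicate proportions are drawn from
  `Beta(p·s, (1−p)·s)` around the locus value (`s` = 50 by default),
  emulating biological variation within a condition; `s → ∞` recovers the
  no-subject-effect design.  Degenerate proportions (0/1) stay exact.
* Defaults are the benchmark conditions: 20 000 loci, two replicates per
  condition.

What the generator does **not** emulate: spatial correlation of adjacent
CpGs, coverage-methylation dependence, strand effects, and the heavy-tailed
patient-to-patient variation of real tumour samples.  Passing tests
demonstrate calibration and power under binomial sampling with the stated
pool shapes, not performance on any real cohort.

## Evaluation metrics

For three-way truth vs. three-way calls, discoveries are `call ≠ 0`:

* **FDR** — fraction of discoveries with truth 0;
* **mdFDR** — FDR plus wrong-direction discoveries (truth 1 called 2 or
  vice versa) in the numerator; always ≥ FDR, equal iff no directional
  mistakes;
* **TPR** — fraction of true DML discovered regardless of direction;
* **TPR_hypo / TPR_hyper** — fraction of truly hypo/hyper loci called with
  the *matching* direction.  The directional reading is the one consistent
  with mdFDR's treatment of direction errors; a permissive flag
  (`directional=False`) counts any discovery instead.

Zero-denominator rates are reported as NaN (undefined), never as 0.  The
matched-FDR benchmark protocol runs the Bayesian caller first, averages its
realized FDR over replicates, and uses that as the q-value threshold for
the baselines, so that power is compared at equal empirical FDR.

## Numerical choices

* All probability arithmetic is in log space via log-gamma; the
  three-argument Beta function is evaluated as
  `Σ lnΓ(k_j + l_j) − lnΓ(Σ(k_j + l_j))` minus the same at `l = 0`.
* Binomial coefficients are identical across the three hypotheses for a
  locus and cancel from every posterior ratio; they are excluded from the
  cached marginals and included only on request (needed when comparing
  against direct numerical integration).
* `P(X < Y)` uses an exact finite-sum closed form for integer shapes with
  per-distribution shape sums ≤ 50, and adaptive Gauss–Kronrod quadrature
  of `∫ f_X(t)(1 − F_Y(t)) dt` otherwise (absolute tolerance 1e−13; the
  complement identity `P(X<Y) + P(Y<X) = 1` holds to 1e−10 across shapes
  down to 0.2).  Before taking logs the probability is clamped to
  `[1e−300, 1 − 1e−16]` so strongly ordered loci keep finite marginals in
  the acceptance ratio.
* Replicates with zero coverage contribute empty factors (`M = N = 0`),
  the natural limit of the collapsed marginals; no special-casing beyond
  the input-level filter.
* The `call` output writes `p_hyper = 1 − (p_equal + p_hypo)`, making the
  left-to-right triplet sum exactly 1.0 in IEEE double; reading the TSV
  with a round-trip float parser preserves this.

## Input handling

Merged count TSVs (`chrom`, `pos`, optional `strand`, `meth_<sample>` /
`cov_<sample>` pairs) or per-sample bismark-coverage files (1-based start;
`coverage = methylated + unmethylated`) joined on position.  Loci missing
from a sample are kept with coverage 0 (a strict-intersection flag keeps
only commonly mapped loci instead).  Coordinates are 1-based; strand is
carried through when present but never collapsed.  The pre-analysis filter
removes loci fully methylated or unmethylated in every covered sample, and
loci with zero pooled coverage in either condition; the three categories
are logged separately so real-data filter summaries can be reconstructed.

## Problem sizes used in the shipped validation

The recovery and comparison studies run at 1000 loci, 2+2 replicates, 2000
sweeps, five replicate datasets (recovery) and five to ten (benchmark) —
sizes at which the metrics stabilize to the second decimal while a full
validation pass stays interactive.  The same code paths scale to
genome-wide locus counts; chain cost is linear in sweeps × loci.

## Limitations

* Conditional independence of loci given the labels: no spatial model of
  adjacent-CpG correlation.
* The no-subject-effect likelihood: biological variation within a
  condition is emulated by the generator but not modelled by the caller
  (robustness to moderate subject effects is a claim about the model, not
  a guarantee).
* Beta-binomial dispersion estimation, region-level smoothing and
  external-cohort effects are out of scope.
* Single-chain inference: no cross-chain convergence statistics are
  computed (the test suite checks two-initialization agreement instead).
* Runtime: the sampler is a pure-Python loop at ~10⁵ proposals/second;
  genome-scale runs (10⁵–10⁶ loci) are feasible but take hours, as
  expected for a single-site MH sampler of this model.
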