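# Methods

## The problem

The trapezoidal area under an empirical ROC curve built from n true-positive
(case) scores and m true-negative (control) scores equals U/(nm), where U is
the Mann–Whitney count of correctly ordered (case, control) pairs.  Under a
null model in which case scores are iid with distribution F and control
scores iid with distribution G, the AUC is a discrete random variable on the
lattice {0, 1/nm, …, 1}.  Biomarker screens that Bonferroni-correct for
10^4–10^8 simultaneous hypotheses need the *far upper tail* of this
distribution — tail masses of 10^-7 to 10^-16 — where normal approximations
to U are unusable and plain Monte Carlo would require 10^10+ replicates.

`exactroc` computes that distribution three ways and stitches them together:

1. **Exact tail** (order statistics).  Every tie-free interleaving of the
   pooled scores ("word") has probability given by an iterated integral of
   the order-statistic joint density.  The probability of AUC = 1 − i/nm is
   the sum of word probabilities over all interleavings with *deficit* i
   (the number of (case, control) pairs ordered wrongly); those interleavings
   correspond one-to-one to partitions of i into at most n parts, each at
   most m, so their number k_i is a Gaussian-binomial coefficient.
2. **Monte Carlo body.**  Seeded simulation of AUC deficits with percentile
   estimation by the superlevel-set rule inf{x : F̂(x) ≥ α}.
3. **Geometric bridge.**  In the top percentile the ratio of subsequent
   probability differences tracks the corresponding ratio of count
   differences up to a constant C (exactly, with C = 1, when F = G, since
   then x_i = k_i·n!m!/(n+m)!).  The recurrence
   x_i ≈ x_{i−1} + C·Δk_i·Δx_{i−1}/Δk_{i−1} extends the exact tail to the
   deficit where a Monte Carlo percentile becomes reliable; C is fitted by
   bisection so the bridged upper-tail mass at that percentile equals its
   empirical estimate.

Inference then reads off inclusive one-sided p-values P(AUC ≥ observed) and
conservative lattice critical values (smallest c with P(AUC > c) ≤ α,
rejection when observed > c), with Bonferroni correction
α = (1 − level)/hypotheses.

## Exact-tail engines

The literal construction (`engine="word_sum"`) performs one chain of n+m
cumulative integrations per interleaving; its cost grows with the partition
count, i.e. exponentially in the deficit.  It is retained as the
correctness oracle.

The default engine (`engine="state_dp"`) is a deficit-tracking dynamic
program over the grid.  Scanning the pooled order statistics from smallest
to largest, the state is (a cases placed, b controls placed, accumulated
deficit d); appending a control above a already-placed cases adds a to the
deficit.  The running functions satisfy

    S[a,b,d](t) = ∫_{−∞}^t ( f·S[a−1,b,d] + g·S[a,b−1,d−a] )(s) ds,

with x_i = S[n,m,i](+∞).  States that cannot finish within the requested
deficit range (d + a·(m−b) > i_max) are pruned, which makes deep tails cheap
even for hundreds of observations per group: the 57-entry tail for
n = m = 50 takes a few seconds, and 44 × 800 about ten.  Arrays store
L!·S at pooled length L, so nothing underflows even for ~850 chained
integrations; the final division by binomial(n+m, n) happens in log space.

Both engines are checked against each other (they are algebraically
identical under a linear quadrature rule and agree to ~10^-10 there), against
the closed one- and three-dimensional integral forms for x_0 and x_1,
against the combinatorial F = G null, and against Monte Carlo.

## Numerical quadrature

All chained integrals use a fixed grid spanning the component means ± 9
standard deviations.  Two hard-won choices:

* **Exponential-fit rule.**  Intermediate functions such as G(t)^b rise by
  several e-foldings per grid step once b is in the hundreds.  The
  trapezoid rule overestimates every convex segment, and those
  overestimates compound multiplicatively down the chain — for b = 800 the
  pure-trapezoid chain is wrong by tens of orders of magnitude.  Each
  interval is therefore integrated by fitting an exponential through its
  endpoint values, h·(y1−y0)/ln(y1/y0), which is exact on exponential
  segments and second-order accurate in the curvature of log y; near-flat
  or zero-touching intervals fall back to trapezoid.
* **Richardson extrapolation.**  The compounded O(h²) error of ~n+m chained
  cumulative integrations is material (≈10% for n = m = 50 on a
  4001-point grid).  The default table is computed on the base grid and its
  twofold refinement and extrapolated as (4·fine − coarse)/3, reducing the
  error to ~10^-3 relative or better (x_0 for n = m = 50 agrees with
  adaptive quadrature of the closed form to 2·10^-6).

The base grid has max(4001, 16·(n+m)+1) points, scaling with the pooled
sample size because the intermediate functions steepen with it.  Doubling
the resolution is also exposed directly (`IntegrationGrid.refined`) and a
grid-stability test guards the defaults.

## Monte Carlo

Each replicate computes the deficit from a single argsort of the pooled
scores (O((n+m)log(n+m))), stored as an exact integer.  Replicates are
generated in fixed logical blocks of 20,000 from spawned children of the
master `SeedSequence`, so results depend only on (model, n, m, reps, seed)
and never on chunking; the block size keeps even thousand-observation
designs within a couple hundred MB.  10^7 replicates of a 100-observation
design take about a minute on one core.

## Bridge details

* The fit matches *mass*, not just the lattice percentile: the bridged
  upper-tail cumulative at the empirical match percentile is equated (by
  bisection on log C, bracket [10^-3, 10^3], relative tolerance 10^-6) to
  the empirical fraction of simulated AUCs at or above it.  With F = G
  inputs whose empirical distribution equals the exact one this recovers
  C = 1 exactly, the identity that motivates the method.
* Δk guard: Δk_{i−1} = 0 occurs at i = 2 and near nm/2; the previous Δx/Δk
  ratio is carried forward one step and the event is logged.
* Unbalanced designs: the normalised ratio drifts instead of stabilising,
  so an alternative coefficient path c_i = 1 − (1 − C_tail)·((i_med −
  i)/(i_med − i_tail))^p rises monotonically from the tail anchor (mean
  normalised ratio over the last five exact deficits) to 1 at the Monte
  Carlo median deficit, where the S-shaped distribution function forces
  Δx_i/Δx_{i−1} = 1.  The exponent p > 0 is fitted by the same
  percentile-matching criterion.  No closed functional form is canonical
  here; this family was chosen for monotonicity and correct endpoints and
  is validated qualitatively only.
* Assembly concatenates exact (top), bridged, and Monte Carlo (body)
  blocks; a junction mismatch above 5% relative triggers a warning, and
  the default match percentile is the 99.9th (configurable — worked
  examples at desk scale use the 99th, cohort screens the 99.9th+).

## Conventions and edge cases

* **Ties** between a case and a control count ½ toward U (midrank), so real
  data are handled; the null models are continuous, so all exact-tail math
  assumes tie-free samples.  AUC values are stored as exact rationals
  (2U as an integer) to keep lattice binning exact.
* **p-values are inclusive**, P(AUC ≥ observed); off-lattice observations
  use the next lattice point at or above.  Lower-tail questions use the
  symmetry P(AUC = a | F, G) = P(AUC = 1 − a | G, F) (swap the roles).
* **Critical values are conservative** on the discrete lattice: smallest c
  with P(AUC > c) ≤ α, rejection only when observed > c.
* Degenerate requests fail loudly: α below the resolvable tail mass asks
  for a deeper exact tail; a bridge anchored where Δk vanishes asks for one
  more exact deficit.

## What the synthetic generators do and do not cover

The built-in null models are the equal-variance binormal family
(delta = mean difference; population AUC Φ(delta/√2); `binormal_for_auc`
inverts this to realise "on par with a benchmark of AUC 0.88"-style nulls)
and tabulated densities on a grid.  Real biomarker data exhibit ties,
skewness, heavy tails and within-subject correlation that these models do
not; passing tests demonstrate correctness of the distributional machinery
under the stated null, not robustness of the binormal assumption.  Rank
invariance means any strictly monotone transform of a continuous model
yields the same AUC distribution, which softens — but does not remove —
that caveat.

## Known discrepancies with the published worked example

Two printed values in the study this package reproduces do not match its
own model, and the package reproduces the model, not the misprints:

* For n = m = 50, delta = 1, the printed p-value 8.5·10^-16 at AUC 0.99
  equals P(AUC = 1) alone: the closed-form one-dimensional integral for
  the top probability evaluates to 8.488·10^-16.  The inclusive tail sum
  over deficits 0..25 is ~3.6·10^-12, and that value — not 8.5·10^-16 —
  is consistent with the same example's other numbers (57-value tail mass
  5.05·10^-10, critical value 0.9816 at α = 10^-10, p(0.95) = 4.3·10^-7),
  as can be checked with the constant-ratio structure of the tail alone.
* The printed p(0.90) = 4.4·10^-4 matches the constant-C geometric
  interpolation (AUC 0.90 lies beyond the 57 exact values), whereas the
  exact computation extended to deficit 250 — and plain Monte Carlo —
  give 4.68·10^-4.  The bridge is an approximation and this is its
  honest size at three hundred deficits' extrapolation.

The corresponding acceptance checks assert the printed values at their
stated tolerances and are expected to fail; the package's computed values
are reported as such.

## Problem sizes used in tests and the acceptance script

Desk-scale reproductions run the n = m = 50 exact tail to deficit 56,
10^7 Monte Carlo replicates for the 0.90 tail, 10^6 for the bridge match,
10^5 for the mean-AUC check, and the unbalanced 44 × 800 cohort screen at
10^6 replicates matched at the 99.9th percentile (the original cohort
screens used 10^8 replicates matched at the 99.99th; at the reduced scale
the reproduced critical value agrees within ~0.002 AUC).  The whole suite
runs in a few minutes on one core.

## Limitations

* Unequal-variance binormal, discrete score distributions, and correlated
  case/control scores are out of scope; so are smoothed ROC curves,
  DeLong-type variance estimates, and multiplicity procedures beyond
  Bonferroni.
* The exponent-form coefficient path is a pragmatic stand-in validated
  only by its endpoint and monotonicity properties.
* Exact-tail accuracy rests on grid quadrature; for pooled samples far
  beyond ~10^3 observations the default grid scaling has not been
  stress-tested.
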