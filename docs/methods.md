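# Methods

This note records the model, the numerical choices, and the design
decisions behind `netrank`, together with what the synthetic benchmark
does and does not establish.

## Model and assumptions

The input is m rank lists over one universe of n genes plus an
undirected, unweighted simple interaction network on those genes. Two
assumptions drive the method: (i) each list orders genes by strength of
association with one trait, so rank ratios of unassociated genes are
uniform on (0, 1]; (ii) genes close in the network tend to share
function and hence rank. Smoothing each list over the network before
aggregation borrows strength from neighborhoods; aggregation then
rewards genes supported by several lists.

**Normal-score transform.** ra = r/n, z = −Φ⁻¹(ra) with Φ the standard
normal CDF. For a full permutation the z column is a discretized
standard normal, which keeps the smoothing step on a stable scale. The
printed form of the transform's defining integral omits the normal
density's 1/√(2π) constant; we implement the proper CDF, since the
unnormalized variant has no inverse on (0, 1). The boundary ratio 1 is
replaced by 0.9999; we apply the cap to *any* ratio ≥ 0.9999 (not only
exactly 1) so that the map stays monotone when n > 10⁴ makes
(n−1)/n exceed the cap.

**Kernel smoothing (CGI).** The diffusion kernel S = e^(−τL) is the
heat kernel of the graph: a global similarity with unit row sums and
nonnegative entries for every τ ≥ 0. We use its cosine normalization
K_{u,v} = S_{u,v}/√(S_{u,u}S_{v,v}) (unit diagonal, entries in [0, 1]).
The update averages the focal gene's signed score with its neighbors'
*absolute* scores, weighted by K and λ. The absolute value is
implemented as specified by the method's rank-based formulation even
though it lets strongly bottom-ranked neighbors boost a gene — in the
original expression-based setting scores are nonnegative association
strengths, where the distinction vanishes. A `neighbor_abs=False`
switch documents the signed alternative; the default is the faithful
form, and all results reported here use it.

**Propagation (GeneRank).** R solves (I − d·HD⁻¹)R = (1 − d)z. For
isolated genes the corresponding column of HD⁻¹ is set to zero (the
only finite continuous extension), so an isolated gene retains
(1 − d)·z plus incoming mass. The iterative form starts from z itself:
the fixed point of the contraction (d < 1 makes HD⁻¹ column-substochastic)
is start-independent, so the ℓ₁ normalization sometimes quoted for the
starting vector is irrelevant to the limit and is omitted. Stopping
rule: max-entry change < 10⁻⁶ or 1000 iterations; a direct linear solve
is the default and the two routes are tested to agree within 10× the
tolerance.

**Aggregation statistics.** Q is the joint CDF of the ascending-sorted
ratio vector under the m-dimensional uniform order-statistic null,
evaluated by the V_k recursion in plain double precision; the recursion
is validated against nested quadrature and Monte Carlo for the m ranges
that occur in practice (lists per gene set are capped far below 100; a
guard refuses m > 100 where the alternating sum would need log-space
care). ρ is the minimum over positions j of the binomial tail
P(Bin(m, r_(j)) ≥ j), computed via the regularized tail function. ρ is
used *raw* — no Bonferroni correction over j — matching the rank-based
formulation implemented here; `rra_correction="bonferroni"` records the
point where the original robust-aggregation publication departs. Ties
in input ranks propagate to identical ratios (no jitter).

**Deterministic tie rule.** Everywhere a statistic is converted to
ranks, ordering is by (statistic, gene identifier) under a stable sort,
making every output bit-reproducible.

## Tuning and evaluation

Parameters are selected by exhaustive grid search minimizing the
one-sided Wilcoxon rank-sum p-value that training genes rank high
(exact null when both groups ≤ 20 and approximate with tie correction
otherwise; final ranks are tie-free by construction). Defaults:
τ ∈ {0.01, 0.1, 0.5, 1}, λ ∈ {0, 0.1, 0.5, 1, 2, 5},
d ∈ {0, 0.1, 0.3, 0.5, 0.7, 0.9} — spanning the no-network point
through network-dominated regimes; all overridable. Ties in the grid
break toward the earlier grid point.

Cross-validation: per round, the positives are split into `folds`
(default 10) near-equal random subsets; each subset in turn is the
*training* set (parameter selection from scant knowledge), the other
nine are the validation set, scored with training genes excluded from
the background (they informed selection and would contaminate the null
group). Ten rounds of ten folds yield 100 records per (gene set,
method). Baseline (no-network) and network arms share partitions under
the same seed, so log-p-fold = log₁₀(p_base/p_net) is a paired,
per-fold comparison. Parameters are re-selected per aggregator.

Because smoothing and aggregation never look at the training fold, the
tuned candidate lists are identical across folds; the implementation
computes them once per grid point and reuses them, which is
bit-identical to the naive loop and orders of magnitude faster.

The alternative composition (aggregate-then-smooth) converts the
aggregated statistic back to a single rank list, re-applies the
normal-score transform, smooths that one list, and re-ranks by the
smoothed score.

## Synthetic benchmark

The fixture generator plants the assumption the method exploits: a
planted-partition graph whose positive genes form one dense module
(within-module edge probability p_in, background p_out), and per-list
latent scores μ·1{positive} + N(0, sd_j) converted to integer ranks.
Per-list noise may differ, so one list can be pure noise — exercising
the robustness rationale of ρ. The default study conditions are 500
genes, 40 positives, p_in = 0.3, p_out = 0.01, μ = 1.5, five lists with
unit noise, full concordance between module and positives.

The benchmark (`experiments.planted_signal_study`) generates 20 such
fixtures and, per fixture, runs one round of ten folds for every arm:
plain Endeavour/RRA, and kernel-smoothed variants on the true network,
on a label-permuted network, and with 20% / 40% of edges rewired onto
original non-edges. A single split per perturbation condition mirrors
the practice of fixing one train/validation classification once the
round-to-round variability is known to be small; 20 independent
fixtures supply the replication. The null calibration uses 200 smaller
fixtures (200 genes, 20 positives, 3 lists) with μ = 0.

What passing shows: the pipeline recovers planted, network-concordant
signal; the gain vanishes under label permutation and degrades but
survives 40% edge noise; p-values are calibrated under the null. What
it does not show: performance on real interactomes (heavy-tailed
degrees, assortativity), on gene sets spanning several modules, with
correlated lists, or under annotation error — the generator models none
of these.

## Numerical choices and limitations

- The matrix exponential is computed densely per connected component
  (block structure is exact); tiny negative entries from roundoff
  (magnitude ≤ 10⁻¹⁰) are clipped to zero and S is symmetrized, keeping
  the kernel invariants exact. Suitable for desk-scale universes
  (thousands of genes), not proteome-scale dense networks.
- Edge rewiring samples replacement pairs uniformly from the complement
  of the *original* edge set (a removed edge cannot be re-added in the
  same call), enumerating the complement when small and rejection
  sampling otherwise.
- p-values are floored at 10⁻³⁰⁰ so −log₁₀ p stays finite.
- All randomized operations take explicit integer seeds; there is no
  global random state.
- Weighted or directed networks, alternative kernels (random walk with
  restart, shortest path), identifier mapping between naming systems,
  and p-value calibration of Q (the gamma approximation used elsewhere
  for significance, not ordering) are out of scope.
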