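# netrank — network-tuned multiple rank aggregation

Many studies of the same biological question each end in a ranked gene
list: differential expression under a perturbation, co-expression with a
transcription factor, association of variants with a phenotype.
Aggregating those lists into one consensus ranking filters noise, but
standard aggregation ignores a second, independent source of evidence —
the molecular interaction network, where functionally related genes sit
close together and tend to share ranks. `netrank` combines both: each
rank list is smoothed over a protein–protein interaction network before
(or after) the lists are aggregated, and the whole pipeline is tuned and
evaluated by cross-validated enrichment testing.

It is aimed at computational biologists prioritizing genes from multiple
ranked screens who also have an interaction network for the organism.

## The method

Given m rank lists over n genes and an undirected network with adjacency
matrix H, degree diagonal D and Laplacian L = D − H:

1. **Normal-score transform.** Each rank r is normalized to a rank ratio
   ra = r/n ∈ (0, 1] and mapped to z = −Φ⁻¹(ra), with ratios ≥ 0.9999
   capped so z stays finite. Each list becomes a (discretely) standard
   normal score vector, largest z = best rank.
2. **Network smoothing**, one of two operators:
   - *Kernel-weighted averaging (CGI)* with the diffusion kernel
     S = e^(−τL), cosine-normalized to K:

         R_i = ( z_i + λ Σ_{l≠i} |z_l| K_{l,i} ) / ( 1 + λ Σ_{l≠i} K_{l,i} )

     λ ≥ 0 sets the neighborhood's weight, τ ≥ 0 the diffusion scale.
   - *Propagation (GeneRank)*, PageRank-style: R solves
     (I − d·HD⁻¹) R = (1 − d) z with damping d ∈ [0, 1).
3. **Aggregation.** Smoothed scores are re-ranked per list and the m
   rank-ratio vectors per gene are reduced to one statistic, either the
   order-statistic Q (joint CDF of the sorted ratios under the uniform
   null, via the V_k recursion) or the robust rank aggregation score
   ρ = min_j P(Bin(m, r_(j)) ≥ j). Smaller statistic = better gene.
4. **Tuning & evaluation.** (τ, λ) or d are chosen by grid search
   minimizing a one-sided Wilcoxon rank-sum p-value that training genes
   rank high; methods are compared by repeated 10-fold cross-validation
   (each fold in turn is the training set, the rest validate), and by
   controls that permute network labels or rewire a fraction of edges.

Both composition orders are available (smooth-then-aggregate, e.g.
`cgi_rra`, and aggregate-then-smooth, e.g. `rra_cgi`).

## Worked example

```python
from netrank import FixtureConfig, NetworkTunedAggregation, generate_fixture

# synthetic benchmark: 200 genes, 25 positives forming a dense network
# module, 4 rank lists with a 1.5-sigma latent signal
net, ranks, gsc = generate_fixture(
    FixtureConfig(n_genes=200, n_lists=4, n_positives=25, seed=11)
)
training = list(gsc["planted"].genes)[:10]

model = NetworkTunedAggregation(ranks, network=net, training_genes=training)
res = model.fit(tuner="cgi", aggregator="rra")
print(res.summary())
```

```
Network-Tuned Rank Aggregation Results
==========================================
method:          cgi_rra
composition:     tune-then-aggregate
genes (n):       200
lists (m):       4
network edges:   272
parameters:      tau=0.1, lam=2
training p:      1.236e-07
------------------------------------------
top genes (statistic, final rank):
  g0013          1.785e-05    1
  g0072          0.0001       2
  g0005          0.0001749    3
  g0024          0.0002483    4
  g0023          0.0002856    5
```

The grid search picked a positive network weight (λ = 2 at τ = 0.1) and
the training genes are strongly enriched at the top (p ≈ 1.2 × 10⁻⁷).
Held-out positives confirm the network helped:

```python
held_out = [g for g in gsc["planted"].genes if g not in training]
res.enrichment_p(held_out, excluded=training)   # 6.9e-11 with the network
model.fit(tuner="none", aggregator="rra") \
     .enrichment_p(held_out, excluded=training) # 3.5e-09 without
```

The same pipeline is scriptable from the shell — `netrank fixture`,
`transform`, `aggregate`, `evaluate`, `perturb` (see `netrank --help`).

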