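"""Synthetic fixtures with planted, controllable signal.

The generator emulates the working assumption of network-tuned
aggregation — functionally related genes sit close together in the
interaction network and near the top of association rank lists:

* network: a planted-partition graph.  The positives assigned to the
  dense module are wired among themselves with probability ``p_in``;
  every other pair with ``p_out``.
* rank lists: per list j, latent gene scores mu * 1{positive} +
  Normal(0, sd_j) converted to integer ranks (largest score = rank 1).
  Per-list noise can differ, so one list may carry no signal at all.
* gene set: the positives, annotated with pseudo-TF identifiers sized
  to pass the standard gene-set filters when so configured.

Everything is driven by one integer seed; the same config always yields
the same fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GeneSet, GeneSetCollection, GeneUniverse, Network, RankMatrix
from .containers import rank_by_statistic

__all__ = ["FixtureConfig", "generate_fixture"]


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for a planted-signal fixture.

    Defaults describe the benchmark condition used throughout the test
    suite: 500 genes, 40 positives forming one dense module (p_in = 0.3
    against background p_out = 0.01), 5 lists with a mean latent-score
    shift of 1.5 standard deviations for positives.
    """

    n_genes: int = 500
    n_lists: int = 5
    n_positives: int = 40
    p_in: float = 0.3
    p_out: float = 0.01
    signal_strength: float = 1.5  # mean latent-score shift of positives
    list_reliability: float | Sequence[float] = 1.0  # per-list noise sd
    concordance: float = 1.0  # fraction of positives inside the dense module
    n_tfs: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be nonnegative")
        if not 0 < self.n_positives < self.n_genes:
            raise ValueError("need 0 < n_positives < n_genes")
        if not 0 <= self.concordance <= 1:
            raise ValueError("concordance must lie in [0, 1]")

    def noise_sds(self) -> np.ndarray:
        sds = np.broadcast_to(np.asarray(self.list_reliability, dtype=float), (self.n_lists,))
        if np.any(sds <= 0):
            raise ValueError("list noise sds must be positive")
        return np.array(sds)


def generate_fixture(cfg: FixtureConfig) -> tuple[Network, RankMatrix, GeneSetCollection]:
    """Build (network, rank lists, gene sets) with planted signal."""
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    universe = GeneUniverse(genes)

    positives = sorted(rng.choice(cfg.n_genes, size=cfg.n_positives, replace=False).tolist())
    n_module = int(round(cfg.concordance * cfg.n_positives))
    module = set(positives[:n_module])  # positives are exchangeable; any subset works

    in_module = np.zeros(cfg.n_genes, dtype=bool)
    in_module[list(module)] = True
    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    pair_in_module = in_module[iu] & in_module[ju]
    probs = np.where(pair_in_module, cfg.p_in, cfg.p_out)
    keep = rng.random(len(probs)) < probs
    edges = [(genes[i], genes[j]) for i, j in zip(iu[keep], ju[keep])]
    net = Network(universe, edges)
    if cfg.p_in > 0 and net.n_edges == 0:
        raise ValueError("degenerate densities produced an empty graph")

    sds = cfg.noise_sds()
    is_positive = np.zeros(cfg.n_genes, dtype=bool)
    is_positive[positives] = True
    cols = {}
    for j in range(cfg.n_lists):
        latent = cfg.signal_strength * is_positive + rng.normal(0.0, sds[j], cfg.n_genes)
        cols[f"list{j}"] = rank_by_statistic(universe, latent, descending=True).astype(float)
    ranks = RankMatrix(universe, pd.DataFrame(cols, index=genes), kind="integer-rank")

    tfs = tuple(f"TF{k}" for k in range(cfg.n_tfs))
    gsc = GeneSetCollection(
        [GeneSet("planted", tuple(genes[i] for i in positives), tfs)]
    )
    return net, ranks, gsc
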