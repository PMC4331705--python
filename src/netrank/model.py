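"""Model/Results interface over the network-tuned aggregation pipeline.

:class:`NetworkTunedAggregation` bundles the data (rank lists, an
optional interaction network and optional training genes);
``fit()`` selects the tuning parameters on the training genes by grid
search (or uses explicitly supplied ones), runs smoothing and
aggregation in the requested order, and returns a
:class:`NetworkTunedAggregationResults` carrying the per-gene statistic,
final ranks, selected parameters and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as nrio
from .containers import AggregationResult, Network, RankMatrix, ScoreMatrix
from .evaluate import (
    EvalResult,
    KernelCache,
    TuningGrid,
    candidate_results,
    cross_validate,
    select_parameters,
    wilcoxon_enrichment_p,
)
from .transform import TransformConfig

__all__ = ["NetworkTunedAggregation", "NetworkTunedAggregationResults"]


class NetworkTunedAggregation:
    """Network-tuned multiple rank aggregation model.

    Parameters
    ----------
    lists : RankMatrix or ScoreMatrix
        The m rank (or normal-score) lists over one gene universe.
    network : Network, optional
        Undirected interaction network over the same universe.  Needed
        for the 'cgi' and 'gr' tuners.
    training_genes : iterable of str, optional
        Genes known to be associated with the trait; used to select the
        tuning parameters when none are given explicitly.
    ratio_cap : float
        Upper cap for rank ratios before the normal-score transform.
    """

    def __init__(
        self,
        lists: RankMatrix | ScoreMatrix,
        network: Network | None = None,
        training_genes: Iterable[str] | None = None,
        ratio_cap: float = 0.9999,
    ):
        if network is not None and network.universe != lists.universe:
            raise ValueError("network and lists are over different universes")
        self.lists = lists
        self.network = network
        self.training_genes = sorted(set(training_genes)) if training_genes else None
        if self.training_genes:
            missing = [g for g in self.training_genes if g not in lists.universe]
            if missing:
                raise ValueError(f"{len(missing)} training gene(s) not in the universe")
        self.transform_cfg = TransformConfig(ratio_cap=ratio_cap)
        self._kernels = KernelCache(network) if network is not None else None

    @classmethod
    def from_files(
        cls,
        list_paths: Sequence[str | Path],
        network_path: str | Path | None = None,
        mode: str = "rank",
        training_genes: Iterable[str] | None = None,
        **kwargs,
    ) -> "NetworkTunedAggregation":
        lists = nrio.read_rank_lists(list_paths, mode=mode)
        network = (
            nrio.read_network(network_path, universe=lists.universe)
            if network_path is not None
            else None
        )
        return cls(lists, network=network, training_genes=training_genes, **kwargs)

    @property
    def universe(self):
        return self.lists.universe

    def fit(
        self,
        tuner: str = "none",
        aggregator: str = "endeavour",
        order: str = "tune-then-aggregate",
        grid: TuningGrid | None = None,
        tau: float | None = None,
        lam: float | None = None,
        d: float | None = None,
    ) -> "NetworkTunedAggregationResults":
        """Fit the pipeline and return a results object.

        If explicit parameters (tau/lam for 'cgi', d for 'gr') are
        given they are used directly; otherwise a grid search on the
        training genes selects them.
        """
        grid = grid or TuningGrid()
        explicit = self._explicit_grid(tuner, tau, lam, d)
        if explicit is not None:
            grid = explicit
        singleton = (
            tuner == "none"
            or (tuner == "cgi" and len(grid.taus) == 1 and len(grid.lams) == 1)
            or (tuner == "gr" and len(grid.ds) == 1)
        )
        if singleton:
            params, result = candidate_results(
                self.lists, self.network, grid, tuner, aggregator, order,
                self._kernels, transform_cfg=self.transform_cfg,
            )[0]
            training_p = (
                wilcoxon_enrichment_p(result, self.training_genes)
                if self.training_genes
                else None
            )
        else:
            if not self.training_genes:
                raise ValueError(
                    "grid search needs training_genes; pass explicit parameters instead"
                )
            sel = select_parameters(
                self.lists, self.network, self.training_genes, grid,
                tuner, aggregator, order, self._kernels,
            )
            params, result, training_p = sel.params, sel.result, sel.p
        return NetworkTunedAggregationResults(
            model=self,
            result=result,
            params=params,
            tuner=tuner,
            aggregator=aggregator,
            order=order,
            training_p=training_p,
        )

    @staticmethod
    def _explicit_grid(tuner, tau, lam, d) -> TuningGrid | None:
        if tuner == "cgi" and tau is not None and lam is not None:
            return TuningGrid(taus=(tau,), lams=(lam,))
        if tuner == "gr" and d is not None:
            return TuningGrid(ds=(d,))
        return None

    def cross_validate(
        self,
        positives: Iterable[str],
        tuner: str = "cgi",
        aggregator: str = "endeavour",
        grid: TuningGrid | None = None,
        rounds: int = 10,
        folds: int = 10,
        seed: int = 0,
        order: str = "tune-then-aggregate",
        gene_set: str = "geneset",
    ) -> EvalResult:
        """Repeated k-fold evaluation of this model's data (see evaluate)."""
        return cross_validate(
            self.lists, self.network, positives, grid or TuningGrid(),
            tuner, aggregator, rounds=rounds, folds=folds, seed=seed,
            order=order, kernels=self._kernels, gene_set=gene_set,
        )


@dataclass
class NetworkTunedAggregationResults:
    """Fitted prioritization: statistic, final ranks, parameters, diagnostics."""

    model: NetworkTunedAggregation
    result: AggregationResult
    params: dict
    tuner: str
    aggregator: str
    order: str
    training_p: float | None = None

    @property
    def method(self) -> str:
        return self.result.method

    @property
    def statistic(self) -> pd.Series:
        return pd.Series(self.result.statistic, index=list(self.result.universe.genes), name="statistic")

    @property
    def final_ranks(self) -> pd.Series:
        return pd.Series(self.result.final_ranks, index=list(self.result.universe.genes), name="rank")

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.result.to_frame().head(k)

    def enrichment_p(self, positives: Iterable[str], excluded: Iterable[str] = ()) -> float:
        return wilcoxon_enrichment_p(self.result, positives, excluded)

    def to_tsv(self, path: str | Path) -> Path:
        return nrio.write_ranked_list(self.result, path)

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        lines = [
            "Network-Tuned Rank Aggregation Results",
            "=" * 42,
            f"method:          {self.method}",
            f"composition:     {self.order}",
            f"genes (n):       {len(self.result.universe)}",
            f"lists (m):       {self.model.lists.ranks.shape[1] if isinstance(self.model.lists, RankMatrix) else self.model.lists.scores.shape[1]}",
            f"network edges:   {self.model.network.n_edges if self.model.network else 'none'}",
        ]
        if self.params:
            pstr = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
            lines.append(f"parameters:      {pstr}")
        if self.training_p is not None:
            lines.append(f"training p:      {self.training_p:.4g}")
        lines.append("-" * 42)
        lines.append("top genes (statistic, final rank):")
        for row in self.top(5).itertuples(index=False):
            lines.append(f"  {row.gene:<14s} {row.statistic:<12.4g} {row.rank}")
        return "\n".join(lines)

    def plot_statistic(self, ax=None, bins: int = 50):
        """Histogram of the aggregation statistic (matplotlib required)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.result.statistic, bins=bins)
        ax.set_xlabel(f"{self.method} statistic (smaller = better)")
        ax.set_ylabel("genes")
        return ax
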