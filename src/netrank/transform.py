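"""Conversions between integer ranks, rank ratios and normal scores.

A rank list over n genes is normalized to rank ratios ra = r/n in
(0, 1], then mapped to normal scores z = -Phi^{-1}(ra), where Phi is the
standard normal CDF.  The best-ranked gene (smallest ratio) gets the
largest z, and for a full permutation the z column is (discretely)
standard normal — which is what makes downstream network smoothing
stable.  A ratio of 1 has no finite quantile, so ratios at or above
``ratio_cap`` (default 0.9999) are capped first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .containers import GeneUniverse, RankMatrix, ScoreMatrix, rank_by_statistic

__all__ = ["TransformConfig", "ranks_to_ratios", "ratios_to_zscores", "scores_to_ranks"]


@dataclass(frozen=True)
class TransformConfig:
    """Settings for the rank-ratio -> normal-score transform.

    ratio_cap : replacement for rank ratios at the upper boundary; any
        ratio >= ratio_cap is set to ratio_cap so the normal quantile
        stays finite and the transform stays monotone.
    """

    ratio_cap: float = 0.9999

    def __post_init__(self):
        if not 0 < self.ratio_cap < 1:
            raise ValueError("ratio_cap must lie strictly between 0 and 1")


def ranks_to_ratios(rm: RankMatrix) -> RankMatrix:
    """Normalize integer ranks to rank ratios ra = r / n."""
    if rm.kind != "integer-rank":
        raise ValueError("ranks_to_ratios expects an integer-rank matrix")
    n = rm.n_genes
    if n < 1:
        raise ValueError("empty rank matrix")
    ratios = rm.ranks.astype(float) / n
    return RankMatrix(rm.universe, ratios, kind="rank-ratio")


def ratios_to_zscores(
    rm: RankMatrix, cfg: TransformConfig = TransformConfig()
) -> ScoreMatrix:
    """Map rank ratios to normal scores z = -Phi^{-1}(ra).

    Ratios at or above ``cfg.ratio_cap`` are replaced by the cap first,
    so every output is finite and the map stays strictly decreasing in
    the ratio.
    """
    if rm.kind != "rank-ratio":
        raise ValueError("ratios_to_zscores expects a rank-ratio matrix")
    ratios = rm.values()
    if np.any(ratios <= 0):
        raise ValueError("rank ratios must be positive")
    capped = np.minimum(ratios, cfg.ratio_cap)
    z = -ndtri(capped)
    frame = pd.DataFrame(z, index=rm.ranks.index, columns=rm.ranks.columns)
    return ScoreMatrix(rm.universe, frame, meaning="z-score")


def scores_to_ranks(sm: ScoreMatrix) -> RankMatrix:
    """Rank each score column descending: the largest score gets rank 1.

    Ties are broken by gene identifier (lexicographic, stable), so the
    output is reproducible bit-for-bit.
    """
    universe = sm.universe
    cols = {
        name: rank_by_statistic(universe, sm.scores[name].to_numpy(), descending=True)
        for name in sm.list_names
    }
    frame = pd.DataFrame(cols, index=list(universe.genes), dtype=float)
    return RankMatrix(universe, frame, kind="integer-rank")
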