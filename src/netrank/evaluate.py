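"""Parameter tuning and cross-validated evaluation of aggregation methods.

The quality criterion throughout is a one-sided Wilcoxon rank-sum test
that a set of positive genes sits higher (smaller final ranks) in an
aggregated list than the remaining genes: smaller p = better ranking.
Tuning parameters (tau, lam for kernel smoothing; d for propagation)
are chosen by exhaustive grid search minimizing that p-value on a
training set.

Evaluation follows a repeated 10-fold protocol: the positives of a gene
set are split into 10 near-equal folds; each fold in turn plays the
TRAINING set (only ~10% of positives — parameters must be selectable
from little knowledge), and the other nine folds form the validation
set, whose enrichment p-value is recorded with the training genes
excluded from the background.  Ten rounds of ten folds give 100
p-values per (gene set, method).

A key economy: for a fixed grid point the tuned-and-aggregated list
does not depend on which fold is training, so candidate lists are
computed once per grid point and shared across all folds.  The results
are identical to the naive per-fold loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .aggregate import aggregate
from .containers import (
    AggregationResult,
    GeneSetCollection,
    Network,
    RankMatrix,
    ScoreMatrix,
    rank_by_statistic,
)
from .kernel import KernelMatrix, diffusion_kernel
from .transform import TransformConfig, ranks_to_ratios, ratios_to_zscores, scores_to_ranks
from .tuning import GeneRankParams, cgi_update, generank_solve

logger = logging.getLogger(__name__)

__all__ = [
    "TuningGrid",
    "KernelCache",
    "EvalResult",
    "ParameterSelection",
    "wilcoxon_enrichment_p",
    "candidate_results",
    "select_parameters",
    "cross_validate",
    "log_p_fold",
    "correlation_with_training_size",
    "filter_gene_sets",
    "coexpression_rank_lists",
]

_P_FLOOR = 1e-300  # keep p strictly positive so -log10 p stays finite


@dataclass(frozen=True)
class TuningGrid:
    """Candidate values for the tuning parameters.

    Defaults span the no-network point (lam = 0, d = 0) through strongly
    network-dominated regimes.
    """

    taus: tuple[float, ...] = (0.01, 0.1, 0.5, 1.0)
    lams: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 2.0, 5.0)
    ds: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9)

    def __post_init__(self):
        if not (self.taus and self.lams and self.ds):
            raise ValueError("grid axes must be nonempty")
        if any(t < 0 for t in self.taus) or any(l < 0 for l in self.lams):
            raise ValueError("tau and lam candidates must be nonnegative")
        if any(not 0 <= d < 1 for d in self.ds):
            raise ValueError("d candidates must lie in [0, 1)")


class KernelCache:
    """Memoized diffusion kernels for one network, keyed by tau.

    The kernel is the expensive part of smoothing; once computed for a
    (network, tau) pair it is reused across lists, folds and gene sets.
    """

    def __init__(self, net: Network):
        self.net = net
        self._kernels: dict[float, KernelMatrix] = {}

    def get(self, tau: float) -> KernelMatrix:
        if tau not in self._kernels:
            self._kernels[tau] = diffusion_kernel(self.net, tau)
        return self._kernels[tau]


def wilcoxon_enrichment_p(
    result: AggregationResult,
    positives: Iterable[str],
    excluded: Iterable[str] = (),
) -> float:
    """One-sided rank-sum p that ``positives`` rank better than the rest.

    ``excluded`` genes are removed from the background comparison (they
    are in neither group).  The exact null distribution is used when
    both groups have at most 20 members, otherwise the normal
    approximation with tie correction.
    """
    positives = sorted(set(positives))
    excluded = set(excluded)
    if not positives:
        raise ValueError("positives must be nonempty")
    if excluded & set(positives):
        raise ValueError("excluded genes overlap the positives")
    background = [
        g for g in result.universe.genes if g not in excluded and g not in set(positives)
    ]
    if not background:
        raise ValueError("background is empty after exclusions")
    pos_ranks = result.ranks_of(positives)
    bg_ranks = result.ranks_of(background)
    method = "exact" if len(pos_ranks) <= 20 and len(bg_ranks) <= 20 else "asymptotic"
    p = mannwhitneyu(pos_ranks, bg_ranks, alternative="less", method=method).pvalue
    return float(min(max(p, _P_FLOOR), 1.0))


def _ensure_zscores(lists: RankMatrix | ScoreMatrix, cfg: TransformConfig) -> ScoreMatrix:
    if isinstance(lists, ScoreMatrix):
        return lists
    rm = lists if lists.kind == "rank-ratio" else ranks_to_ratios(lists)
    return ratios_to_zscores(rm, cfg)


def _result_from_scores(sm: ScoreMatrix, aggregator: str, method: str) -> AggregationResult:
    res = aggregate(scores_to_ranks(sm), method=aggregator)
    return AggregationResult(res.universe, res.statistic, res.final_ranks, method)


def candidate_results(
    lists: RankMatrix | ScoreMatrix,
    net: Network | None,
    grid: TuningGrid,
    tuner: str,
    aggregator: str,
    order: str = "tune-then-aggregate",
    kernels: KernelCache | None = None,
    neighbor_abs: bool = True,
    transform_cfg: TransformConfig = TransformConfig(),
) -> list[tuple[dict, AggregationResult]]:
    """One (params, aggregated result) pair per grid point, in grid order.

    ``tuner`` is ``'cgi'``, ``'gr'`` or ``'none'``; ``order`` composes
    smoothing and aggregation either way round.  With ``tuner='none'``
    there is a single candidate: plain aggregation.
    """
    if tuner not in ("none", "cgi", "gr"):
        raise ValueError(f"unknown tuner {tuner!r}")
    if order not in ("tune-then-aggregate", "aggregate-then-tune"):
        raise ValueError(f"unknown order {order!r}")
    if aggregator not in ("endeavour", "rra"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    z = _ensure_zscores(lists, transform_cfg)
    if tuner == "none":
        return [({}, _result_from_scores(z, aggregator, aggregator))]
    if net is None:
        raise ValueError(f"tuner {tuner!r} requires a network")

    out: list[tuple[dict, AggregationResult]] = []
    if order == "tune-then-aggregate":
        label = f"{tuner}_{aggregator}"
        if tuner == "cgi":
            kernels = kernels or KernelCache(net)
            for tau in grid.taus:
                K = kernels.get(tau)
                for lam in grid.lams:
                    tuned = cgi_update(z, K, lam, neighbor_abs=neighbor_abs)
                    out.append(
                        ({"tau": tau, "lam": lam}, _result_from_scores(tuned, aggregator, label))
                    )
        else:
            for d in grid.ds:
                tuned = generank_solve(z, net, GeneRankParams(d=d))
                out.append(({"d": d}, _result_from_scores(tuned, aggregator, label)))
        return out

    # aggregate-then-tune: smooth the single aggregated list
    label = f"{aggregator}_{tuner}"
    base = _result_from_scores(z, aggregator, aggregator)
    ranks = pd.DataFrame(
        {"aggregated": base.final_ranks.astype(float)}, index=list(z.universe.genes)
    )
    z1 = ratios_to_zscores(
        ranks_to_ratios(RankMatrix(z.universe, ranks, kind="integer-rank")), transform_cfg
    )
    if tuner == "cgi":
        kernels = kernels or KernelCache(net)
        for tau in grid.taus:
            K = kernels.get(tau)
            for lam in grid.lams:
                tuned = cgi_update(z1, K, lam, neighbor_abs=neighbor_abs)
                stat = -tuned.values()[:, 0]  # larger tuned score = better
                out.append(
                    (
                        {"tau": tau, "lam": lam},
                        AggregationResult.from_statistic(z.universe, stat, label),
                    )
                )
    else:
        for d in grid.ds:
            tuned = generank_solve(z1, net, GeneRankParams(d=d))
            stat = -tuned.values()[:, 0]
            out.append(({"d": d}, AggregationResult.from_statistic(z.universe, stat, label)))
    return out


@dataclass(frozen=True)
class ParameterSelection:
    """Grid-search outcome: selected parameters and the achieved training p."""

    params: dict
    p: float
    result: AggregationResult
    method: str


def select_parameters(
    lists: RankMatrix | ScoreMatrix,
    net: Network | None,
    training: Iterable[str],
    grid: TuningGrid,
    tuner: str,
    aggregator: str,
    order: str = "tune-then-aggregate",
    kernels: KernelCache | None = None,
) -> ParameterSelection:
    """Exhaustive grid search for the parameters minimizing the training p.

    Ties are broken by grid order (the first minimum wins).
    """
    training = sorted(set(training))
    if not training:
        raise ValueError("training set must be nonempty")
    cands = candidate_results(lists, net, grid, tuner, aggregator, order, kernels)
    ps = [wilcoxon_enrichment_p(res, training) for _, res in cands]
    best = int(np.argmin(ps))
    params, result = cands[best]
    return ParameterSelection(params, ps[best], result, result.method)


@dataclass
class EvalResult:
    """Tidy per-fold cross-validation records.

    ``records`` columns: gene_set, method, round, fold, p, p_train, and
    the selected parameters (tau/lam or d; NaN where not applicable).
    """

    records: pd.DataFrame

    REQUIRED = ("gene_set", "method", "round", "fold", "p")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"EvalResult records missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def concat(cls, results: Sequence["EvalResult"]) -> "EvalResult":
        return cls(pd.concat([r.records for r in results], ignore_index=True))

    def neg_log10_p(self) -> pd.Series:
        return -np.log10(self.records["p"])

    def median_neg_log10_p(self, method: str | None = None) -> float:
        df = self.records if method is None else self.records[self.records["method"] == method]
        return float(np.median(-np.log10(df["p"])))

    def summary(self) -> pd.DataFrame:
        """Mean -log10 p per (gene set, method)."""
        df = self.records.copy()
        df["neg_log10_p"] = -np.log10(df["p"])
        return (
            df.groupby(["gene_set", "method"])["neg_log10_p"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )

    def significant_sets(self, threshold: float = 1e-4, methods: Sequence[str] = ("endeavour", "rra")) -> list[str]:
        """Gene sets whose baseline median p beats ``threshold`` for any listed method."""
        keep = []
        df = self.records
        for gene_set in sorted(df["gene_set"].unique()):
            sub = df[df["gene_set"] == gene_set]
            for m in methods:
                ps = sub.loc[sub["method"] == m, "p"]
                if len(ps) and float(np.median(ps)) < threshold:
                    keep.append(gene_set)
                    break
        return keep

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.records.to_csv(path, sep="\t", index=False)
        return path


def cross_validate(
    lists: RankMatrix | ScoreMatrix,
    net: Network | None,
    positives: Iterable[str],
    grid: TuningGrid,
    tuner: str,
    aggregator: str,
    rounds: int = 10,
    folds: int = 10,
    seed: int = 0,
    order: str = "tune-then-aggregate",
    kernels: KernelCache | None = None,
    gene_set: str = "geneset",
) -> EvalResult:
    """Repeated k-fold evaluation of one (tuner, aggregator) combination.

    Per round the positives are randomly partitioned into ``folds``
    near-equal subsets.  Each subset in turn is the TRAINING set used
    for parameter selection; the union of the other subsets is the
    validation set, scored by the enrichment test with the training
    genes excluded from the background.  The same seed always yields
    the same partitions, so paired baseline/network comparisons use
    identical folds.
    """
    positives = sorted(set(positives))
    if len(positives) < folds:
        raise ValueError(f"need at least {folds} positives, got {len(positives)}")
    unknown = [g for g in positives if g not in lists.universe]
    if unknown:
        raise ValueError(f"{len(unknown)} positive gene(s) not in the universe")
    cands = candidate_results(lists, net, grid, tuner, aggregator, order, kernels)
    method = cands[0][1].method
    rng = np.random.default_rng(seed)
    pos_array = np.array(positives, dtype=object)

    rows: list[dict] = []
    for rnd in range(rounds):
        perm = rng.permutation(len(pos_array))
        fold_sets = np.array_split(pos_array[perm], folds)
        for fold_i, fold_genes in enumerate(fold_sets):
            training = sorted(fold_genes.tolist())
            validation = sorted(set(positives) - set(training))
            ps_train = [wilcoxon_enrichment_p(res, training) for _, res in cands]
            best = int(np.argmin(ps_train))
            params, result = cands[best]
            p_val = wilcoxon_enrichment_p(result, validation, excluded=training)
            row = {
                "gene_set": gene_set,
                "method": method,
                "round": rnd,
                "fold": fold_i,
                "p": p_val,
                "p_train": ps_train[best],
                "n_training": len(training),
            }
            row.update(params)
            rows.append(row)
    records = pd.DataFrame(rows)
    for col in ("tau", "lam", "d"):
        if col not in records.columns:
            records[col] = np.nan
    return EvalResult(records)


def log_p_fold(p_base: float, p_net: float) -> float:
    """log10(p_base / p_net): positive when the network helped."""
    if not (0 < p_base <= 1) or not (0 < p_net <= 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.log10(p_base) - np.log10(p_net))


def correlation_with_training_size(
    records: EvalResult,
    training_sizes: Mapping[str, float],
    method: str,
    baseline: str,
) -> tuple[float, float, float]:
    """Spearman correlation between improvement and training-set size.

    Per round, each gene set's mean log-p-fold (baseline vs network
    method, paired by fold) is correlated with its training-set size
    across gene sets, one-sided against positive correlation.  Returns
    the mean and standard deviation of the per-round correlations and
    the mean one-sided p.
    """
    df = records.records
    gene_sets = sorted(set(df["gene_set"].unique()) & set(training_sizes))
    if len(gene_sets) < 3:
        raise ValueError("need at least 3 gene sets for a correlation")
    sizes = np.array([training_sizes[g] for g in gene_sets], dtype=float)
    corrs, ps = [], []
    for rnd in sorted(df["round"].unique()):
        lpf = []
        for gs in gene_sets:
            base = df[(df["gene_set"] == gs) & (df["round"] == rnd) & (df["method"] == baseline)]
            netm = df[(df["gene_set"] == gs) & (df["round"] == rnd) & (df["method"] == method)]
            merged = base.merge(netm, on="fold", suffixes=("_base", "_net"))
            if merged.empty:
                raise ValueError(f"no paired records for gene set {gs!r} round {rnd}")
            lpf.append(float(np.mean(np.log10(merged["p_base"] / merged["p_net"]))))
        lpf = np.asarray(lpf)
        if np.all(lpf == lpf[0]) or np.all(sizes == sizes[0]):
            logger.warning("round %s: constant vector, correlation undefined; skipped", rnd)
            continue
        res = spearmanr(sizes, lpf, alternative="greater")
        corrs.append(float(res.statistic))
        ps.append(float(res.pvalue))
    if not corrs:
        raise ValueError("correlation undefined in every round (constant vectors)")
    return float(np.mean(corrs)), float(np.std(corrs, ddof=1)) if len(corrs) > 1 else 0.0, float(np.mean(ps))


def filter_gene_sets(
    gsc: GeneSetCollection,
    min_genes: int = 30,
    min_tfs: int = 5,
    max_tfs: int = 40,
) -> GeneSetCollection:
    """Keep sets with enough member genes and a workable number of TFs.

    Inclusive at ``min_genes`` and ``min_tfs``; sets with more than
    ``max_tfs`` regulators are dropped.
    """
    kept = [
        s for s in gsc
        if s.n_genes >= min_genes and min_tfs <= s.n_tfs <= max_tfs
    ]
    return GeneSetCollection(kept)


def coexpression_rank_lists(expr: pd.DataFrame, tfs: Sequence[str]) -> RankMatrix:
    """Rank all genes by absolute co-expression with each TF.

    ``expr`` is a genes x conditions table.  For each TF one list is
    produced: genes ordered by descending |Pearson correlation| with the
    TF's expression profile.  Zero-variance profiles get correlation 0
    with a warning; the TF itself stays in its own list at |r| = 1, so
    every list shares one universe.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 conditions")
    from .containers import GeneUniverse

    universe = GeneUniverse(list(expr.index))
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d zero-variance expression profile(s): correlation set to 0", int(zero_var.sum()))
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(zero_var, 1.0, np.sqrt((Xc**2).sum(axis=1)))
    Xn = Xc / denom[:, None]
    cols = {}
    for tf in tfs:
        if tf not in universe:
            raise ValueError(f"TF {tf!r} not in the expression matrix")
        t = Xn[universe.index_of(tf)]
        r = np.abs(Xn @ t)
        r[zero_var] = 0.0
        r[universe.index_of(tf)] = 1.0
        cols[tf] = rank_by_statistic(universe, r, descending=True).astype(float)
    frame = pd.DataFrame(cols, index=list(universe.genes))
    return RankMatrix(universe, frame, kind="integer-rank")
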