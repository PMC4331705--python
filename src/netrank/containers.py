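"""Core in-memory containers shared across the toolkit.

Everything downstream (transforms, kernels, aggregation, evaluation) is
defined over a single, ordered :class:`GeneUniverse`.  Rank and score
tables are thin wrappers around a pandas DataFrame indexed by the
universe; the network wraps a :class:`networkx.Graph` whose node set is
exactly the universe (genes absent from the edge list are isolated
nodes, so every ranked gene has a well-defined degree and kernel row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GeneUniverse",
    "RankMatrix",
    "ScoreMatrix",
    "Network",
    "GeneSet",
    "GeneSetCollection",
    "AggregationResult",
]


class GeneUniverse:
    """An ordered set of unique gene identifiers.

    Parameters
    ----------
    genes : iterable of str
        Gene identifiers in a fixed order.  Duplicates raise ``ValueError``.
    """

    __slots__ = ("genes", "_index")

    def __init__(self, genes: Iterable[str]):
        genes = tuple(str(g) for g in genes)
        index = {g: i for i, g in enumerate(genes)}
        if len(index) != len(genes):
            seen: set[str] = set()
            dup = next(g for g in genes if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene identifier in universe: {dup!r}")
        self.genes = genes
        self._index = index

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __iter__(self):
        return iter(self.genes)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneUniverse) and self.genes == other.genes

    def __hash__(self) -> int:
        return hash(self.genes)

    def __repr__(self) -> str:
        return f"GeneUniverse(n={len(self)})"

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def positions(self, genes: Iterable[str]) -> np.ndarray:
        """Integer positions of ``genes``; unknown genes raise ``KeyError``."""
        return np.fromiter((self._index[g] for g in genes), dtype=np.intp)


def _check_frame(universe: GeneUniverse, table: pd.DataFrame) -> pd.DataFrame:
    if list(table.index) != list(universe.genes):
        raise ValueError("table index does not match the gene universe")
    return table


@dataclass(frozen=True)
class RankMatrix:
    """Genes x lists table of integer ranks or rank ratios.

    ``kind`` is ``"integer-rank"`` (values in 1..n, 1 = best) or
    ``"rank-ratio"`` (values in (0, 1], rank/n, smaller = better).
    """

    universe: GeneUniverse
    ranks: pd.DataFrame
    kind: str = "integer-rank"

    def __post_init__(self):
        if self.kind not in ("integer-rank", "rank-ratio"):
            raise ValueError(f"unknown RankMatrix kind: {self.kind!r}")
        _check_frame(self.universe, self.ranks)
        values = self.ranks.to_numpy(dtype=float)
        n = len(self.universe)
        if self.kind == "integer-rank":
            if not np.all((values >= 1) & (values <= n)):
                raise ValueError(f"integer ranks must lie in 1..{n}")
            if not np.all(values == np.round(values)):
                raise ValueError("integer-rank matrix contains non-integer values")
        else:
            if not np.all((values > 0) & (values <= 1)):
                raise ValueError("rank ratios must lie in (0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    @property
    def n_lists(self) -> int:
        return self.ranks.shape[1]

    @property
    def list_names(self) -> list[str]:
        return list(self.ranks.columns)

    def values(self) -> np.ndarray:
        return self.ranks.to_numpy(dtype=float)


@dataclass(frozen=True)
class ScoreMatrix:
    """Genes x lists table of real-valued association scores.

    ``meaning`` is ``"z-score"`` for normal scores derived from rank
    ratios, or ``"tuned-score"`` for network-updated scores R.  Larger
    score = stronger association = better rank.
    """

    universe: GeneUniverse
    scores: pd.DataFrame
    meaning: str = "z-score"

    def __post_init__(self):
        if self.meaning not in ("z-score", "tuned-score"):
            raise ValueError(f"unknown ScoreMatrix meaning: {self.meaning!r}")
        _check_frame(self.universe, self.scores)
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError("score matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    @property
    def n_lists(self) -> int:
        return self.scores.shape[1]

    @property
    def list_names(self) -> list[str]:
        return list(self.scores.columns)

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


class Network:
    """Undirected simple graph over the gene universe.

    Node set is always exactly the universe; self-loops are forbidden.
    """

    def __init__(self, universe: GeneUniverse, edges: Iterable[tuple[str, str]] = ()):
        graph = nx.Graph()
        graph.add_nodes_from(universe.genes)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r} not allowed")
            if u not in universe or v not in universe:
                raise ValueError(f"edge ({u!r}, {v!r}) leaves the universe")
            graph.add_edge(u, v)
        self.universe = universe
        self.graph = graph

    @property
    def n_nodes(self) -> int:
        return len(self.universe)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges()}

    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 adjacency matrix H in universe order."""
        return nx.to_numpy_array(self.graph, nodelist=self.universe.genes, dtype=float)

    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree[g] for g in self.universe.genes], dtype=float)

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    tfs: tuple[str, ...] = ()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)


class GeneSetCollection:
    """Named gene sets (e.g. GO terms) with optional regulator annotations."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValueError(f"duplicate gene set name: {s.name!r}")
            self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name: {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set


def rank_by_statistic(
    universe: GeneUniverse, statistic: np.ndarray, descending: bool = False
) -> np.ndarray:
    """Assign ranks 1..n to ``statistic`` with deterministic tie-breaking.

    Primary key is the statistic (ascending unless ``descending``),
    secondary key the gene identifier, lexicographic, via a stable sort.
    Returns an integer array of final ranks in universe order.
    """
    stat = np.asarray(statistic, dtype=float)
    if stat.shape != (len(universe),):
        raise ValueError("statistic length does not match universe")
    gene_keys = np.asarray(universe.genes, dtype=object)
    key = -stat if descending else stat
    order = np.lexsort((gene_keys, key))  # last key is primary
    ranks = np.empty(len(universe), dtype=np.int64)
    ranks[order] = np.arange(1, len(universe) + 1)
    return ranks


@dataclass(frozen=True)
class AggregationResult:
    """Outcome of aggregating rank lists into one prioritized list.

    ``statistic`` follows the smaller-is-better convention (the order
    statistic Q or the robust aggregation score rho), and ``final_ranks``
    is the permutation of 1..n induced by it under the deterministic tie
    rule (statistic, then gene identifier).
    """

    universe: GeneUniverse
    statistic: np.ndarray
    final_ranks: np.ndarray
    method: str

    def __post_init__(self):
        n = len(self.universe)
        if self.statistic.shape != (n,) or self.final_ranks.shape != (n,):
            raise ValueError("statistic/final_ranks length does not match universe")
        if sorted(self.final_ranks.tolist()) != list(range(1, n + 1)):
            raise ValueError("final_ranks is not a permutation of 1..n")

    @classmethod
    def from_statistic(
        cls, universe: GeneUniverse, statistic: np.ndarray, method: str
    ) -> "AggregationResult":
        ranks = rank_by_statistic(universe, statistic)
        return cls(universe, np.asarray(statistic, dtype=float), ranks, method)

    def rank_of(self, gene: str) -> int:
        return int(self.final_ranks[self.universe.index_of(gene)])

    def ranks_of(self, genes: Iterable[str]) -> np.ndarray:
        return self.final_ranks[self.universe.positions(genes)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-gene table sorted by final rank."""
        df = pd.DataFrame(
            {
                "gene": list(self.universe.genes),
                "statistic": self.statistic,
                "rank": self.final_ranks,
            }
        )
        return df.sort_values("rank", kind="stable").reset_index(drop=True)

    def ordered_genes(self) -> list[str]:
        inv = np.empty(len(self.universe), dtype=np.intp)
        inv[self.final_ranks - 1] = np.arange(len(self.universe))
        return [self.universe.genes[i] for i in inv]
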