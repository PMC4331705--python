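"""Readers and writers for the plain-text formats the toolkit touches.

Formats
-------
* rank/score lists: two-column TSV ``gene<TAB>value``
* networks: two-column TSV edge lists or SIF (``source type target...``)
* gene sets: GMT (``name<TAB>description<TAB>member...``) with an optional
  companion two-column TSV mapping set name -> transcription-factor id
* ranked outputs: three-column TSV ``gene, statistic, rank``

All files are UTF-8; lines starting with ``#`` are skipped everywhere.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AggregationResult,
    GeneSet,
    GeneSetCollection,
    GeneUniverse,
    Network,
    RankMatrix,
    rank_by_statistic,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_rank_lists",
    "read_network",
    "read_gene_sets",
    "write_rank_lists",
    "write_network",
    "write_gene_sets",
    "write_ranked_list",
    "read_ranked_list",
]


def _data_lines(path: Path):
    """Yield (line_number, stripped_line) skipping comments and blanks."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _read_two_column(path: Path) -> tuple[list[str], list[float]]:
    genes: list[str] = []
    values: list[float] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        gene, value = parts
        if gene in seen:
            raise ValueError(f"{path}: duplicate gene {gene!r}")
        try:
            values.append(float(value))
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-numeric value {value!r} for gene {gene!r}"
            ) from None
        seen.add(gene)
        genes.append(gene)
    return genes, values


def read_rank_lists(paths: Sequence[str | Path], mode: str = "rank") -> RankMatrix:
    """Read one rank list per file into a single :class:`RankMatrix`.

    In ``rank`` mode each value must be an integer rank in 1..n.  In
    ``score`` mode values are arbitrary finite scores and are converted
    to integer ranks per list (descending score = rank 1, ties broken by
    gene identifier) before storage.

    All files must cover the same gene set — the shared universe is the
    union across files, and a gene missing from any one file is an error
    rather than being imputed.
    """
    if mode not in ("rank", "score"):
        raise ValueError(f"mode must be 'rank' or 'score', got {mode!r}")
    if not paths:
        raise ValueError("no input files given")
    paths = [Path(p) for p in paths]
    per_file: list[tuple[list[str], list[float]]] = [_read_two_column(p) for p in paths]

    ordered_genes: list[str] = []
    seen: set[str] = set()
    for genes, _ in per_file:
        for g in genes:
            if g not in seen:
                seen.add(g)
                ordered_genes.append(g)
    universe = GeneUniverse(ordered_genes)

    for path, (genes, _) in zip(paths, per_file):
        missing = seen - set(genes)
        if missing:
            raise ValueError(
                f"{path}: {len(missing)} genes of the shared universe are missing "
                f"(e.g. {sorted(missing)[:3]}); lists must share one gene set"
            )

    n = len(universe)
    columns: dict[str, np.ndarray] = {}
    for path, (genes, values) in zip(paths, per_file):
        pos = universe.positions(genes)
        col = np.empty(n, dtype=float)
        col[pos] = values
        name = path.stem
        if name in columns:
            name = str(path)
        if mode == "rank":
            if not np.all(col == np.round(col)):
                raise ValueError(f"{path}: ranks must be integers")
            if col.min() < 1 or col.max() > n:
                raise ValueError(f"{path}: ranks must lie in 1..{n}")
            columns[name] = col
        else:
            columns[name] = rank_by_statistic(universe, col, descending=True).astype(float)

    frame = pd.DataFrame(columns, index=list(universe.genes))
    return RankMatrix(universe, frame, kind="integer-rank")


def read_network(path: str | Path, universe: GeneUniverse | None = None) -> Network:
    """Read an undirected simple network from a TSV or SIF edge list.

    Two columns make an edge; three or more columns are interpreted as
    SIF (``source interaction-type target [target...]``, the type column
    ignored).  Duplicate and reversed-duplicate edges collapse; self-loops
    are dropped with a logged count.  With a ``universe``, edges touching
    unknown genes are dropped and universe genes absent from the file
    become isolated nodes; without one, the universe is the node set in
    order of first appearance.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    node_order: list[str] = []
    node_seen: set[str] = set()
    n_self_loops = 0
    n_lines = 0
    for lineno, line in _data_lines(path):
        n_lines += 1
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: malformed edge line")
        if len(parts) == 2:
            pairs = [(parts[0], parts[1])]
        else:  # SIF: source, type, one or more targets
            pairs = [(parts[0], t) for t in parts[2:]]
        for u, v in pairs:
            if u == v:
                n_self_loops += 1
                continue
            for g in (u, v):
                if g not in node_seen:
                    node_seen.add(g)
                    node_order.append(g)
            edges.append((u, v))
    if n_lines == 0:
        raise ValueError(f"{path}: empty network file")
    if n_self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_self_loops)

    if universe is None:
        universe = GeneUniverse(node_order)
        kept = edges
    else:
        kept = [(u, v) for u, v in edges if u in universe and v in universe]
        n_dropped = len(edges) - len(kept)
        if n_dropped:
            logger.info("%s: dropped %d edge(s) outside the universe", path, n_dropped)
    return Network(universe, kept)


def read_gene_sets(
    path: str | Path,
    tf_path: str | Path | None = None,
    universe: GeneUniverse | None = None,
) -> GeneSetCollection:
    """Read GMT gene sets, optionally with TF annotations and a universe filter.

    Members outside the universe are dropped with a logged count; sets
    left without members are skipped with a warning.
    """
    path = Path(path)
    tf_map: dict[str, list[str]] = {}
    if tf_path is not None:
        for lineno, line in _data_lines(Path(tf_path)):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{tf_path}:{lineno}: expected 2 columns")
            tf_map.setdefault(parts[0], []).append(parts[1])

    collection = GeneSetCollection()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: malformed GMT line")
        name, _desc, *members = parts
        deduped: list[str] = []
        seen: set[str] = set()
        for m in members:
            if m and m not in seen:
                seen.add(m)
                deduped.append(m)
        if universe is not None:
            in_universe = [m for m in deduped if m in universe]
            n_dropped = len(deduped) - len(in_universe)
            if n_dropped:
                logger.info(
                    "%s: set %s: dropped %d member(s) outside the universe",
                    path, name, n_dropped,
                )
            deduped = in_universe
        if not deduped:
            logger.warning("%s:%d: skipping empty gene set %s", path, lineno, name)
            continue
        collection.add(GeneSet(name, tuple(deduped), tuple(tf_map.get(name, ()))))
    return collection


def write_rank_lists(rm: RankMatrix, directory: str | Path) -> list[Path]:
    """Write each column as a two-column TSV; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in rm.list_names:
        p = directory / f"{name}.tsv"
        col = rm.ranks[name]
        with open(p, "w", encoding="utf-8") as fh:
            for gene, value in col.items():
                v = int(value) if rm.kind == "integer-rank" else value
                fh.write(f"{gene}\t{v}\n")
        paths.append(p)
    return paths


def write_network(net: Network, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges()):
            fh.write(f"{u}\t{v}\n")
    return path


def write_gene_sets(
    gsc: GeneSetCollection, gmt_path: str | Path, tf_path: str | Path | None = None
) -> None:
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for s in gsc:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")
    if tf_path is not None:
        with open(tf_path, "w", encoding="utf-8") as fh:
            for s in gsc:
                for tf in s.tfs:
                    fh.write(f"{s.name}\t{tf}\n")


def write_ranked_list(result: AggregationResult, path: str | Path) -> Path:
    """Write an aggregated ranking as TSV (gene, statistic, rank).

    Rows are ordered by final rank, which already encodes the
    deterministic tie rule (statistic, then gene identifier).
    """
    path = Path(path)
    frame = result.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tstatistic\trank\n")
        for row in frame.itertuples(index=False):
            fh.write(f"{row.gene}\t{row.statistic:.10g}\t{row.rank}\n")
    return path


def read_ranked_list(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_ranked_list` output."""
    return pd.read_csv(path, sep="\t", comment="#")
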