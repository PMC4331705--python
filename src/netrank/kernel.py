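"""Graph Laplacian, diffusion kernel, and network surgery.

The diffusion kernel S = exp(-tau * L), with L = D - H the combinatorial
Laplacian, measures global node similarity: S_{u,v} is the probability
that a continuous-time "lazy" random walk of duration tau started at u
sits at v.  Rows of S sum to one and entries are nonnegative for every
graph and tau >= 0.  The kernel used downstream is the cosine
normalization K_{u,v} = S_{u,v} / sqrt(S_{u,u} S_{v,v}), which has unit
diagonal and entries in [0, 1].

This module also hosts the network perturbations used to probe whether
an observed gain really comes from network structure: merging several
networks, permuting node labels (topology kept, biology destroyed), and
rewiring a fraction of edges onto previously non-interacting pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.linalg import expm

from .containers import GeneUniverse, Network

__all__ = [
    "KernelMatrix",
    "laplacian",
    "diffusion_kernel",
    "merge_networks",
    "permute_labels",
    "inject_noise",
]

# expm of a Metzler matrix is nonnegative in exact arithmetic; entries
# below -_NEG_TOL indicate a real numerical problem rather than roundoff.
_NEG_TOL = 1e-10


@dataclass(frozen=True)
class KernelMatrix:
    """Normalized diffusion-kernel similarity over the gene universe."""

    universe: GeneUniverse
    values: np.ndarray
    tau: float

    def __post_init__(self):
        n = len(self.universe)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match universe")


def laplacian(net: Network) -> np.ndarray:
    """Combinatorial Laplacian L = D - H in universe order."""
    H = net.adjacency()
    return np.diag(H.sum(axis=1)) - H


def diffusion_kernel(net: Network, tau: float) -> KernelMatrix:
    """Diffusion kernel S = exp(-tau L), cosine-normalized to K.

    The exponential is taken per connected component (the exponential of
    a block-diagonal matrix is block-diagonal), so isolated genes get a
    kernel row that is 1 on the diagonal and 0 elsewhere.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    n = net.n_nodes
    S = np.zeros((n, n))
    if tau == 0:
        np.fill_diagonal(S, 1.0)
    else:
        for comp in nx.connected_components(net.graph):
            idx = net.universe.positions(sorted(comp))
            if len(idx) == 1:
                S[idx[0], idx[0]] = 1.0
                continue
            sub = nx.to_numpy_array(net.graph, nodelist=[net.universe.genes[i] for i in idx])
            L = np.diag(sub.sum(axis=1)) - sub
            block = expm(-tau * L)
            if block.min() < -_NEG_TOL:
                raise FloatingPointError("diffusion kernel went significantly negative")
            block = np.clip((block + block.T) / 2.0, 0.0, None)
            S[np.ix_(idx, idx)] = block
    d = np.sqrt(np.diag(S))
    K = S / np.outer(d, d)
    K = np.clip((K + K.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(net.universe, K, float(tau))


def raw_diffusion(net: Network, tau: float) -> np.ndarray:
    """Unnormalized S = exp(-tau L); exposed for diagnostics and tests."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    return expm(-tau * laplacian(net))


def merge_networks(nets: list[Network]) -> Network:
    """Union of node sets and edge sets across networks.

    The merged universe preserves order of first appearance across the
    inputs; duplicate edges collapse.
    """
    if not nets:
        raise ValueError("merge_networks needs at least one network")
    genes: list[str] = []
    seen: set[str] = set()
    for net in nets:
        for g in net.universe.genes:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    universe = GeneUniverse(genes)
    edges: set[tuple[str, str]] = set()
    for net in nets:
        for u, v in net.graph.edges():
            edges.add((u, v) if u <= v else (v, u))
    return Network(universe, sorted(edges))


def permute_labels(net: Network, seed: int) -> Network:
    """Shuffle gene names over the network, keeping topology intact.

    The returned network has the same universe and the same unlabeled
    graph (hence the same degree multiset), but node identities are
    reassigned uniformly at random — destroying any correlation between
    network position and gene scores.
    """
    rng = np.random.default_rng(seed)
    genes = list(net.universe.genes)
    perm = rng.permutation(len(genes))
    mapping = {genes[i]: genes[perm[i]] for i in range(len(genes))}
    edges = [(mapping[u], mapping[v]) for u, v in net.graph.edges()]
    return Network(net.universe, edges)


def inject_noise(net: Network, alpha_pct: float, seed: int) -> Network:
    """Replace alpha% of edges with uniformly sampled original non-edges.

    Exactly ``round(alpha/100 * |E|)`` edges are removed (sampled without
    replacement) and the same number of new edges added; each addition is
    drawn uniformly from unordered pairs that were non-edges in the
    ORIGINAL network and have not already been added.  The edge count is
    conserved and no self-loops appear.
    """
    if not 0 <= alpha_pct <= 100:
        raise ValueError("alpha_pct must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    edges = sorted(tuple(sorted(e)) for e in net.graph.edges())
    n_replace = int(round(alpha_pct / 100.0 * len(edges)))
    if n_replace == 0:
        return Network(net.universe, edges)
    n = net.n_nodes
    n_pairs = n * (n - 1) // 2
    n_non_edges = n_pairs - len(edges)
    if n_non_edges < n_replace:
        raise ValueError(
            f"graph has only {n_non_edges} non-edges; cannot host {n_replace} replacements"
        )
    remove_idx = set(rng.choice(len(edges), size=n_replace, replace=False).tolist())
    kept = [e for i, e in enumerate(edges) if i not in remove_idx]

    genes = net.universe.genes
    edge_set = set(edges)
    added: set[tuple[str, str]] = set()
    if n_pairs <= 200_000:
        complement = [
            (genes[i], genes[j])
            for i, j in itertools.combinations(range(n), 2)
            if (genes[i], genes[j]) not in edge_set and (genes[j], genes[i]) not in edge_set
        ]
        pick = rng.choice(len(complement), size=n_replace, replace=False)
        added = {complement[i] for i in pick.tolist()}
    else:  # rejection sampling against the (sparse) original edge set
        while len(added) < n_replace:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            u, v = (genes[i], genes[j]) if genes[i] <= genes[j] else (genes[j], genes[i])
            if (u, v) in edge_set or (u, v) in added:
                continue
            added.add((u, v))
    return Network(net.universe, kept + sorted(added))
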