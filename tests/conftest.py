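"""Shared fixtures and independent oracles for the test suite."""

from math import comb, factorial

import numpy as np
import pandas as pd
import pytest

from netrank import GeneUniverse, Network, RankMatrix, ScoreMatrix
from netrank.experiments import planted_signal_study


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)

def q_oracle_quadrature(ratios) -> float:
    """Order-statistic joint CDF by nested Gauss-Legendre quadrature.

    The nested integrand is a polynomial of degree <= m in each
    variable, so 6-node Gauss-Legendre per level is exact (up to
    roundoff) for m <= 4.
    """
    r = np.sort(np.asarray(ratios, dtype=float))
    m = len(r)
    nodes, weights = np.polynomial.legendre.leggauss(6)

    def inner(level: int, lower: float) -> float:
        if level == m:
            return 1.0
        a, b = lower, r[level]
        if b <= a:
            return 0.0
        x = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        vals = np.array([inner(level + 1, xi) for xi in x])
        return 0.5 * (b - a) * float(weights @ vals)

    return factorial(m) * inner(0, 0.0)


def q_oracle_monte_carlo(ratios, n_draws: int, rng) -> float:
    """P(all m sorted uniforms <= componentwise sorted bounds), simulated."""
    r = np.sort(np.asarray(ratios, dtype=float))
    u = np.sort(rng.random((n_draws, len(r))), axis=1)
    return float(np.all(u <= r[None, :], axis=1).mean())


def rho_oracle_factorial(ratios) -> float:
    """Minimum binomial tail over order-statistic positions, via factorials."""
    r = sorted(float(x) for x in ratios)
    m = len(r)

    def beta(j: int) -> float:
        p = r[j - 1]
        return sum(comb(m, l) * p**l * (1.0 - p) ** (m - l) for l in range(j, m + 1))

    return min(beta(j) for j in range(1, m + 1))


# ---------------------------------------------------------------------------
# small builders

def make_rank_matrix(columns: dict[str, list[float]], genes: list[str]) -> RankMatrix:
    universe = GeneUniverse(genes)
    frame = pd.DataFrame(columns, index=genes, dtype=float)
    return RankMatrix(universe, frame, kind="integer-rank")


def make_score_matrix(columns: dict[str, list[float]], genes: list[str]) -> ScoreMatrix:
    universe = GeneUniverse(genes)
    frame = pd.DataFrame(columns, index=genes, dtype=float)
    return ScoreMatrix(universe, frame, meaning="z-score")


def random_network(n: int, p: float, rng) -> Network:
    """Erdos-Renyi network over string gene ids."""
    genes = [f"n{i:04d}" for i in range(n)]
    universe = GeneUniverse(genes)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < p
    edges = [(genes[i], genes[j]) for i, j in zip(iu[keep], ju[keep])]
    return Network(universe, edges)


# ---------------------------------------------------------------------------
# session-scoped benchmark shared by the planted-signal pattern tests

@pytest.fixture(scope="session")
def planted_study() -> pd.DataFrame:
    """20-fixture benchmark: plain vs kernel-smoothed aggregation under the
    true, label-permuted and edge-rewired network conditions."""
    return planted_signal_study(n_seeds=20, seed=0)
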