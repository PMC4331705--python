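"""Aggregation of m rank-ratio lists into one prioritized list.

Two statistics, both computed on a gene's rank ratios sorted ascending,
both smaller-is-better:

* the order statistic Q — the joint cumulative probability that the m
  sorted ratios of i.i.d. uniforms fall below the observed sorted
  ratios, evaluated by the V_k recursion
      V_0 = 1,  V_k = sum_{l=1..k} (-1)^(l-1) * V_{k-l} / l! * r_{m-k+1}^l,
      Q = m! * V_m
* the robust aggregation score rho — the minimum over j of the binomial
  tail probability that the j-th order statistic of m uniforms is at
  most the observed j-th smallest ratio:
      beta_j = sum_{l=j..m} C(m,l) r_j^l (1-r_j)^(m-l),  rho = min_j beta_j.

Q rewards genes consistently near the top of every list; rho rewards a
gene that is near the top of at least a few lists, which makes it robust
when some lists carry no signal.  Neither is corrected for the minimum
over j by default (an optional Bonferroni switch records the point where
the original robust-aggregation method departs).
"""

from __future__ import annotations

from math import factorial

import numpy as np
from scipy.stats import binom

from .containers import AggregationResult, RankMatrix
from .transform import ranks_to_ratios

__all__ = ["endeavour_q", "rra_rho", "aggregate"]

_MAX_LISTS = 100  # the double-precision V_k recursion is validated well below this


def _as_sorted_ratios(ratios: np.ndarray) -> np.ndarray:
    r = np.asarray(ratios, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("ratios must be a nonempty 1-D vector")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("ratios must lie in [0, 1]")
    return np.sort(r)


def _q_from_sorted(sorted_ratios: np.ndarray) -> np.ndarray:
    """Vectorized V_k recursion over rows of an (n_genes, m) sorted array."""
    r = sorted_ratios
    m = r.shape[1]
    if m > _MAX_LISTS:
        raise ValueError(f"more than {_MAX_LISTS} lists; recursion not validated there")
    V = np.zeros((r.shape[0], m + 1))
    V[:, 0] = 1.0
    for k in range(1, m + 1):
        acc = np.zeros(r.shape[0])
        base = r[:, m - k]  # r_{m-k+1} in 1-based indexing
        power = np.ones_like(base)
        for l in range(1, k + 1):
            power = power * base
            acc += (-1.0) ** (l - 1) * V[:, k - l] / factorial(l) * power
        V[:, k] = acc
    return factorial(m) * V[:, m]


def _rho_from_sorted(sorted_ratios: np.ndarray, correction: str = "none") -> np.ndarray:
    r = sorted_ratios
    m = r.shape[1]
    j = np.arange(1, m + 1)
    beta = binom.sf(j[None, :] - 1, m, r)  # P(Bin(m, r_j) >= j)
    rho = beta.min(axis=1)
    if correction == "bonferroni":
        rho = np.minimum(rho * m, 1.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return rho


def endeavour_q(ratios: np.ndarray) -> float:
    """Order-statistic Q for one gene's vector of m rank ratios."""
    r = _as_sorted_ratios(ratios)
    return float(_q_from_sorted(r[None, :])[0])


def rra_rho(ratios: np.ndarray, correction: str = "none") -> float:
    """Robust aggregation score rho for one gene's vector of rank ratios."""
    r = _as_sorted_ratios(ratios)
    return float(_rho_from_sorted(r[None, :], correction)[0])


def aggregate(
    rm: RankMatrix, method: str = "endeavour", rra_correction: str = "none"
) -> AggregationResult:
    """Aggregate a rank matrix into one prioritized list.

    Integer ranks are normalized to rank ratios first.  The per-gene
    statistic is computed on that gene's ascending-sorted ratio vector;
    final ranks ascend in the statistic, ties broken by gene identifier.
    """
    if method not in ("endeavour", "rra"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if rm.kind == "integer-rank":
        rm = ranks_to_ratios(rm)
    sorted_ratios = np.sort(rm.values(), axis=1)
    if method == "endeavour":
        stat = _q_from_sorted(sorted_ratios)
    else:
        stat = _rho_from_sorted(sorted_ratios, rra_correction)
    return AggregationResult.from_statistic(rm.universe, stat, method)
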