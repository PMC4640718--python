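"""Independent brute-force re-implementations used only as test oracles.

Everything here is recomputed directly from the defining formulas with
plain Python loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations


def sd(xs: list[float]) -> float:
    n = len(xs)
    mean = sum(xs) / n
    return math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1))


def brute_pairwise_v(quantities: dict[str, list[float]], j: str, k: str) -> float:
    ratios = [math.log2(a / b) for a, b in zip(quantities[j], quantities[k])]
    return sd(ratios)


def brute_m_values(quantities: dict[str, list[float]], genes: list[str]) -> dict[str, float]:
    ms = {}
    for j in genes:
        vs = [brute_pairwise_v(quantities, j, k) for k in genes if k != j]
        ms[j] = sum(vs) / len(vs)
    return ms


def brute_stepwise(quantities: dict[str, list[float]]):
    """Exclusion order, M trajectory and final pair, straight from the rules."""
    remaining = sorted(quantities)
    order, trajectory = [], []
    while len(remaining) > 2:
        ms = brute_m_values(quantities, remaining)
        trajectory.append(dict(ms))
        worst_m = max(ms.values())
        tied = sorted(g for g, m in ms.items() if m == worst_m)
        removed = tied[-1]  # lexicographically last among ties
        order.append(removed)
        remaining.remove(removed)
    trajectory.append(brute_m_values(quantities, remaining))
    return order, trajectory, tuple(sorted(remaining))


def brute_nf(quantities: dict[str, list[float]], genes: list[str]) -> list[float]:
    n_samples = len(next(iter(quantities.values())))
    out = []
    for s in range(n_samples):
        prod = 1.0
        for g in genes:
            prod *= quantities[g][s]
        out.append(prod ** (1.0 / len(genes)))
    return out


def brute_v_series(quantities: dict[str, list[float]], ranking: list[str]) -> dict[int, float]:
    k = len(ranking)
    series = {}
    for n in range(2, k):
        nf_n = brute_nf(quantities, ranking[:n])
        nf_n1 = brute_nf(quantities, ranking[: n + 1])
        series[n] = sd([math.log2(a / b) for a, b in zip(nf_n, nf_n1)])
    return series
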