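"""geNorm reference-gene stability analysis.

The geNorm model rests on one idea: the expression *ratio* of two ideal
reference genes is identical in every sample, so the spread of that ratio
measures how far a pair is from ideal. For genes j and k with linear
quantities a_j, a_k the pairwise variation

    V_jk = SD over samples of log2(a_j / a_k)   (n−1 denominator)

is zero for perfectly co-stable genes. A gene's stability value

    M_j = mean over k≠j of V_jk

is its average pairwise variation with every other candidate; low M means
stable. Because M is defined on ratios, a per-sample loading factor
common to all genes cancels exactly, and rescaling one gene only adds a
constant to its log-ratios, leaving every SD unchanged.

Ranking proceeds by stepwise exclusion: repeatedly drop the gene with the
highest M and recompute, until two genes remain (a single ratio cannot
order its two members, so the final pair is reported as joint best).

To decide how many reference genes a normalization needs, per-sample
normalization factors NF_n — geometric means of the n most stable genes —
are compared sequentially: V(n/n+1) = SD over samples of
log2(NF_n / NF_n+1). Once V(n/n+1) falls below 0.15, the (n+1)-th gene no
longer changes the factor materially and n genes suffice.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import CtMatrix, ExpressionMatrix
from .preprocess import ct_to_relative_quantity

logger = logging.getLogger(__name__)

DEFAULT_M_CUTOFF = 1.5
DEFAULT_V_CUTOFF = 0.15


@dataclass
class GeNormResult:
    """Stepwise-exclusion trajectory, normalization factors and V series.

    Attributes
    ----------
    exclusion_order
        Genes in removal order (first = least stable).
    m_trajectory
        One mapping gene -> M per exclusion step, starting with the full
        gene set and ending with the final pair.
    final_pair
        The two genes never excluded (joint rank 1–2).
    m_at_removal
        Each gene's M value at the step it was excluded (final pair: the
        two-gene M).
    nf_table
        Per-sample NF_n for n = 2..k (columns), geometric means of the n
        most stable genes.
    v_series
        Pairwise variation V(n/n+1) for n = 2..k−1.
    optimal_n
        Smallest n with V(n/n+1) below the cutoff, or k if none passes.
    no_n_satisfies_cutoff
        True when the fallback (optimal_n = k) was taken.
    tie_breaks
        Steps at which the maximal-M tie rule fired (provenance).
    """

    exclusion_order: list[str] = field(default_factory=list)
    m_trajectory: list[dict[str, float]] = field(default_factory=list)
    final_pair: tuple[str, str] | None = None
    m_at_removal: dict[str, float] = field(default_factory=dict)
    nf_table: pd.DataFrame | None = None
    v_series: dict[int, float] = field(default_factory=dict)
    optimal_n: int | None = None
    no_n_satisfies_cutoff: bool = False
    tie_breaks: list[dict] = field(default_factory=list)

    @property
    def ranking_order(self) -> list[str]:
        """Genes from most to least stable: final pair first, then reverse exclusion."""
        if self.final_pair is None:
            raise ValueError("ranking not computed")
        return list(self.final_pair) + list(reversed(self.exclusion_order))

    def ranks(self) -> dict[str, int]:
        """Rank per gene; the final pair shares rank 1 (joint rank 1–2)."""
        order = self.ranking_order
        ranks = {g: i + 1 for i, g in enumerate(order)}
        for g in self.final_pair:
            ranks[g] = 1
        return ranks

    def to_frame(self) -> pd.DataFrame:
        order = self.ranking_order
        ranks = self.ranks()
        steps = {g: i + 1 for i, g in enumerate(self.exclusion_order)}
        return pd.DataFrame(
            {
                "gene": order,
                "M": [self.m_at_removal[g] for g in order],
                "rank": [ranks[g] for g in order],
                "step_excluded": [steps.get(g, 0) for g in order],
            }
        )


def _as_quantities(expr: ExpressionMatrix | CtMatrix) -> ExpressionMatrix:
    if isinstance(expr, CtMatrix):
        return ct_to_relative_quantity(expr)
    return expr


def _log2_matrix(expr: ExpressionMatrix, genes: Sequence[str] | None = None) -> pd.DataFrame:
    values = expr.values if genes is None else expr.values.loc[list(genes)]
    arr = values.to_numpy()
    if (arr <= 0).any() or np.isnan(arr).any():
        g, s = np.argwhere(~(arr > 0))[0]
        raise ValueError(
            f"nonpositive/missing quantity at gene {values.index[g]!r}, "
            f"sample {values.columns[s]!r}; geNorm needs strictly positive quantities"
        )
    return pd.DataFrame(np.log2(arr), index=values.index, columns=values.columns)


def pairwise_variation(expr: ExpressionMatrix | CtMatrix, gene_j: str, gene_k: str) -> float:
    """V_jk: SD (n−1) over samples of log2 quantity ratio of genes j and k."""
    expr = _as_quantities(expr)
    y = _log2_matrix(expr, [gene_j, gene_k])
    if y.shape[1] < 2:
        raise ValueError("pairwise variation needs at least 2 samples")
    ratios = y.iloc[0].to_numpy() - y.iloc[1].to_numpy()
    return float(np.std(ratios, ddof=1))


def m_values(
    expr: ExpressionMatrix | CtMatrix, gene_set: Iterable[str] | None = None
) -> dict[str, float]:
    """M value per gene: mean pairwise variation with all other genes in the set."""
    expr = _as_quantities(expr)
    genes = list(gene_set) if gene_set is not None else expr.gene_ids
    if len(genes) < 2:
        raise ValueError("M values need at least 2 genes")
    y = _log2_matrix(expr, genes).to_numpy()
    if y.shape[1] < 2:
        raise ValueError("M values need at least 2 samples")
    k = len(genes)
    v = np.zeros((k, k))
    for j, l in itertools.combinations(range(k), 2):
        v[j, l] = v[l, j] = np.std(y[j] - y[l], ddof=1)
    m = v.sum(axis=1) / (k - 1)
    return {g: float(m_g) for g, m_g in zip(genes, m)}


def stepwise_ranking(expr: ExpressionMatrix | CtMatrix) -> GeNormResult:
    """Rank genes by stepwise exclusion of the highest-M gene.

    Ties at the maximal M are broken by removing the lexicographically
    last gene id; every tie-break is recorded in the result provenance.
    """
    expr = _as_quantities(expr)
    remaining = list(expr.gene_ids)
    if len(remaining) < 3:
        raise ValueError("stepwise ranking needs at least 3 genes")
    result = GeNormResult()
    step = 0
    while len(remaining) > 2:
        m = m_values(expr, remaining)
        result.m_trajectory.append(m)
        max_m = max(m.values())
        worst = sorted(g for g, v in m.items() if v == max_m)
        if len(worst) > 1:
            result.tie_breaks.append({"step": step + 1, "tied": worst, "removed": worst[-1]})
        removed = worst[-1]
        result.exclusion_order.append(removed)
        result.m_at_removal[removed] = m[removed]
        remaining.remove(removed)
        step += 1
    final_m = m_values(expr, remaining)
    result.m_trajectory.append(final_m)
    result.final_pair = tuple(sorted(remaining))
    for g in result.final_pair:
        result.m_at_removal[g] = final_m[g]
    return result


def normalization_factor(
    expr: ExpressionMatrix | CtMatrix, genes: Sequence[str]
) -> pd.Series:
    """NF per sample: geometric mean of the given genes' quantities."""
    expr = _as_quantities(expr)
    if len(genes) < 1:
        raise ValueError("normalization factor needs at least 1 gene")
    y = _log2_matrix(expr, genes)
    return pd.Series(2.0 ** y.to_numpy().mean(axis=0), index=y.columns, name=f"NF_{len(genes)}")


def nf_pairwise_variation(
    expr: ExpressionMatrix | CtMatrix, ranking: GeNormResult
) -> GeNormResult:
    """Fill nf_table and v_series: V(n/n+1) = SD of log2(NF_n/NF_n+1), n = 2..k−1.

    NF_n is built over the n most stable genes of the final ranking
    (final pair first, then reverse exclusion order).
    """
    expr = _as_quantities(expr)
    order = ranking.ranking_order
    k = len(order)
    if k < 3:
        raise ValueError("V series needs at least 3 genes")
    nfs = {n: normalization_factor(expr, order[:n]) for n in range(2, k + 1)}
    ranking.nf_table = pd.DataFrame({f"NF_{n}": nf for n, nf in nfs.items()})
    for n in range(2, k):
        ratios = np.log2(nfs[n].to_numpy() / nfs[n + 1].to_numpy())
        ranking.v_series[n] = float(np.std(ratios, ddof=1))
    return ranking


def optimal_gene_count(
    v_series: Mapping[int, float], cutoff: float = DEFAULT_V_CUTOFF
) -> tuple[int, bool]:
    """Smallest n with V(n/n+1) < cutoff; fallback (k, True) if none passes."""
    if not v_series:
        raise ValueError("empty V series")
    for n in sorted(v_series):
        if v_series[n] < cutoff:
            return n, False
    k = max(v_series) + 1
    logger.warning("no V(n/n+1) below %.3g; falling back to all %d genes", cutoff, k)
    return k, True


def m_cutoff_check(m: float, cutoff: float = DEFAULT_M_CUTOFF) -> bool:
    """True iff the M value is strictly below the usability cutoff (default 1.5)."""
    if m < 0:
        raise ValueError("M values are nonnegative")
    return m < cutoff


def genorm_analysis(
    expr: ExpressionMatrix | CtMatrix,
    *,
    v_cutoff: float = DEFAULT_V_CUTOFF,
) -> GeNormResult:
    """Run the full geNorm pipeline: ranking, NF table, V series, optimal count."""
    expr = _as_quantities(expr)
    result = stepwise_ranking(expr)
    nf_pairwise_variation(expr, result)
    result.optimal_n, result.no_n_satisfies_cutoff = optimal_gene_count(result.v_series, v_cutoff)
    return result
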