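"""NormFinder-style model-based stability estimation.

The model treats log2 expression of gene i in sample s of group g as

    y_igs = alpha_i + mu_gs + d_ig + eps_igs,   eps ~ N(0, sigma²_ig)

where mu_gs is a sample-specific loading effect shared by all genes, d_ig
is a systematic group-specific deviation of gene i (heat induction, say)
and sigma²_ig its within-group technical/biological noise. Subtracting
the per-sample mean over genes removes alpha and mu exactly, but the
centering leaks a 1/k share of every gene's noise and shift into every
other gene, so both variance and difference estimates must be corrected
for it:

* intra-group variances solve the moment relation
  E[v_ig] = (1 − 2/k)·sigma²_ig + (1/k²)·Σ_l sigma²_lg, where v_ig is the
  naive within-group variance of the centered values (estimates clamped
  at zero);
* inter-group differences d̂_ig (group mean of centered values, centered
  again across groups) are shrunk toward zero by an empirical-Bayes
  factor γ̂²/(γ̂² + sigmâ²_ig/n_g), so that pure-noise differences vanish.

The stability value combines both error sources on the scale of a
normalized log2 expression estimate:

    rho_i = (1/G) Σ_g ( |d̃_ig| + sqrt(sigmâ²_ig / n_g) )

Low rho means the gene neither shifts between groups nor fluctuates
within them. With a single group (or ungrouped data) rho_i reduces to
sqrt(sigmâ²_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import CtMatrix, ExpressionMatrix
from .preprocess import ct_to_relative_quantity

logger = logging.getLogger(__name__)


@dataclass
class StabilityRanking:
    """Ordered (gene, value, rank) stability table for one method/condition."""

    method: str
    entries: list[tuple[str, float, int]]
    condition: str | None = None

    @property
    def ordered_genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def top(self, n: int) -> list[str]:
        return self.ordered_genes[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene", "stability", "rank"])


@dataclass
class NormFinderResult:
    """Variance decomposition and combined stability per candidate gene."""

    intragroup_variance: pd.DataFrame  # genes × groups, sigma^2 (log2 units squared)
    intergroup_difference: pd.DataFrame  # genes × groups, shrunken d~ (log2 units)
    raw_difference: pd.DataFrame  # genes × groups, unshrunken d^
    stability: pd.Series  # rho per gene
    ranking: StabilityRanking
    group_sizes: pd.Series
    ungrouped: bool = False

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"gene": self.stability.index, "stability": self.stability.to_numpy()})
        for g in self.intragroup_variance.columns:
            frame[f"var_{g}"] = self.intragroup_variance[g].to_numpy()
            frame[f"d_{g}"] = self.intergroup_difference[g].to_numpy()
        ranks = {g: r for g, _, r in self.ranking.entries}
        frame["rank"] = [ranks[g] for g in frame["gene"]]
        return frame.sort_values("rank", kind="stable").reset_index(drop=True)


def _as_quantities(expr: ExpressionMatrix | CtMatrix) -> ExpressionMatrix:
    if isinstance(expr, CtMatrix):
        return ct_to_relative_quantity(expr)
    return expr


def log_and_center(expr: ExpressionMatrix | CtMatrix) -> pd.DataFrame:
    """log2-transform and subtract the per-sample mean over genes.

    Every column of the result sums to zero, which removes sample loading
    effects exactly. Requires >=3 genes — the downstream variance
    correction divides by (1 − 2/k).
    """
    expr = _as_quantities(expr)
    if len(expr.gene_ids) < 3:
        raise ValueError("NormFinder variance correction requires >=3 genes")
    arr = expr.values.to_numpy()
    if (arr <= 0).any() or np.isnan(arr).any():
        raise ValueError("NormFinder needs strictly positive, non-missing quantities")
    y = np.log2(arr)
    z = y - y.mean(axis=0, keepdims=True)
    return pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns)


def _group_table(z: pd.DataFrame, groups: pd.Series) -> dict[str, list[str]]:
    groups = pd.Series(groups).loc[list(z.columns)]
    table: dict[str, list[str]] = {}
    for sample, g in groups.items():
        table.setdefault(str(g), []).append(sample)
    return table


def estimate_intragroup_variance(z: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Bias-corrected within-group variance sigma^2 per gene per group.

    The naive variance v_ig of centered values is deflated by the
    centering; inverting E[v_ig] = (1−2/k)·sigma²_ig + (1/k²)·Σ_l sigma²_lg
    gives Σ̂_g = Σ_i v_ig / (1 − 1/k) and
    sigmâ²_ig = (v_ig − Σ̂_g/k²) / (1 − 2/k), clamped at zero.
    """
    k = z.shape[0]
    if k < 3:
        raise ValueError("NormFinder variance correction requires >=3 genes")
    out = {}
    for g, samples in _group_table(z, groups).items():
        if len(samples) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        v = z[samples].to_numpy().var(axis=1, ddof=1)
        total = v.sum() / (1.0 - 1.0 / k)
        out[g] = np.clip((v - total / k**2) / (1.0 - 2.0 / k), 0.0, None)
    return pd.DataFrame(out, index=z.index)


def estimate_intergroup_difference(
    z: pd.DataFrame, groups: pd.Series, sigma2: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Group-specific expression differences with empirical-Bayes shrinkage.

    Returns (d_tilde, d_hat, ungrouped). d̂_ig is the within-group mean of
    centered values minus the gene's across-group mean; it sums to zero
    over genes within each group and over groups within each gene. The
    shrinkage factor γ̂²/(γ̂² + sigmâ²_ig/n_g) with
    γ̂² = max(0, mean(d̂²) − mean(sigmâ²_ig/n_g)) sends pure-noise
    differences to zero while leaving well-supported shifts nearly intact.
    """
    table = _group_table(z, groups)
    if len(table) < 2:
        logger.info("single sample group: ungrouped mode, all d set to 0")
        zero = pd.DataFrame(0.0, index=z.index, columns=list(table))
        return zero, zero.copy(), True
    if sigma2 is None:
        sigma2 = estimate_intragroup_variance(z, groups)
    a = pd.DataFrame(
        {g: z[samples].to_numpy().mean(axis=1) for g, samples in table.items()}, index=z.index
    )
    d_hat = a.sub(a.mean(axis=1), axis=0)
    n_g = pd.Series({g: len(samples) for g, samples in table.items()})
    se2 = sigma2.div(n_g, axis=1)  # sampling variance of each d-hat entry
    gamma2 = max(0.0, float((d_hat.to_numpy() ** 2).mean()) - float(se2.to_numpy().mean()))
    if gamma2 == 0.0:
        d_tilde = d_hat * 0.0
    else:
        d_tilde = d_hat * (gamma2 / (gamma2 + se2))
    return d_tilde, d_hat, False


def stability_values(
    expr: ExpressionMatrix | CtMatrix, groups: pd.Series | None = None
) -> NormFinderResult:
    """Full NormFinder analysis: centering, variance decomposition, rho, ranks."""
    expr = _as_quantities(expr)
    if groups is None:
        groups = expr.groups
    if groups is None:
        groups = pd.Series("all", index=expr.values.columns)
    groups = pd.Series(groups).astype(str)
    z = log_and_center(expr)
    sigma2 = estimate_intragroup_variance(z, groups)
    d_tilde, d_hat, ungrouped = estimate_intergroup_difference(z, groups, sigma2)
    n_g = pd.Series({g: len(s) for g, s in _group_table(z, groups).items()})
    if ungrouped:
        rho = pd.Series(np.sqrt(sigma2.to_numpy()[:, 0]), index=z.index, name="stability")
    else:
        se = np.sqrt(sigma2.div(n_g, axis=1))
        rho = (d_tilde.abs() + se).mean(axis=1).rename("stability")
    ranking = rank_genes(rho, method="normfinder")
    return NormFinderResult(
        intragroup_variance=sigma2,
        intergroup_difference=d_tilde,
        raw_difference=d_hat,
        stability=rho,
        ranking=ranking,
        group_sizes=n_g,
        ungrouped=ungrouped,
    )


def rank_genes(
    stabilities: pd.Series | dict[str, float],
    method: str = "normfinder",
    condition: str | None = None,
) -> StabilityRanking:
    """Sort genes by ascending stability value; 1 = most stable.

    Ties share the lower rank and are ordered lexicographically by gene id.
    """
    items = sorted(pd.Series(stabilities).items(), key=lambda kv: (kv[1], kv[0]))
    if any(not np.isfinite(v) for _, v in items):
        raise ValueError("stability values must be finite")
    entries: list[tuple[str, float, int]] = []
    for i, (gene, value) in enumerate(items):
        rank = entries[-1][2] if entries and value == entries[-1][1] else i + 1
        entries.append((str(gene), float(value), rank))
    return StabilityRanking(method=method, entries=entries, condition=condition)
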