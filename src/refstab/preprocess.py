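"""Ct-to-quantity transforms and expression-intensity summaries.

A Ct difference of one cycle corresponds to one E-fold difference in
starting template, so linear relative quantities are E^(ΔCt). Quantities
are anchored per gene at the sample with the minimal Ct (quantity 1);
the anchor cancels in every ratio-based statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import CtMatrix, ExpressionMatrix


class MissingCtError(ValueError):
    """Missing Ct values must be resolved (e.g. drop_incomplete_samples) first."""


@dataclass(frozen=True)
class CtSummary:
    """Per-gene Ct location/spread statistics (box-plot style)."""

    gene_id: str
    mean_ct: float
    median_ct: float
    q25: float
    q75: float
    min_ct: float
    max_ct: float
    n_samples: int


def ct_to_relative_quantity(ct: CtMatrix) -> ExpressionMatrix:
    """Transform Ct values to linear relative quantities Q = E^(minCt − Ct).

    Per gene the sample with minimal Ct gets quantity exactly 1 and all
    quantities are strictly positive. Group labels are carried over.
    """
    if ct.values.isna().to_numpy().any():
        bad = list(ct.values.index[ct.values.isna().any(axis=1)])
        raise MissingCtError(
            f"missing Ct values in genes {bad}; apply a drop policy "
            "(e.g. CtMatrix.drop_incomplete_samples) before transforming"
        )
    e = ct.efficiencies.to_numpy()[:, None]
    c = ct.values.to_numpy()
    q = e ** (c.min(axis=1, keepdims=True) - c)
    values = pd.DataFrame(q, index=ct.values.index, columns=ct.values.columns)
    return ExpressionMatrix(values, ct.groups.copy())


def ct_summary(ct: CtMatrix) -> list[CtSummary]:
    """Per-gene mean/median/quartile/min/max of Ct across samples.

    Quartiles use linear interpolation between order statistics. Missing
    Ct values are ignored per gene; an all-missing gene is an error.
    """
    out: list[CtSummary] = []
    for gene, row in ct.values.iterrows():
        vals = row.dropna().to_numpy()
        if vals.size == 0:
            raise MissingCtError(f"gene {gene!r} has no non-missing Ct values")
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        out.append(
            CtSummary(
                gene_id=str(gene),
                mean_ct=float(vals.mean()),
                median_ct=float(med),
                q25=float(q25),
                q75=float(q75),
                min_ct=float(vals.min()),
                max_ct=float(vals.max()),
                n_samples=int(vals.size),
            )
        )
    return out


def fold_difference(mean_ct_a: float, mean_ct_b: float, efficiency: float = 2.0) -> float:
    """How many fold more abundant gene a is than gene b, from mean Cts.

    Returns efficiency**(mean_ct_b − mean_ct_a): lower Ct means higher
    abundance, and each cycle is one E-fold.
    """
    if efficiency <= 1.0:
        raise ValueError(f"amplification efficiency must be > 1, got {efficiency}")
    return float(efficiency ** (mean_ct_b - mean_ct_a))
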