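"""Synthetic qPCR Ct and expression data with known ground truth.

The Ct generator writes the measurement model the stability algorithms
assume, directly on the cycle (log2) scale where multiplicative
expression noise is additive:

    Ct(i, s) = base_i + shift_{i, group(s)} + load_s + eps_is

with eps_is ~ N(0, noise_sd_i²) per gene and load_s ~ N(0, loading_sd²)
drawn once per sample and shared by all genes — exactly the loading
effect that ratio-based stability measures must cancel. Planted
parameters are returned as ground truth so any ranking can be scored
without re-deriving them.

Scenario presets emulate a rice-endosperm heat-stress design: 13 genes
(three rRNA-scale around Ct 8–13, ten mRNA-scale around Ct 19–25), heat
vs control samples over short-term hour series or long-term
days-after-pollination (DAP) series, with heat shifts planted on the
classically unstable housekeeping genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import CtMatrix, ExpressionMatrix


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    base_ct: float
    noise_sd: float = 0.0  # cycles (= log2 units on the expression scale)
    group_shifts: Mapping[str, float] = field(default_factory=dict)  # cycles
    efficiency: float = 2.0


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic Ct dataset."""

    genes: list[GeneSpec]
    samples: list[tuple[str, str]]  # (sample_id, group)
    loading_sd: float = 0.0  # cycles, per-sample effect shared across genes
    seed: int = 0
    censor_above: float | None = None  # optional: Ct above this -> missing

    def validate(self) -> None:
        if not self.genes or not self.samples:
            raise ValueError("spec needs at least one gene and one sample")
        if self.loading_sd < 0:
            raise ValueError("loading_sd must be >= 0")
        sample_groups = {g for _, g in self.samples}
        for gs in self.genes:
            if gs.noise_sd < 0:
                raise ValueError(f"gene {gs.gene_id!r}: noise_sd must be >= 0")
            if not (1.0 < gs.efficiency <= 2.0):
                raise ValueError(f"gene {gs.gene_id!r}: efficiency must be in (1, 2]")
            unknown = set(gs.group_shifts) - sample_groups
            if unknown:
                raise ValueError(f"gene {gs.gene_id!r}: shifts for unknown groups {unknown}")


@dataclass
class GroundTruth:
    """Planted per-gene parameters and the stability order they imply."""

    noise_sd: pd.Series  # per gene, cycles
    shifts: pd.DataFrame  # genes × groups, cycles
    loading: pd.Series  # realized per-sample loading effect, cycles
    stability_order: list[str]  # most stable first
    composite: pd.Series  # the score the order sorts by

    @staticmethod
    def compose(noise_sd: pd.Series, shifts: pd.DataFrame) -> pd.Series:
        # declared composite: noise SD plus the mean absolute planted shift
        return noise_sd + shifts.abs().mean(axis=1)


def generate_ct_dataset(spec: SyntheticSpec) -> tuple[CtMatrix, GroundTruth]:
    """Draw a Ct matrix from the spec's measurement model, with ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gene_ids = [g.gene_id for g in spec.genes]
    sample_ids = [s for s, _ in spec.samples]
    groups = pd.Series({s: g for s, g in spec.samples})
    group_labels = sorted({g for _, g in spec.samples})

    loading = rng.normal(0.0, spec.loading_sd, size=len(sample_ids)) if spec.loading_sd > 0 else np.zeros(len(sample_ids))
    ct = np.empty((len(gene_ids), len(sample_ids)))
    for i, gs in enumerate(spec.genes):
        noise = rng.normal(0.0, gs.noise_sd, size=len(sample_ids)) if gs.noise_sd > 0 else np.zeros(len(sample_ids))
        shift = np.array([gs.group_shifts.get(g, 0.0) for _, g in spec.samples])
        ct[i] = gs.base_ct + shift + loading + noise
    values = pd.DataFrame(ct, index=gene_ids, columns=sample_ids)
    if spec.censor_above is not None:
        values = values.mask(values > spec.censor_above)
    eff = pd.Series({g.gene_id: g.efficiency for g in spec.genes})
    matrix = CtMatrix(values, groups, eff)

    noise_sd = pd.Series({g.gene_id: g.noise_sd for g in spec.genes})
    shifts = pd.DataFrame(
        {grp: [g.group_shifts.get(grp, 0.0) for g in spec.genes] for grp in group_labels},
        index=gene_ids,
    )
    composite = GroundTruth.compose(noise_sd, shifts)
    order = list(composite.sort_values(kind="stable").index)
    truth = GroundTruth(
        noise_sd=noise_sd,
        shifts=shifts,
        loading=pd.Series(loading, index=sample_ids),
        stability_order=order,
        composite=composite,
    )
    return matrix, truth


def generate_expression_dataset(
    n_genes: int,
    cv_targets: Sequence[float],
    n_samples: int,
    seed: int = 0,
    *,
    mean_range: tuple[float, float] = (10.0, 1000.0),
    means: Sequence[float] | None = None,
    gene_ids: Sequence[str] | None = None,
    gene_prefix: str = "g",
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Log-normal expression rows with planted coefficients of variation.

    For a log-normal distribution CV = sqrt(exp(sigma_log²) − 1), so
    sigma_log = sqrt(ln(1 + CV²)) plants the exact population CV. A target
    CV of 0 yields a constant gene. Means are spread log-uniformly over
    ``mean_range``.
    """
    if len(cv_targets) != n_genes:
        raise ValueError("need one CV target per gene")
    if any(cv < 0 for cv in cv_targets):
        raise ValueError("CV targets must be >= 0")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"{gene_prefix}{i:03d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("need one gene id per gene")
    sample_ids = [f"s{j:03d}" for j in range(n_samples)]
    if means is None:
        means = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_genes))
    else:
        means = np.asarray(means, dtype=float)
        if means.shape != (n_genes,):
            raise ValueError("need one mean per gene")
        if (means <= 0).any():
            raise ValueError("means must be positive")
    data = np.empty((n_genes, n_samples))
    for i, cv in enumerate(cv_targets):
        if cv == 0:
            data[i] = means[i]
            continue
        sigma = np.sqrt(np.log1p(cv**2))
        mu = np.log(means[i]) - sigma**2 / 2  # lognormal mean = exp(mu + sigma^2/2)
        data[i] = rng.lognormal(mu, sigma, size=n_samples)
    expr = ExpressionMatrix(pd.DataFrame(data, index=gene_ids, columns=sample_ids))
    cv_series = pd.Series(list(cv_targets), index=gene_ids, dtype=float)
    shifts = pd.DataFrame(index=gene_ids)
    truth = GroundTruth(
        noise_sd=cv_series,
        shifts=shifts,
        loading=pd.Series(0.0, index=sample_ids),
        stability_order=list(cv_series.sort_values(kind="stable").index),
        composite=cv_series,
    )
    return expr, truth


# 13-gene panel mirroring a rice endosperm study: 3 rRNA-scale genes, 2 novel
# candidates and 8 classic housekeeping genes. Noise SDs are assumptions of
# the stated scenario (stable genes ~0.1-0.3 cycles; notoriously condition-
# dependent genes 0.5-0.9), not measured values.
_PANEL: list[tuple[str, float, float, bool]] = [
    # (gene, base Ct, noise SD cycles, heat-responsive?)
    ("25S_rRNA", 7.8, 0.30, False),
    ("17S_rRNA", 8.4, 0.15, False),
    ("18S_rRNA", 13.2, 0.20, False),
    ("Fb15", 24.4, 0.10, False),
    ("UBQ5", 21.0, 0.12, False),
    ("eIF-4a", 20.5, 0.15, False),
    ("SKP-1b", 25.1, 0.25, False),
    ("UBC", 22.0, 0.30, False),
    ("Actin", 19.5, 0.35, False),
    ("eEF-1a", 19.0, 0.40, False),
    ("UBQ10", 22.5, 0.55, True),
    ("GAPDH", 21.5, 0.70, True),
    ("beta-TUB", 23.0, 0.90, True),
]

DEFAULT_HEAT_SHIFT = 1.5  # cycles, applied to heat-responsive genes in heat groups
DEFAULT_LOADING_SD = 0.5  # cycles, per-sample loading spread

SCENARIOS = ("short-term", "long-term", "development")


def study_scenario(
    name: str,
    *,
    seed: int = 0,
    heat_shift: float = DEFAULT_HEAT_SHIFT,
    loading_sd: float = DEFAULT_LOADING_SD,
) -> SyntheticSpec:
    """Preset specs for the three experimental conditions of the study design.

    ``short-term``: hour series 0/1/6/12 h, heat vs control (7 samples);
    ``long-term``: 7/9/12/14 DAP, heat vs control (8 samples);
    ``development``: control-only DAP series (single group, 4 samples).
    """
    if name == "short-term":
        samples = [("0N", "control"), ("1N", "control"), ("6N", "control"), ("12N", "control"),
                   ("1H", "heat"), ("6H", "heat"), ("12H", "heat")]
        heat_groups = ["heat"]
    elif name == "long-term":
        samples = [(f"{d}DAP-N", "control") for d in (7, 9, 12, 14)] + [
            (f"{d}DAP-H", "heat") for d in (7, 9, 12, 14)
        ]
        heat_groups = ["heat"]
    elif name == "development":
        samples = [(f"{d}DAP-N", "development") for d in (7, 9, 12, 14)]
        heat_groups = []
    else:
        raise ValueError(f"unknown scenario {name!r}; presets: {', '.join(SCENARIOS)}")
    genes = [
        GeneSpec(
            gene_id=g,
            base_ct=base,
            noise_sd=sd,
            group_shifts={grp: heat_shift for grp in heat_groups} if responsive else {},
        )
        for g, base, sd, responsive in _PANEL
    ]
    return SyntheticSpec(genes=genes, samples=samples, loading_sd=loading_sd, seed=seed)


def write_dataset(matrix: CtMatrix, truth: GroundTruth, outdir) -> None:
    """Emit ct.tsv, meta.tsv and truth.tsv for a generated dataset."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(outdir / "ct.tsv", sep="\t", index_label="gene_id", na_rep="NA")
    meta = pd.DataFrame({"sample_id": matrix.sample_ids, "group": matrix.groups.to_numpy()})
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    truth_frame = pd.DataFrame(
        {
            "gene_id": truth.noise_sd.index,
            "noise_sd": truth.noise_sd.to_numpy(),
            "composite": truth.composite.to_numpy(),
        }
    )
    for grp in truth.shifts.columns:
        truth_frame[f"shift_{grp}"] = truth.shifts[grp].to_numpy()
    truth_frame.to_csv(outdir / "truth.tsv", sep="\t", index=False)
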