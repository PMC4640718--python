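"""Candidate reference-gene screening across expression datasets.

The screen mirrors how stable genes are nominated from transcriptome
compendia before any qPCR is run: per dataset, keep genes whose
coefficient of variation (CV = SD/mean) is below a cutoff; intersect the
per-dataset survivors; then require an expression intensity comparable to
a familiar anchor gene (Actin by default) and at most a small number of
annotated isoforms, since alternative splicing defeats a single primer
pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_tables import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSummary:
    """Per-gene mean (MV), standard deviation (SD, n−1) and CV for one dataset."""

    gene_id: str
    mean_value: float
    sd: float
    cv: float
    n_isoforms: int | None = None


@dataclass
class CandidateSet:
    """A set of surviving gene ids plus the filters that produced it."""

    dataset_id: str
    gene_ids: frozenset[str]
    provenance: list[dict] = field(default_factory=list)

    def derive(self, gene_ids, step: dict) -> "CandidateSet":
        return CandidateSet(self.dataset_id, frozenset(gene_ids), self.provenance + [step])


@dataclass
class SelectionConfig:
    cv_cutoff: float = 0.2
    anchor_gene: str = "Actin"
    intensity_window_log2: float = 3.0
    max_isoforms: int = 2
    intensity_dataset: int = 0  # index of the dataset anchoring the intensity filter


def summarize_genes(expr: ExpressionMatrix) -> list[GeneSummary]:
    """Mean, SD (n−1) and CV per gene; zero-mean genes are excluded and logged."""
    out: list[GeneSummary] = []
    for gene, row in expr.values.iterrows():
        vals = row.to_numpy()
        if vals.size < 2:
            raise ValueError(f"gene {gene!r}: need >=2 samples for SD")
        mv = float(vals.mean())
        if mv <= 0:
            logger.warning("gene %r excluded: zero mean, CV undefined", gene)
            continue
        sd = float(vals.std(ddof=1))
        out.append(GeneSummary(str(gene), mv, sd, sd / mv))
    return out


def filter_by_cv(
    summaries: Sequence[GeneSummary], cutoff: float = 0.2, dataset_id: str = "dataset"
) -> CandidateSet:
    """Keep genes with CV strictly below the cutoff."""
    if cutoff <= 0:
        raise ValueError("CV cutoff must be positive")
    kept = frozenset(s.gene_id for s in summaries if s.cv < cutoff)
    return CandidateSet(dataset_id, kept, [{"filter": "cv", "cutoff": cutoff, "n_kept": len(kept)}])


def intersect_candidates(sets: Sequence[CandidateSet]) -> CandidateSet:
    """Genes present in every input set; provenance lists all parents."""
    if not sets:
        raise ValueError("need at least one candidate set")
    genes = frozenset.intersection(*(s.gene_ids for s in sets))
    if not genes:
        logger.warning("candidate intersection is empty")
    prov = [{"filter": "intersect", "parents": [s.dataset_id for s in sets], "n_kept": len(genes)}]
    return CandidateSet("+".join(s.dataset_id for s in sets), genes, prov)


def filter_by_intensity(
    summaries: Sequence[GeneSummary],
    anchor_gene: str,
    window: float = 3.0,
    dataset_id: str = "dataset",
) -> CandidateSet:
    """Keep genes within ±window log2-folds of the anchor gene's mean expression.

    The window is boundary-inclusive; the anchor itself always passes.
    """
    by_id = {s.gene_id: s for s in summaries}
    if anchor_gene not in by_id or by_id[anchor_gene].mean_value <= 0:
        raise ValueError(f"anchor gene {anchor_gene!r} absent or has nonpositive mean")
    anchor_mv = by_id[anchor_gene].mean_value
    kept = frozenset(
        s.gene_id
        for s in summaries
        if s.mean_value > 0 and abs(math.log2(s.mean_value / anchor_mv)) <= window
    )
    prov = [{"filter": "intensity", "anchor": anchor_gene, "window_log2": window, "n_kept": len(kept)}]
    return CandidateSet(dataset_id, kept, prov)


def filter_by_isoforms(
    candidates: CandidateSet,
    isoform_counts: Mapping[str, int],
    max_isoforms: int = 2,
) -> CandidateSet:
    """Drop genes with more than max_isoforms annotated isoforms.

    Genes with no isoform annotation are retained (absence of evidence)
    and logged.
    """
    kept, unknown = [], []
    for g in candidates.gene_ids:
        n = isoform_counts.get(g)
        if n is None:
            unknown.append(g)
            kept.append(g)
        elif n <= max_isoforms:
            kept.append(g)
    if unknown:
        logger.warning("isoform count unknown for %d gene(s); retained: %s", len(unknown), sorted(unknown))
    return candidates.derive(
        kept, {"filter": "isoforms", "max": max_isoforms, "n_unknown": len(unknown), "n_kept": len(kept)}
    )


def select_candidates(
    datasets: Sequence[ExpressionMatrix],
    config: SelectionConfig | None = None,
    *,
    isoform_counts: Mapping[str, int] | None = None,
    dataset_ids: Sequence[str] | None = None,
) -> CandidateSet:
    """Full screening pipeline: CV per dataset → intersect → intensity → isoforms.

    A gene absent from any dataset fails that dataset's CV filter, so it
    cannot survive the intersection (absence is not evidence of stability).
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    config = config or SelectionConfig()
    ids = list(dataset_ids) if dataset_ids else [f"dataset{i}" for i in range(len(datasets))]
    per_dataset_summaries = [summarize_genes(d) for d in datasets]
    cv_sets = [
        filter_by_cv(summ, config.cv_cutoff, dataset_id=did)
        for summ, did in zip(per_dataset_summaries, ids)
    ]
    selected = intersect_candidates(cv_sets)
    anchor_summaries = per_dataset_summaries[config.intensity_dataset]
    intensity = filter_by_intensity(
        anchor_summaries, config.anchor_gene, config.intensity_window_log2, ids[config.intensity_dataset]
    )
    selected = selected.derive(selected.gene_ids & intensity.gene_ids, intensity.provenance[0])
    if isoform_counts is not None:
        selected = filter_by_isoforms(selected, isoform_counts, config.max_isoforms)
    logger.info("candidate selection: %d gene(s) survive all filters", len(selected.gene_ids))
    return selected
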