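"""Combined geNorm/NormFinder recommendation reports and pipeline driver."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genorm import GeNormResult, genorm_analysis
from .io_tables import CtMatrix, read_ct_table, write_report
from .normfinder import NormFinderResult, StabilityRanking, rank_genes, stability_values
from .preprocess import ct_to_relative_quantity

logger = logging.getLogger(__name__)


@dataclass
class RecommendationReport:
    """Per-condition joint recommendation from both stability methods.

    The geNorm final pair is unordered, so when the optimal count is 2
    both of its members count as top-2 for the concordance computation.
    """

    condition: str
    genorm_ranking: StabilityRanking
    normfinder_ranking: StabilityRanking
    optimal_n: int
    recommended: dict[str, list[str]]  # method -> top optimal_n genes
    intersection: list[str]
    concordance: float  # |intersection| / optimal_n
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, ranking in (
            ("genorm", self.genorm_ranking),
            ("normfinder", self.normfinder_ranking),
        ):
            for gene, value, rank in ranking.entries:
                rows.append(
                    {
                        "condition": self.condition,
                        "method": method,
                        "gene": gene,
                        "stability": value,
                        "rank": rank,
                        "recommended": gene in self.recommended[method],
                    }
                )
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = [
            f"condition: {self.condition}",
            f"optimal number of reference genes: {self.optimal_n}",
            f"geNorm top-{self.optimal_n}: {', '.join(self.recommended['genorm'])}",
            f"NormFinder top-{self.optimal_n}: {', '.join(self.recommended['normfinder'])}",
            f"agreed genes: {', '.join(self.intersection) or '(none)'} "
            f"(concordance {len(self.intersection)}/{self.optimal_n})",
        ]
        for key, value in sorted(self.provenance.items()):
            lines.append(f"  {key} = {value}")
        return "\n".join(lines)


def genorm_to_ranking(result: GeNormResult, condition: str | None = None) -> StabilityRanking:
    """Express a geNorm result as a StabilityRanking (final pair = joint rank 1)."""
    order = result.ranking_order
    ranks = result.ranks()
    entries = [(g, float(result.m_at_removal[g]), ranks[g]) for g in order]
    return StabilityRanking(method="genorm", entries=entries, condition=condition)


def combine_rankings(
    genorm: GeNormResult,
    normfinder: NormFinderResult,
    optimal_n: int,
    *,
    condition: str = "all",
    provenance: dict | None = None,
) -> RecommendationReport:
    """Merge both methods' rankings into one recommendation.

    Both results must cover the same gene set; a mismatch is a hard error
    naming the odd genes.
    """
    g_genes = set(genorm.ranking_order)
    n_genes = set(normfinder.stability.index)
    if g_genes != n_genes:
        raise ValueError(
            f"gene sets differ between methods; only in one: {sorted(g_genes ^ n_genes)}"
        )
    g_rank = genorm_to_ranking(genorm, condition)
    # the final pair is unordered: at n=2 both members are "top" by construction
    g_top = list(genorm.final_pair) if optimal_n == 2 else g_rank.top(optimal_n)
    n_top = normfinder.ranking.top(optimal_n)
    inter = sorted(set(g_top) & set(n_top))
    report = RecommendationReport(
        condition=condition,
        genorm_ranking=g_rank,
        normfinder_ranking=normfinder.ranking,
        optimal_n=optimal_n,
        recommended={"genorm": g_top, "normfinder": n_top},
        intersection=inter,
        concordance=len(inter) / optimal_n if optimal_n else 0.0,
        provenance=provenance or {},
    )
    logger.info(
        "condition %s: %d/%d genes agreed between methods", condition, len(inter), optimal_n
    )
    return report


@dataclass
class PipelineConfig:
    """Flat configuration for the end-to-end analysis."""

    ct_path: str | None = None
    meta_path: str | None = None
    scenario: str | None = None  # generate inputs inline instead of reading files
    condition: str = "all"
    outdir: str | None = None
    cutoff_m: float = 1.5
    cutoff_v: float = 0.15
    efficiency_default: float = 2.0
    missing_token: str = "NA"
    drop_incomplete_samples: bool = False
    delimiter: str = "\t"
    seed: int = 0

    def validate(self) -> None:
        if self.scenario is None and (self.ct_path is None or self.meta_path is None):
            raise ValueError("config needs either a scenario or both ct_path and meta_path")


def run_pipeline(config: PipelineConfig) -> RecommendationReport:
    """Load (or simulate) Ct data, run geNorm + NormFinder, combine, write reports."""
    config.validate()
    if config.scenario is not None:
        from .simulate import generate_ct_dataset, study_scenario

        spec = study_scenario(config.scenario, seed=config.seed)
        ct, _truth = generate_ct_dataset(spec)
        condition = config.condition if config.condition != "all" else config.scenario
        logger.info("generated scenario %r with seed %d", config.scenario, config.seed)
    else:
        ct = read_ct_table(
            config.ct_path,
            config.meta_path,
            delimiter=config.delimiter,
            missing_token=config.missing_token,
        )
        condition = config.condition
    if config.drop_incomplete_samples:
        ct = ct.drop_incomplete_samples()

    expr = ct_to_relative_quantity(ct)
    genorm_res = genorm_analysis(expr, v_cutoff=config.cutoff_v)
    normfinder_res = stability_values(expr)
    worst_m = max(genorm_res.m_at_removal.values())
    provenance = {
        "cutoff_m": config.cutoff_m,
        "cutoff_v": config.cutoff_v,
        "seed": config.seed,
        "n_genes": len(ct.gene_ids),
        "n_samples": len(ct.sample_ids),
        "worst_M": round(worst_m, 6),
        "all_genes_below_m_cutoff": worst_m < config.cutoff_m,
        "tie_breaks": genorm_res.tie_breaks,
        "v_fallback": genorm_res.no_n_satisfies_cutoff,
    }
    report = combine_rankings(
        genorm_res,
        normfinder_res,
        genorm_res.optimal_n,
        condition=condition,
        provenance=provenance,
    )
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(genorm_res, outdir / "ranking.tsv")
        m_steps = pd.DataFrame(genorm_res.m_trajectory).rename_axis("step").reset_index()
        m_steps["step"] += 1
        write_report(m_steps, outdir / "m_values.tsv")
        v_frame = pd.DataFrame(
            {"n": list(genorm_res.v_series), "V": list(genorm_res.v_series.values())}
        )
        write_report(v_frame, outdir / "v_series.tsv")
        write_report(normfinder_res, outdir / "stability.tsv")
        write_report(report, outdir / "report.tsv")
        (outdir / "summary.txt").write_text(report.summary_text() + "\n")
    return report
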