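"""End-to-end driver: targets → design waterfall → in-silico PCR →
off-target evaluation → merged report plus audit files.

The whole reference is held in memory as plain strings for the scan stage;
this is the intended regime for panel-scale references and the synthetic
fixtures this package is tested on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import design as _design
from . import evaluate as _evaluate
from . import ispcr as _ispcr
from . import report as _report
from . import targets as _targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one place (mirrors the CLI flags)."""

    flank: int = _targets.DEFAULT_FLANK
    engine: _design.EngineParams = field(default_factory=_design.EngineParams)
    matcher: _ispcr.MatcherParams = field(default_factory=_ispcr.MatcherParams)
    min_score: int = _evaluate.DEFAULT_MIN_SCORE
    hq_threshold: float = _evaluate.DEFAULT_HQ_THRESHOLD
    decoy_patterns: tuple[str, ...] = _evaluate.DEFAULT_DECOY_PATTERNS
    tas_product_range: tuple[int, int] = (150, 200)
    tas_optimal_product: int = 190
    relaxed_max_product: int = 500
    target_distance_range: tuple[int, int] = (60, 100)

    def modes(self) -> dict:
        return _design.default_modes(
            self.tas_product_range, self.tas_optimal_product,
            self.relaxed_max_product, self.target_distance_range,
        )


@dataclass
class PipelineResult:
    sites: list
    outcomes: dict  # variant_ID -> DesignOutcome
    assessments: dict  # variant_ID -> SiteAssessment
    report_path: Optional[Path] = None
    products_fasta: Optional[Path] = None
    hits_bed: Optional[Path] = None
    details_path: Optional[Path] = None


def _load_genome(reference: _targets.Fasta) -> dict[str, str]:
    return {name: str(reference[name][:]).upper() for name in reference.keys()}


def run_pipeline(
    table_path: str | Path,
    reference_path: str | Path,
    outdir: Optional[str | Path] = None,
    config: Optional[PipelineConfig] = None,
    genome: Optional[Mapping[str, str]] = None,
) -> PipelineResult:
    """Run the full pipeline for one target table against one reference.

    When ``outdir`` is given, writes the tab-delimited report, the audit
    products FASTA and hits BED, and the off-target detail table there.
    ``genome`` may supply pre-loaded contig sequences (fixtures); otherwise
    contigs are read from the reference FASTA.
    """
    cfg = config or PipelineConfig()
    sites = _targets.parse_target_table(table_path)
    reference = _targets.open_reference(reference_path)
    genome = dict(genome) if genome is not None else _load_genome(reference)

    outcomes_list = _design.waterfall_design(
        sites, reference, modes=cfg.modes(), params=cfg.engine, flank=cfg.flank
    )
    outcomes = {o.site.variant_id: o for o in outcomes_list}
    logger.info("designed %d/%d sites",
                sum(o.primer3_ok for o in outcomes_list), len(sites))

    assessments: dict[str, _evaluate.SiteAssessment] = {}
    fasta_path = bed_path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta_path = outdir / "products.fa"
        bed_path = outdir / "hits.bed"
        for p in (fasta_path, bed_path):
            p.write_text("")

    for outcome in outcomes_list:
        if outcome.pair is None:
            continue
        pair = outcome.pair
        site = outcome.site
        hits = _ispcr.scan(pair, genome, cfg.matcher,
                           target_chrom=site.chrom, target_pos0=site.pos0)
        if fasta_path is not None:
            _ispcr.write_products_fasta(hits, pair, fasta_path)
            _ispcr.write_hits_bed(hits, pair, bed_path)
        kept = _evaluate.filter_low_score(
            _evaluate.filter_decoys(hits, cfg.decoy_patterns), cfg.min_score
        )
        predicted = genome[pair.chrom][pair.amplicon_start:pair.amplicon_end]
        assessments[site.variant_id] = _evaluate.assess_site(
            site, pair, kept, reference_gold=predicted,
            hq_threshold=cfg.hq_threshold,
        )

    result = PipelineResult(sites=sites, outcomes=outcomes,
                            assessments=assessments,
                            products_fasta=fasta_path, hits_bed=bed_path)
    if outdir is not None:
        result.report_path = _report.write_report(
            sites, outcomes, assessments, outdir / "report.tsv"
        )
        result.details_path = _report.write_offtarget_details(
            assessments, outdir / "offtarget_details.tsv"
        )
    return result
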