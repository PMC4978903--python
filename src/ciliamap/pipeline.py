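"""End-to-end orchestration: simulate -> screen -> annotate -> rank.

A run is fully determined by its serialized :class:`RunConfig` (one seed
drives every stage), and every stage's output is materialized so each step
can be inspected or re-run independently: the simulated inputs (VCF, GFF3,
FASTA, expression TSV, truth ledger), the candidate VCF, the consequence
and ranked TSVs, and a funnel report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import coexpr, consequence, io, screen, simulate
from .errors import ConfigError
from .io import VariantRecord

FUNNEL_STAGES = ("variants", "post_missing_filter", "post_screen",
                 "post_chromosome_restriction", "in_gene")


@dataclass
class RunConfig:
    """Serializable description of one reproducible pipeline run."""

    seed: int = 1
    outdir: str = "ciliamap_run"
    plan: simulate.CrossPlan = field(default_factory=simulate.CrossPlan)
    seq_model: simulate.SequencingModel = field(default_factory=simulate.SequencingModel)
    mapped_chromosome: str | None = "chr1"
    require_hom_ref_references: bool = False
    codon_table_id: int = consequence.CILIATE_TABLE_ID
    similarity_method: str = "pearson"
    reference_genes: tuple[str, ...] = simulate.MUCOCYST_REFERENCE_GENES
    expression_background: float = 1.0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "plan" in data:
            data["plan"] = simulate.CrossPlan(**data["plan"])
        if "seq_model" in data:
            data["seq_model"] = simulate.SequencingModel(**data["seq_model"])
        if "reference_genes" in data:
            data["reference_genes"] = tuple(data["reference_genes"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["reference_genes"] = list(self.reference_genes)
        return data

    def to_yaml(self, path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return Path(path)


@dataclass
class RunReport:
    """Funnel counts, ranked candidates, and the recovery verdict."""

    summary: screen.VariantSummary
    stage_counts: dict[str, int]
    ranked: list[coexpr.RankedCandidate]
    n_selected_assortants: int | None = None
    causal_survived: bool | None = None
    causal_rank: int | None = None


def validate_config(config: RunConfig) -> list[str]:
    """Collect every constraint violation (empty list means valid)."""
    errors: list[str] = []
    model = config.seq_model
    if model.mutant_sample in model.reference_samples:
        errors.append("mutant sample listed among reference samples")
    if model.mutant_sample not in model.coverage:
        errors.append(f"no coverage configured for mutant sample {model.mutant_sample!r}")
    if not model.reference_samples:
        errors.append("at least one reference sample is required")
    if not config.reference_genes:
        errors.append("references nonempty: the reference gene list must not be empty")
    if config.similarity_method not in coexpr.SIMILARITY_METHODS:
        errors.append(f"unknown similarity method {config.similarity_method!r}")
    if config.expression_background <= 0:
        errors.append("expression_background must be positive")
    plan = config.plan
    if plan.pool_size > plan.n_f2:
        errors.append("pool_size cannot exceed n_f2")
    if not (0 <= model.base_error < 0.5):
        errors.append("base_error must be in [0, 0.5)")
    if not (0 < model.hom_fraction <= 1):
        errors.append("hom_fraction must be in (0, 1]")
    try:
        consequence.codon_table(config.codon_table_id)
    except Exception:
        errors.append(f"unknown codon table id {config.codon_table_id}")
    return errors


@dataclass
class AnalysisResult:
    records: list[VariantRecord]
    passed_missing: list[VariantRecord]
    candidates: list[VariantRecord]
    mapped: list[VariantRecord]
    conseqs: list[consequence.ConsequenceRecord]
    in_gene: list[consequence.ConsequenceRecord]
    ranked: list[coexpr.RankedCandidate]
    summary: screen.VariantSummary


def analyze(records: Sequence[VariantRecord],
            screen_config: screen.ScreenConfig,
            models: Sequence[io.GeneModel],
            genome_sequences: dict[str, str],
            expression: dict[str, io.ExpressionProfile],
            references: Sequence[str],
            mappable_size: int,
            table_id: int = consequence.CILIATE_TABLE_ID,
            method: str = "pearson",
            background: float | None = None) -> AnalysisResult:
    """Screen, restrict, annotate, and rank one set of variant records."""
    records = list(records)
    summary = screen.summarize_variants(records, mappable_size)
    passed = screen.filter_missing(records)
    candidates = screen.screen_candidates(passed, screen_config)
    summary.per_chromosome_counts = screen.tally_by_chromosome(candidates, screen_config)
    mapped = screen.restrict_to_mapped(candidates, screen_config)
    table = consequence.codon_table(table_id)
    conseqs = consequence.annotate_variants(
        [r for r in mapped if r.is_snv], models, genome_sequences, table)
    in_gene = [c for c in conseqs
               if c.gene_model is not None and c.gene_model.annotated]
    ranked = coexpr.rank_candidates(in_gene, expression, references,
                                    method=method, background=background)
    return AnalysisResult(records, passed, candidates, mapped, conseqs, in_gene,
                          ranked, summary)


def _stage_counts(result: AnalysisResult) -> dict[str, int]:
    in_gene_sites = {(c.variant.chrom, c.variant.pos) for c in result.in_gene}
    return {
        "variants": len(result.records),
        "post_missing_filter": len(result.passed_missing),
        "post_screen": len(result.candidates),
        "post_chromosome_restriction": len(result.mapped),
        "in_gene": len(in_gene_sites),
    }


def _recovery(result: AnalysisResult, causal: simulate.Site) -> tuple[bool, int | None]:
    survived = any(r.chrom == causal.chrom and r.pos == causal.pos
                   and causal.alt in r.alt_alleles for r in result.candidates)
    rank = None
    for rc in result.ranked:
        v = rc.variant.variant
        if v.chrom == causal.chrom and v.pos == causal.pos and rc.variant.alt_allele == causal.alt:
            rank = rc.rank
            break
    return survived, rank


def run_simulation_analysis(config: RunConfig) -> tuple[simulate.SimulationResult,
                                                        AnalysisResult, RunReport]:
    """Simulate a cross under ``config`` and analyze it, without touching disk."""
    problems = validate_config(config)
    if problems:
        raise ConfigError("; ".join(problems))
    sim = simulate.simulate_cross(config.plan, config.seq_model, seed=config.seed)
    screen_config = screen.ScreenConfig(
        mutant_sample=config.seq_model.mutant_sample,
        reference_samples=config.seq_model.reference_samples,
        placed_chromosomes=sim.genome.placed_chromosomes,
        mapped_chromosome=config.mapped_chromosome,
        require_hom_ref_references=config.require_hom_ref_references,
    )
    result = analyze(sim.records, screen_config, sim.genome.gene_models,
                     sim.genome.sequences, sim.expression, config.reference_genes,
                     sim.genome.mappable_size, config.codon_table_id,
                     config.similarity_method, config.expression_background)
    survived, rank = _recovery(result, sim.genome.causal_site)
    report = RunReport(result.summary, _stage_counts(result), result.ranked,
                       sim.n_selected, survived, rank)
    return sim, result, report


def run_pipeline(config: RunConfig) -> RunReport:
    """Full run with every stage's output written under ``config.outdir``."""
    sim, result, report = run_simulation_analysis(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    io.write_genome(sim.genome.sequences, outdir / "genome.fasta")
    io.write_gene_models(sim.genome.gene_models, outdir / "genes.gff3")
    io.write_variants(sim.records, sim.samples, outdir / "variants.vcf")
    io.write_expression_table(sim.expression, outdir / "expression.tsv")
    simulate.write_truth(sim.truth, outdir / "truth.tsv")
    io.write_variants(result.candidates, sim.samples, outdir / "candidates.vcf")
    consequence.write_consequences(result.conseqs, outdir / "consequences.tsv")
    coexpr.write_ranked(result.ranked, outdir / "ranked.tsv")
    write_report(report, outdir / "report.tsv")
    (outdir / "report.txt").write_text(format_report(report))
    return report


def write_report(report: RunReport, path) -> Path:
    """Machine-readable key/value report (TSV) that round-trips its numbers."""
    lines = ["key\tvalue"]
    s = report.summary
    lines.append(f"n_variants\t{s.n_variants}")
    lines.append(f"n_snv\t{s.n_snv}")
    lines.append(f"snv_density_per_kbp\t{s.snv_density_per_kbp:.6f}")
    if s.per_chromosome_counts:
        for chrom, n in s.per_chromosome_counts.items():
            lines.append(f"candidates_{chrom}\t{n}")
    for stage in FUNNEL_STAGES:
        lines.append(f"stage_{stage}\t{report.stage_counts[stage]}")
    if report.n_selected_assortants is not None:
        lines.append(f"n_selected_assortants\t{report.n_selected_assortants}")
    if report.causal_survived is not None:
        lines.append(f"causal_survived\t{int(report.causal_survived)}")
    lines.append(f"causal_rank\t{report.causal_rank if report.causal_rank else '.'}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_report(path) -> dict[str, float | int | None]:
    """Parse a report TSV back into numeric fields."""
    out: dict[str, float | int | None] = {}
    lines = Path(path).read_text().strip().splitlines()[1:]
    for line in lines:
        key, value = line.split("\t")
        if value == ".":
            out[key] = None
        elif "." in value:
            out[key] = float(value)
        else:
            out[key] = int(value)
    return out


def format_report(report: RunReport) -> str:
    """Human-readable funnel summary."""
    s = report.summary
    lines = [
        "ciliamap run report",
        "===================",
        f"variant records:            {s.n_variants}",
        f"SNVs:                       {s.n_snv}",
        f"SNV density (per kbp):      {s.snv_density_per_kbp:.4f}",
        f"after missing-call filter:  {report.stage_counts['post_missing_filter']}",
        f"candidate sites:            {report.stage_counts['post_screen']}",
    ]
    if s.per_chromosome_counts:
        tally = ", ".join(f"{c}: {n}" for c, n in s.per_chromosome_counts.items())
        lines.append(f"candidates per chromosome:  {tally}")
    lines.append(f"on mapped chromosome:       {report.stage_counts['post_chromosome_restriction']}")
    lines.append(f"within annotated genes:     {report.stage_counts['in_gene']}")
    if report.ranked:
        top = report.ranked[0]
        sim_txt = f"{top.similarity:.4f}" if top.similarity is not None else "n/a"
        lines.append(f"top-ranked candidate:       {top.gene_id} "
                     f"(similarity {sim_txt}, effect {top.variant.effect.value})")
    if report.causal_survived is not None:
        verdict = ("causal site rank "
                   f"{report.causal_rank}" if report.causal_rank else
                   ("causal site survived screening but was not ranked"
                    if report.causal_survived else "causal site lost in screening"))
        lines.append(f"recovery verdict:           {verdict}")
    return "\n".join(lines) + "\n"
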