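"""Candidate screening of multi-sample variant records.

The screen implements the two-step bulk-segregant filter: drop every record
in which any sample's genotype is uncertain (MISSING), then keep the sites
at which every sample is homozygous and the mutant pool's homozygous allele
differs from that of every reference strain. Summaries reproduce the
per-chromosome candidate tally and the genome-wide SNV density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, ContractError
from .io import GenotypeState, VariantRecord

UNDEFINED_CHROMOSOME = "undefined"


@dataclass
class ScreenConfig:
    """Sample roles and chromosome context for the candidate screen."""

    mutant_sample: str
    reference_samples: tuple[str, ...]
    placed_chromosomes: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4", "chr5")
    mapped_chromosome: str | None = None
    #: Stricter reading of the filter: references must be homozygous
    #: *reference*, not merely homozygous and different from the mutant.
    require_hom_ref_references: bool = False

    def __post_init__(self) -> None:
        self.reference_samples = tuple(self.reference_samples)
        if not self.reference_samples:
            raise ConfigError("reference_samples must be nonempty")
        if self.mutant_sample in self.reference_samples:
            raise ConfigError(
                f"mutant sample {self.mutant_sample!r} also listed among references")

    @property
    def samples(self) -> tuple[str, ...]:
        return (self.mutant_sample, *self.reference_samples)


@dataclass
class VariantSummary:
    """Counts and density summarizing a variant set."""

    n_variants: int
    n_snv: int
    snv_density_per_kbp: float
    per_chromosome_counts: dict[str, int] | None = None


def filter_missing(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep exactly the records in which no sample's call is MISSING."""
    return [r for r in records
            if not any(c.is_missing for c in r.calls.values())]


def screen_candidates(records: Sequence[VariantRecord],
                      config: ScreenConfig) -> list[VariantRecord]:
    """Apply the homozygosity + difference filter; order preserved.

    A record survives iff every configured sample is homozygous and the
    mutant sample's homozygous allele differs from each reference sample's
    homozygous allele (allele *sequence* identity, so HOM_ALT calls with
    different alt indices but the same base do not count as different).
    Records with MISSING calls must have been removed first.
    """
    out: list[VariantRecord] = []
    for r in records:
        for s in config.samples:
            if s not in r.calls:
                raise ContractError(f"record {r.chrom}:{r.pos} lacks sample {s!r}")
            if r.calls[s].is_missing:
                raise ContractError(
                    f"record {r.chrom}:{r.pos} has a MISSING call for {s!r}; "
                    "apply filter_missing first")
        if not all(r.calls[s].is_homozygous for s in config.samples):
            continue
        mut_allele = r.called_allele(config.mutant_sample)
        ok = True
        for s in config.reference_samples:
            if config.require_hom_ref_references and \
                    r.calls[s].state is not GenotypeState.HOM_REF:
                ok = False
                break
            if r.called_allele(s) == mut_allele:
                ok = False
                break
        if ok:
            out.append(r)
    return out


def tally_by_chromosome(candidates: Sequence[VariantRecord],
                        config: ScreenConfig) -> dict[str, int]:
    """Candidate counts per placed chromosome, unplaced under "undefined"."""
    counts = {c: 0 for c in config.placed_chromosomes}
    counts[UNDEFINED_CHROMOSOME] = 0
    for r in candidates:
        key = r.chrom if r.chrom in counts else UNDEFINED_CHROMOSOME
        counts[key] += 1
    return counts


def restrict_to_mapped(candidates: Sequence[VariantRecord],
                       config: ScreenConfig) -> list[VariantRecord]:
    """Candidates on the chromosome identified by prior physical mapping."""
    if config.mapped_chromosome is None:
        raise ConfigError("mapped_chromosome is not set")
    return [r for r in candidates if r.chrom == config.mapped_chromosome]


def snv_density(n_snv: int, mappable_size: int) -> float:
    """SNVs per kbp of mappable genome."""
    if mappable_size <= 0:
        raise ContractError("mappable_size must be positive")
    return n_snv * 1000.0 / mappable_size


def summarize_variants(records: Sequence[VariantRecord],
                       mappable_size: int) -> VariantSummary:
    """Total and SNV counts plus SNV density per kbp."""
    n_variants = len(records)
    n_snv = sum(1 for r in records if r.is_snv)
    return VariantSummary(n_variants, n_snv, snv_density(n_snv, mappable_size))
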