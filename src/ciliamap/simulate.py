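"""Synthetic forward-genetic cross with macronuclear assortment and pooled sequencing.

The generator emulates the study design of a nitrosoguanidine mutagenesis
screen in a ciliate with a diploid germline micronucleus (MIC) and a
polyploid (~45-copy) somatic macronucleus (MAC):

1. heavy mutagenesis plants a Poisson number of background SNVs plus one
   causal stop-loss, all heterozygous in the mutagenized parent's MIC;
2. an outcross to a wild-type strain yields F1 clones; two F1s heterozygous
   for the causal allele are mated, so the recessive phenotype segregates
   1:3 among the F2;
3. each F2's MAC develops from its MIC and then drifts by amitotic division
   (phenotypic assortment, modelled as replicate-then-hypergeometric-split);
4. clones with zero wild-type copies at the causal site are selected, 25 of
   them pooled and "sequenced" (Poisson depth, uniform base-flip errors)
   alongside the parental and outcross reference strains; and
5. a simple caller turns read counts into multi-sample variant records.

Every stage draws from an independently spawned stream of one seed, so the
whole simulation is reproducible and each stage can be replayed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError, SimulationError
from .io import (CONDITION_LABELS, ExpressionProfile, GeneModel, GenotypeCall,
                 VariantRecord)

DEFAULT_PLOIDY = 45

_BASES = np.array(list("ACGT"))
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
#: Sense codons under the ciliate nuclear code (TGA is the sole stop).
_SENSE_CODONS = [c for c in _ALL_CODONS if c != "TGA"]


@dataclass(frozen=True)
class Site:
    """A biallelic SNV site: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class CrossPlan:
    """Study design of the cross: mutation load, progeny counts, pooling."""

    mutation_rate: float = 200.0   # expected background SNVs per mutagenized genome
    n_f1: int = 24                 # F1 clones drawn from the outcross
    n_f2: int = 200                # F2 progeny drawn from the F1 x F1 mating
    n_divisions: int = 50          # vegetative divisions before assortant screening
    pool_size: int = 25            # clones pooled for sequencing
    ploidy: int = DEFAULT_PLOIDY   # MAC copies per site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutation_rate < 0:
            raise ContractError("mutation_rate must be >= 0")
        for name in ("n_f1", "n_f2", "pool_size", "ploidy"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be positive")
        if self.n_divisions < 0:
            raise ContractError("n_divisions must be >= 0")


def _default_coverage() -> dict[str, float]:
    return {"mutant_pool": 70.0, "parental": 256.0, "outcross_1": 65.0, "outcross_2": 73.0}


@dataclass
class SequencingModel:
    """Pooled-sequencing and genotype-calling parameters.

    ``coverage`` maps sample name to mean depth. ``hom_fraction`` is the
    minimum major-allele read fraction for a homozygous call; below
    ``min_depth`` a call is MISSING.
    """

    coverage: dict[str, float] = field(default_factory=_default_coverage)
    base_error: float = 0.002
    min_depth: int = 10
    hom_fraction: float = 0.95
    mutant_sample: str = "mutant_pool"

    def __post_init__(self) -> None:
        if not (0 <= self.base_error < 0.5):
            raise ContractError("base_error must be in [0, 0.5)")
        if not (0 < self.hom_fraction <= 1):
            raise ContractError("hom_fraction must be in (0, 1]")
        if self.mutant_sample not in self.coverage:
            raise ContractError(f"no coverage given for mutant sample {self.mutant_sample!r}")

    @property
    def reference_samples(self) -> tuple[str, ...]:
        return tuple(s for s in self.coverage if s != self.mutant_sample)


@dataclass
class GenomeSpec:
    """Synthetic genome: chromosome sequences, gene models, the planted causal site."""

    chrom_lengths: dict[str, int]
    placed_chromosomes: tuple[str, ...]
    sequences: dict[str, str]
    gene_models: list[GeneModel]
    causal_site: Site
    causal_gene_id: str
    mappable_size: int

    def __post_init__(self) -> None:
        total = sum(self.chrom_lengths.values())
        if self.mappable_size > total:
            raise ContractError("mappable_size exceeds total genome size")


@dataclass(frozen=True)
class MicronuclearGenotype:
    """Diploid germline genotype over a fixed, ordered site set.

    ``alleles`` has shape (n_sites, 2) with entries 0 (wild type) or 1
    (mutant/alt).
    """

    sites: tuple[Site, ...]
    alleles: np.ndarray

    @classmethod
    def wildtype(cls, sites: Sequence[Site]) -> "MicronuclearGenotype":
        return cls(tuple(sites), np.zeros((len(sites), 2), dtype=np.int8))

    def site_index(self, site: Site) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise ContractError(f"site {site} not in genotype site set") from None

    def dosage(self) -> np.ndarray:
        """Mutant-allele count per site (0, 1, or 2)."""
        return self.alleles.sum(axis=1)


@dataclass(frozen=True)
class MacronuclearState:
    """Per-site mutant-allele copy counts out of ``ploidy`` MAC copies."""

    sites: tuple[Site, ...]
    alt_copies: np.ndarray
    ploidy: int = DEFAULT_PLOIDY
    clone_id: int | None = None

    def __post_init__(self) -> None:
        if ((self.alt_copies < 0) | (self.alt_copies > self.ploidy)).any():
            raise ContractError("allele copy counts must lie in [0, ploidy]")

    def site_index(self, site: Site) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise ContractError(f"site {site} not in state site set") from None


@dataclass(frozen=True)
class ReadCounts:
    """Per-site, per-sample read counts from pooled sequencing.

    Arrays are shaped (n_samples, n_sites); ``other_counts`` are error reads
    matching neither the ref nor the alt base.
    """

    sites: tuple[Site, ...]
    samples: tuple[str, ...]
    depth: np.ndarray
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    other_counts: np.ndarray


@dataclass(frozen=True)
class TruthLedger:
    """Ground truth of one simulated cross, sufficient to score recovery."""

    sites: tuple[Site, ...]
    causal: Site
    background: tuple[Site, ...]
    clone_ids: tuple[int, ...]
    clone_dosage: np.ndarray  # (n_clones, n_sites) MIC mutant-allele counts


@dataclass
class SimulationResult:
    genome: GenomeSpec
    plan: CrossPlan
    seq_model: SequencingModel
    records: list[VariantRecord]
    truth: TruthLedger
    expression: dict[str, ExpressionProfile]
    samples: tuple[str, ...]
    n_selected: int


# ---------------------------------------------------------------------------
# Genome construction


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    # AT-rich composition, as in the Tetrahymena macronuclear genome
    return list(rng.choice(_BASES, size=length, p=[0.375, 0.125, 0.125, 0.375]))


def _orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + TGA; no internal in-frame stop."""
    if n_codons < 2:
        raise ContractError("an ORF needs at least start and stop codons")
    body = rng.integers(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TGA"


def _write_seq(seq: list[str], start: int, text: str) -> None:
    """Overwrite ``seq`` (1-based start) with ``text``."""
    seq[start - 1:start - 1 + len(text)] = list(text)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def default_genome(rng: np.random.Generator | None = None,
                   chrom_length: int = 30_000,
                   scaffold_length: int = 4_000,
                   extension_codons: int = 179) -> GenomeSpec:
    """Build the default synthetic genome.

    Five placed chromosomes plus two unplaced scaffolds; a causal gene on
    chromosome 1 whose terminal TGA is followed in frame by
    ``extension_codons`` sense codons and then the next TGA (so the planted
    stop-loss extends the product by ``extension_codons + 1`` residues);
    decoy genes on every chromosome, including minus-strand and two-exon
    models and one unannotated model.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    placed = ("chr1", "chr2", "chr3", "chr4", "chr5")
    scaffolds = ("scaffold_1", "scaffold_2")
    lengths = {c: chrom_length for c in placed}
    lengths.update({c: scaffold_length for c in scaffolds})
    seqs = {name: _random_sequence(rng, n) for name, n in lengths.items()}

    models: list[GeneModel] = []

    def plant_single(gene_id: str, chrom: str, strand: str, start: int,
                     n_codons: int, annotated: bool = True) -> GeneModel:
        orf = _orf(rng, n_codons)
        text = orf if strand == "+" else _revcomp(orf)
        _write_seq(seqs[chrom], start, text)
        model = GeneModel(gene_id, chrom, strand,
                          ((start, start + len(orf) - 1),), annotated)
        models.append(model)
        return model

    # Causal gene: plus strand, single exon, terminal codon TGA on chr1.
    causal = plant_single("gene_chr1_a", "chr1", "+", 5_001, 120)
    cds_end = causal.cds_segments[-1][1]
    # In-frame read-through region: sense codons, then the next TGA.
    tail = "".join(_SENSE_CODONS[i]
                   for i in rng.integers(len(_SENSE_CODONS), size=extension_codons)) + "TGA"
    _write_seq(seqs["chr1"], cds_end + 1, tail)
    causal_site = Site("chr1", cds_end, "A", "T")  # TGA -> TGT (Cys)

    plant_single("gene_chr1_b", "chr1", "+", 12_001, 100)
    plant_single("gene_chr1_c", "chr1", "-", 18_001, 90)
    plant_single("gene_chr1_d", "chr1", "+", 24_001, 80, annotated=False)
    plant_single("gene_chr2_a", "chr2", "+", 6_001, 110)
    plant_single("gene_chr2_b", "chr2", "-", 15_001, 70)

    # Two-exon plus-strand gene on chr3 with a mid-codon intron boundary.
    orf = _orf(rng, 100)
    exon1_len, intron_len = 151, 80
    s1 = 8_001
    e1 = s1 + exon1_len - 1
    s2 = e1 + intron_len + 1
    e2 = s2 + (len(orf) - exon1_len) - 1
    _write_seq(seqs["chr3"], s1, orf[:exon1_len])
    _write_seq(seqs["chr3"], s2, orf[exon1_len:])
    models.append(GeneModel("gene_chr3_a", "chr3", "+", ((s1, e1), (s2, e2))))

    plant_single("gene_chr4_a", "chr4", "+", 10_001, 60)
    plant_single("gene_chr5_a", "chr5", "-", 9_001, 120)

    sequences = {name: "".join(seq) for name, seq in seqs.items()}
    return GenomeSpec(
        chrom_lengths=lengths,
        placed_chromosomes=placed,
        sequences=sequences,
        gene_models=models,
        causal_site=causal_site,
        causal_gene_id=causal.gene_id,
        mappable_size=sum(lengths[c] for c in placed),
    )


# ---------------------------------------------------------------------------
# Mutagenesis and crosses


def simulate_mutagenesis(genome: GenomeSpec, plan: CrossPlan,
                         rng: np.random.Generator,
                         ) -> tuple[MicronuclearGenotype, tuple[Site, ...]]:
    """Mutagenize the parent: Poisson background SNVs, all heterozygous.

    The causal site is always planted (heterozygous). Background positions
    are uniform over the genome; a draw colliding with the causal site or a
    previous draw is resampled deterministically from the stream.
    """
    k = int(rng.poisson(plan.mutation_rate))
    chrom_names = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chrom_names], dtype=np.int64)
    cum = np.cumsum(lengths)
    total = int(cum[-1])
    taken = {(genome.causal_site.chrom, genome.causal_site.pos)}
    background: list[Site] = []
    while len(background) < k:
        off = int(rng.integers(total))
        ci = int(np.searchsorted(cum, off, side="right"))
        pos = off - (int(cum[ci]) - int(lengths[ci])) + 1
        chrom = chrom_names[ci]
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        ref = genome.sequences[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        background.append(Site(chrom, pos, ref, alt))
    order = {c: i for i, c in enumerate(chrom_names)}
    sites = sorted([genome.causal_site, *background], key=lambda s: (order[s.chrom], s.pos))
    alleles = np.tile(np.array([0, 1], dtype=np.int8), (len(sites), 1))
    return MicronuclearGenotype(tuple(sites), alleles), tuple(background)


def cross(parent_a: MicronuclearGenotype, parent_b: MicronuclearGenotype,
          n: int, rng: np.random.Generator) -> list[MicronuclearGenotype]:
    """Mendelian cross: each progeny draws one allele per site from each parent.

    Sites segregate independently (no linkage map).
    """
    if parent_a.sites != parent_b.sites:
        raise ContractError("parents are defined over different site sets")
    n_sites = len(parent_a.sites)
    idx = np.arange(n_sites)
    pick_a = rng.integers(2, size=(n, n_sites))
    pick_b = rng.integers(2, size=(n, n_sites))
    gam_a = parent_a.alleles[idx[None, :], pick_a]
    gam_b = parent_b.alleles[idx[None, :], pick_b]
    progeny = np.stack([gam_a, gam_b], axis=2).astype(np.int8)
    return [MicronuclearGenotype(parent_a.sites, progeny[i]) for i in range(n)]


# ---------------------------------------------------------------------------
# Macronuclear development and assortment


def develop_macronucleus(mic: MicronuclearGenotype, ploidy: int = DEFAULT_PLOIDY,
                         clone_id: int | None = None) -> MacronuclearState:
    """New MAC from a MIC genotype.

    Homozygous sites develop at ploidy:0; heterozygous sites start with the
    mutant allele holding the ceil(ploidy/2) share (fixed tie-break).
    """
    if ploidy < 2:
        raise ContractError("ploidy must be >= 2")
    dosage = mic.dosage()
    alt = np.zeros(len(mic.sites), dtype=np.int64)
    alt[dosage == 2] = ploidy
    alt[dosage == 1] = -(-ploidy // 2)  # ceil
    return MacronuclearState(mic.sites, alt, ploidy, clone_id)


def _assort_matrix(alt: np.ndarray, ploidy: int, divisions: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Amitotic divisions on an array of copy counts (any shape).

    Each division replicates every site to 2*ploidy copies and deals the
    tracked daughter ploidy copies without replacement (hypergeometric
    partition). 0 and ploidy are absorbing.
    """
    alt = np.asarray(alt, dtype=np.int64).copy()
    for _ in range(divisions):
        alt = rng.hypergeometric(2 * alt, 2 * (ploidy - alt), ploidy)
    return alt


def assort(state: MacronuclearState, divisions: int,
           rng: np.random.Generator) -> MacronuclearState:
    """Phenotypic assortment of one MAC over ``divisions`` amitotic divisions."""
    if divisions < 0:
        raise ContractError("divisions must be >= 0")
    alt = _assort_matrix(state.alt_copies, state.ploidy, divisions, rng)
    return replace(state, alt_copies=alt)


def assort_population(states: Sequence[MacronuclearState], divisions: int,
                      rng: np.random.Generator) -> list[MacronuclearState]:
    """Assort many clones at once (one hypergeometric draw per division)."""
    if not states:
        return []
    ploidy = states[0].ploidy
    mat = np.stack([s.alt_copies for s in states])
    mat = _assort_matrix(mat, ploidy, divisions, rng)
    return [replace(s, alt_copies=mat[i]) for i, s in enumerate(states)]


def select_assortants(clones: Sequence[MacronuclearState],
                      causal_site: Site) -> list[MacronuclearState]:
    """Clones with zero wild-type copies at the causal site, order preserved."""
    out = []
    for clone in clones:
        i = clone.site_index(causal_site)
        if clone.ploidy - int(clone.alt_copies[i]) == 0:
            out.append(clone)
    return out


# ---------------------------------------------------------------------------
# Sequencing and calling


def pool_and_sequence(clones: Sequence[MacronuclearState],
                      refs: Mapping[str, MacronuclearState],
                      model: SequencingModel,
                      rng: np.random.Generator) -> ReadCounts:
    """Sequence the equimolar clone pool and each reference strain.

    Depth is Poisson(coverage) per site; each read draws its true allele
    from the sample's pooled copy fraction and flips to a uniformly random
    other base with probability ``base_error``.
    """
    if not clones:
        raise ContractError("clone pool is empty")
    sites = clones[0].sites
    pool_frac = np.mean([c.alt_copies / c.ploidy for c in clones], axis=0)
    samples = (model.mutant_sample, *refs)
    fracs = [pool_frac] + [refs[s].alt_copies / refs[s].ploidy for s in refs]
    n_sites = len(sites)
    e = model.base_error
    pvals = np.array([1 - e, e / 3, 2 * e / 3])
    depth = np.empty((len(samples), n_sites), dtype=np.int64)
    ref_c = np.empty_like(depth)
    alt_c = np.empty_like(depth)
    oth_c = np.empty_like(depth)
    for i, (sample, frac) in enumerate(zip(samples, fracs)):
        d = rng.poisson(model.coverage[sample], size=n_sites)
        alt_true = rng.binomial(d, frac)
        ref_true = d - alt_true
        # error channel: stay / flip to the other declared allele / flip elsewhere
        r_split = rng.multinomial(ref_true, pvals)
        a_split = rng.multinomial(alt_true, pvals)
        depth[i] = d
        ref_c[i] = r_split[:, 0] + a_split[:, 1]
        alt_c[i] = a_split[:, 0] + r_split[:, 1]
        oth_c[i] = r_split[:, 2] + a_split[:, 2]
    return ReadCounts(sites, samples, depth, ref_c, alt_c, oth_c)


def call_genotypes(counts: ReadCounts, model: SequencingModel) -> list[VariantRecord]:
    """Per-sample genotype calls from read counts.

    MISSING below ``min_depth``; homozygous when the major declared allele
    holds at least ``hom_fraction`` of all reads; HET otherwise. Sites with
    no non-reference call in any sample are not emitted.
    """
    records: list[VariantRecord] = []
    for j, site in enumerate(counts.sites):
        calls: dict[str, GenotypeCall] = {}
        emit = False
        for i, sample in enumerate(counts.samples):
            d = int(counts.depth[i, j])
            r = int(counts.ref_counts[i, j])
            a = int(counts.alt_counts[i, j])
            ad = (r, a)
            if d < model.min_depth:
                calls[sample] = GenotypeCall.missing(d, ad)
                continue
            if a / d >= model.hom_fraction:
                calls[sample] = GenotypeCall.hom_alt(1, d, ad)
                emit = True
            elif r / d >= model.hom_fraction:
                calls[sample] = GenotypeCall.hom_ref(d, ad)
            else:
                calls[sample] = GenotypeCall.het(1, d, ad)
                emit = True
        if emit:
            records.append(VariantRecord(site.chrom, site.pos, site.ref, (site.alt,), calls))
    return records


# ---------------------------------------------------------------------------
# Truth ledger


def make_truth(genome: GenomeSpec, background: Sequence[Site],
               sites: Sequence[Site],
               pooled_clones: Sequence[tuple[int, MicronuclearGenotype]]) -> TruthLedger:
    """Assemble the ground-truth ledger for recovery scoring."""
    clone_ids = tuple(cid for cid, _ in pooled_clones)
    dosage = np.stack([g.dosage() for _, g in pooled_clones]) if pooled_clones else \
        np.zeros((0, len(sites)), dtype=np.int8)
    return TruthLedger(tuple(sites), genome.causal_site, tuple(background),
                       clone_ids, dosage.astype(np.int8))


def write_truth(truth: TruthLedger, path) -> Path:
    roles = {truth.causal: "causal"}
    rows = []
    for j, site in enumerate(truth.sites):
        row = {"chrom": site.chrom, "pos": site.pos, "ref": site.ref, "alt": site.alt,
               "role": roles.get(site, "background")}
        for i, cid in enumerate(truth.clone_ids):
            row[f"clone_{cid}"] = int(truth.clone_dosage[i, j])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_truth(path) -> TruthLedger:
    df = pd.read_csv(path, sep="\t")
    sites = tuple(Site(r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples())
    causal_rows = df.index[df["role"] == "causal"]
    if len(causal_rows) != 1:
        raise FormatError("truth ledger must contain exactly one causal site")
    causal = sites[causal_rows[0]]
    background = tuple(s for s, role in zip(sites, df["role"]) if role == "background")
    clone_cols = [c for c in df.columns if c.startswith("clone_")]
    clone_ids = tuple(int(c.split("_", 1)[1]) for c in clone_cols)
    dosage = df[clone_cols].to_numpy(dtype=np.int8).T
    return TruthLedger(sites, causal, background, clone_ids, dosage)


# ---------------------------------------------------------------------------
# Expression fixtures

#: Shape of the shared mucocyst-pathway expression profile: low in growth,
#: strongly induced in starvation, re-induced mid-conjugation.
MUCOCYST_ARCHETYPE = np.array([
    0.04, 0.06, 0.05,
    0.30, 0.85, 1.00, 0.90, 0.70, 0.55, 0.35,
    0.10, 0.25, 0.55, 0.80, 1.00, 0.90, 0.60, 0.40, 0.25, 0.15,
])

#: Decoy shape: high in growing cultures, declining elsewhere.
GROWTH_ARCHETYPE = np.array([
    1.00, 0.95, 0.90,
    0.45, 0.30, 0.22, 0.18, 0.15, 0.12, 0.10,
    0.50, 0.40, 0.35, 0.30, 0.28, 0.25, 0.22, 0.20, 0.18, 0.15,
])

MUCOCYST_REFERENCE_GENES = ("SOR4", "GRL1", "GRL3")


def default_expression_table(genome: GenomeSpec, rng: np.random.Generator,
                             reference_genes: Sequence[str] = MUCOCYST_REFERENCE_GENES,
                             causal_scale: float = 1.6,
                             noise_sd: float = 0.08) -> dict[str, ExpressionProfile]:
    """Expression profiles for all genome genes plus the reference pathway genes.

    The causal gene follows the mucocyst archetype at very low absolute
    abundance (its maximum sits below twice a unit background, mirroring a
    barely expressed pathway member); decoy genes follow the growth
    archetype; reference genes follow the mucocyst archetype at high
    abundance. Noise is per-condition multiplicative lognormal.
    """

    def noisy(archetype: np.ndarray, scale: float) -> tuple[float, ...]:
        values = archetype * scale * np.exp(rng.normal(0.0, noise_sd, size=archetype.size))
        return tuple(float(v) for v in values)

    table: dict[str, ExpressionProfile] = {}
    for gid in reference_genes:
        table[gid] = ExpressionProfile(gid, noisy(MUCOCYST_ARCHETYPE, float(rng.uniform(40, 120))))
    for model in genome.gene_models:
        if model.gene_id == genome.causal_gene_id:
            table[model.gene_id] = ExpressionProfile(
                model.gene_id, noisy(MUCOCYST_ARCHETYPE, causal_scale))
        else:
            table[model.gene_id] = ExpressionProfile(
                model.gene_id, noisy(GROWTH_ARCHETYPE, float(rng.uniform(20, 60))))
    return table


# ---------------------------------------------------------------------------
# End-to-end simulation


def simulate_cross(plan: CrossPlan | None = None,
                   seq_model: SequencingModel | None = None,
                   genome: GenomeSpec | None = None,
                   seed: int | None = None) -> SimulationResult:
    """Run the full synthetic cross and return called variant records + truth.

    All randomness derives from one seed (``seed`` argument, else
    ``plan.seed``) via spawned, stage-specific streams.
    """
    plan = plan if plan is not None else CrossPlan()
    seq_model = seq_model if seq_model is not None else SequencingModel()
    base_seed = plan.seed if seed is None else seed
    streams = np.random.SeedSequence(base_seed).spawn(7)
    (r_genome, r_mut, r_f1, r_f2, r_assort, r_seq, r_expr) = \
        (np.random.default_rng(s) for s in streams)

    if genome is None:
        genome = default_genome(r_genome)

    mut_parent, background = simulate_mutagenesis(genome, plan, r_mut)
    wildtype = MicronuclearGenotype.wildtype(mut_parent.sites)
    f1 = cross(mut_parent, wildtype, plan.n_f1, r_f1)
    causal_idx = mut_parent.site_index(genome.causal_site)
    het_f1 = [g for g in f1 if int(g.alleles[causal_idx].sum()) == 1]
    if len(het_f1) < 2:
        raise SimulationError(
            "fewer than two F1 clones heterozygous at the causal site; increase n_f1")
    f2 = cross(het_f1[0], het_f1[1], plan.n_f2, r_f2)

    macs = [develop_macronucleus(g, plan.ploidy, clone_id=i) for i, g in enumerate(f2)]
    macs = assort_population(macs, plan.n_divisions, r_assort)
    selected = select_assortants(macs, genome.causal_site)
    if len(selected) < plan.pool_size:
        raise SimulationError(
            f"only {len(selected)} fully mutant assortant clones for a pool of "
            f"{plan.pool_size}; increase n_f2 or n_divisions")
    pool = selected[:plan.pool_size]

    zeros = np.zeros(len(mut_parent.sites), dtype=np.int64)
    refs = {name: MacronuclearState(mut_parent.sites, zeros, plan.ploidy)
            for name in seq_model.reference_samples}
    counts = pool_and_sequence(pool, refs, seq_model, r_seq)
    records = call_genotypes(counts, seq_model)

    pooled = [(c.clone_id, f2[c.clone_id]) for c in pool]
    truth = make_truth(genome, background, mut_parent.sites, pooled)
    expression = default_expression_table(genome, r_expr)
    return SimulationResult(genome, plan, seq_model, records, truth, expression,
                            counts.samples, len(selected))
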