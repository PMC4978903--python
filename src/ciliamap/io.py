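"""Interchange formats and the shared domain types.

Variant records follow multi-sample VCF conventions (1-based positions,
``GT:DP:AD`` sample fields), gene models follow GFF3 (1-based inclusive
intervals, CDS features attached to ``gene`` features), genomes are plain
FASTA, and expression tables are TSV with one row per gene and the 20
standard culture-condition columns (three growing, seven starvation, ten
conjugation time points). Positions are kept 1-based in the domain types;
internal arithmetic converts to 0-based half-open slices at the point of
use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ContractError, DataError, FormatError, ModelError

#: Condition labels of the 20-point expression profile, in fixed order:
#: growing cultures at low/medium/high density, starvation time points (h),
#: and conjugation time points (h).
CONDITION_LABELS: tuple[str, ...] = (
    "L-l", "L-m", "L-h",
    "S-0", "S-3", "S-6", "S-9", "S-12", "S-15", "S-24",
    "C-0", "C-2", "C-4", "C-6", "C-8", "C-10", "C-12", "C-14", "C-16", "C-18",
)

_BASES = frozenset("ACGT")


class GenotypeState(Enum):
    HOM_REF = "hom_ref"
    HOM_ALT = "hom_alt"
    HET = "het"
    MISSING = "missing"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site.

    ``alt_index`` is the 1-based index into the record's alt alleles; it is
    meaningful only for HOM_ALT and HET states. ``allele_depths`` are
    per-allele read counts in (ref, alt1, ...) order; reads assigned to
    neither declared allele (e.g. sequencing errors to a third base) count
    toward ``depth`` only, hence sum(allele_depths) <= depth.
    """

    state: GenotypeState
    alt_index: int = 1
    depth: int = 0
    allele_depths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.depth < 0 or any(d < 0 for d in self.allele_depths):
            raise DataError("read depths must be nonnegative")
        if self.allele_depths and sum(self.allele_depths) > self.depth:
            raise DataError("allele depths exceed total depth")
        if self.state in (GenotypeState.HOM_ALT, GenotypeState.HET) and self.alt_index < 1:
            raise DataError("alt_index must be >= 1 for alt-bearing calls")

    @property
    def is_homozygous(self) -> bool:
        return self.state in (GenotypeState.HOM_REF, GenotypeState.HOM_ALT)

    @property
    def is_missing(self) -> bool:
        return self.state is GenotypeState.MISSING

    @classmethod
    def missing(cls, depth: int = 0, allele_depths: Sequence[int] = ()) -> "GenotypeCall":
        return cls(GenotypeState.MISSING, depth=depth, allele_depths=tuple(allele_depths))

    @classmethod
    def hom_ref(cls, depth: int = 0, allele_depths: Sequence[int] = ()) -> "GenotypeCall":
        return cls(GenotypeState.HOM_REF, depth=depth, allele_depths=tuple(allele_depths))

    @classmethod
    def hom_alt(cls, alt_index: int = 1, depth: int = 0,
                allele_depths: Sequence[int] = ()) -> "GenotypeCall":
        return cls(GenotypeState.HOM_ALT, alt_index=alt_index, depth=depth,
                   allele_depths=tuple(allele_depths))

    @classmethod
    def het(cls, alt_index: int = 1, depth: int = 0,
            allele_depths: Sequence[int] = ()) -> "GenotypeCall":
        return cls(GenotypeState.HET, alt_index=alt_index, depth=depth,
                   allele_depths=tuple(allele_depths))


@dataclass(frozen=True)
class VariantRecord:
    """One variant site with per-sample genotype calls."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    calls: Mapping[str, GenotypeCall]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, *self.alt_alleles):
            if not allele or set(allele) - _BASES:
                raise DataError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        """True iff the ref and every alt allele have length 1."""
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)

    def called_allele(self, sample: str) -> str | None:
        """Allele sequence asserted by a homozygous call, or None otherwise."""
        call = self.calls[sample]
        if call.state is GenotypeState.HOM_REF:
            return self.ref_allele
        if call.state is GenotypeState.HOM_ALT:
            return self.alt_alleles[call.alt_index - 1]
        return None


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene model carrying CDS intervals only.

    ``cds_segments`` are 1-based inclusive intervals, ordered in
    transcription order: ascending genomic coordinates on '+', descending on
    '-'. The concatenated CDS length must be a multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    annotated: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.cds_segments:
            raise ModelError(f"gene {self.gene_id}: no CDS segments")
        for s, e in self.cds_segments:
            if not (1 <= s <= e):
                raise ModelError(f"gene {self.gene_id}: bad CDS interval ({s}, {e})")
        starts = [s for s, _ in self.cds_segments]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ModelError(f"gene {self.gene_id}: CDS segments not in transcription order")
        spans = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ModelError(f"gene {self.gene_id}: overlapping CDS segments")
        if self.cds_length % 3 != 0:
            raise ModelError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (min start, max end) over all CDS segments."""
        return (min(s for s, _ in self.cds_segments), max(e for _, e in self.cds_segments))

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS, else None."""
        off = 0
        for s, e in self.cds_segments:
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        return None

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced, strand-corrected (5'->3') CDS sequence."""
        seq = genome[self.chrom]
        parts = []
        for s, e in self.cds_segments:
            part = seq[s - 1:e]
            if self.strand == "-":
                part = str(Seq(part).reverse_complement())
            parts.append(part)
        return "".join(parts)


@dataclass(frozen=True)
class ExpressionProfile:
    """Transcript abundance of one gene over the 20 standard conditions."""

    gene_id: str
    values: tuple[float, ...]
    conditions: tuple[str, ...] = CONDITION_LABELS

    def __post_init__(self) -> None:
        if len(self.values) != len(self.conditions):
            raise DataError(
                f"gene {self.gene_id}: expected {len(self.conditions)} values, "
                f"got {len(self.values)}")
        for v in self.values:
            if not math.isfinite(v) or v < 0:
                raise DataError(f"gene {self.gene_id}: abundance values must be finite and >= 0")


# ---------------------------------------------------------------------------
# Variant files


def _parse_call(sample_rec, n_alts: int) -> GenotypeCall:
    gt = sample_rec.get("GT")
    dp = sample_rec.get("DP")
    ad = sample_rec.get("AD")
    if ad is not None:
        ad = tuple(int(x) for x in ad if x is not None)
    else:
        ad = ()
    depth = int(dp) if dp is not None else 0
    depth = max(depth, sum(ad))
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return GenotypeCall.missing(depth, ad)
    alleles = {int(a) for a in gt}
    if alleles == {0}:
        return GenotypeCall.hom_ref(depth, ad)
    if len(alleles) == 1:
        (k,) = alleles
        if k > n_alts:  # unparseable: allele index beyond declared alts
            return GenotypeCall.missing(depth, ad)
        return GenotypeCall.hom_alt(k, depth, ad)
    k = max(alleles)
    if k > n_alts:
        return GenotypeCall.missing(depth, ad)
    return GenotypeCall.het(k, depth, ad)


def read_variants(path, samples: Sequence[str]) -> list[VariantRecord]:
    """Read a multi-sample VCF-style file into VariantRecords, in file order.

    Every expected sample must be present in the header; genotype fields that
    cannot be interpreted map to MISSING calls.
    """
    samples = tuple(samples)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse variant file {path}: {exc}") from None
    records: list[VariantRecord] = []
    with vf:
        present = set(vf.header.samples)
        for s in samples:
            if s not in present:
                raise FormatError(f"sample column {s!r} missing from {path}")
        for rec in vf:
            if rec.alts is None:
                continue  # confident-reference line, not a variant
            calls = {s: _parse_call(rec.samples[s], len(rec.alts)) for s in samples}
            records.append(VariantRecord(
                rec.contig, rec.pos, rec.ref.upper(),
                tuple(a.upper() for a in rec.alts), calls))
    return records


def _encode_gt(call: GenotypeCall) -> tuple:
    if call.state is GenotypeState.MISSING:
        return (None, None)
    if call.state is GenotypeState.HOM_REF:
        return (0, 0)
    if call.state is GenotypeState.HOM_ALT:
        return (call.alt_index, call.alt_index)
    return (0, call.alt_index)


def write_variants(records: Iterable[VariantRecord], samples: Sequence[str], path) -> Path:
    """Write VariantRecords as an uncompressed multi-sample VCF-style file."""
    samples = tuple(samples)
    records = list(records)
    header = pysam.VariantHeader()
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Per-allele read depth")
    contigs: dict[str, None] = {}
    for r in records:
        for s in samples:
            if s not in r.calls:
                raise ContractError(
                    f"record {r.chrom}:{r.pos} lacks a call for sample {s!r}")
        if r.chrom not in contigs:
            contigs[r.chrom] = None
            header.contigs.add(r.chrom)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(contig=r.chrom, start=r.pos - 1,
                                 alleles=(r.ref_allele,) + r.alt_alleles)
            n_alleles = 1 + len(r.alt_alleles)
            for s in samples:
                call = r.calls[s]
                fmt = rec.samples[s]
                fmt["GT"] = _encode_gt(call)
                fmt["DP"] = call.depth
                if call.allele_depths:
                    ad = list(call.allele_depths)[:n_alleles]
                    ad += [0] * (n_alleles - len(ad))
                    fmt["AD"] = ad
            out.write(rec)
    return Path(path)


# ---------------------------------------------------------------------------
# Gene models (GFF3)


def read_gene_models(path, chrom_lengths: Mapping[str, int] | None = None) -> list[GeneModel]:
    """Read GFF3 gene models (gene + CDS features) into GeneModel objects.

    If ``chrom_lengths`` is given, CDS intervals are validated against it.
    """
    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except Exception as exc:  # gffutils raises assorted types on malformed input
        raise FormatError(f"cannot parse GFF3 file {path}: {exc}") from None
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        segs = [(c.start, c.end) for c in db.children(gene, featuretype="CDS", order_by="start")]
        if not segs:
            continue
        if gene.strand == "-":
            segs = segs[::-1]
        annotated = gene.attributes.get("annotated", ["true"])[0].lower() != "false"
        model = GeneModel(gene.id, gene.seqid, gene.strand, tuple(segs), annotated)
        if chrom_lengths is not None:
            if model.chrom not in chrom_lengths:
                raise ModelError(f"gene {model.gene_id}: unknown chromosome {model.chrom}")
            if model.span[1] > chrom_lengths[model.chrom]:
                raise ModelError(
                    f"gene {model.gene_id}: CDS extends past the end of {model.chrom}")
        models.append(model)
    return models


def write_gene_models(models: Iterable[GeneModel], path) -> Path:
    """Write GeneModels as a minimal GFF3 file (gene + CDS features)."""
    lines = ["##gff-version 3"]
    for m in models:
        lo, hi = m.span
        flag = "true" if m.annotated else "false"
        lines.append("\t".join([
            m.chrom, "ciliamap", "gene", str(lo), str(hi), ".", m.strand, ".",
            f"ID={m.gene_id};annotated={flag}"]))
        off = 0
        for s, e in m.cds_segments:
            phase = (3 - off % 3) % 3
            lines.append("\t".join([
                m.chrom, "ciliamap", "CDS", str(s), str(e), ".", m.strand,
                str(phase), f"ID=cds-{m.gene_id};Parent={m.gene_id}"]))
            off += e - s + 1
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# Genome (FASTA)


def read_genome(path) -> dict[str, str]:
    """Read a FASTA genome into a dict of uppercase sequences."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise FormatError(f"no sequences found in {path}")
    return genome


def write_genome(sequences: Mapping[str, str], path) -> Path:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")
    return Path(path)


# ---------------------------------------------------------------------------
# Expression tables (TSV)


def read_expression_table(path) -> dict[str, ExpressionProfile]:
    """Read a genes x conditions TSV into ExpressionProfiles.

    The header must consist of ``gene_id`` plus the 20 condition labels in
    their canonical order.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse expression table {path}: {exc}") from None
    if "gene_id" not in df.columns:
        raise FormatError(f"expression table {path} lacks a gene_id column")
    cols = tuple(c for c in df.columns if c != "gene_id")
    if cols != CONDITION_LABELS:
        raise FormatError(
            f"expression table {path} must have exactly the 20 condition columns "
            f"{CONDITION_LABELS} in order; got {cols}")
    profiles: dict[str, ExpressionProfile] = {}
    for _, row in df.iterrows():
        values = tuple(float(row[c]) for c in CONDITION_LABELS)
        if any(not math.isfinite(v) for v in values):
            raise FormatError(
                f"expression row for {row['gene_id']} has missing or non-finite values")
        profiles[row["gene_id"]] = ExpressionProfile(row["gene_id"], values)
    return profiles


def write_expression_table(profiles: Mapping[str, ExpressionProfile], path) -> Path:
    rows = [{"gene_id": gid, **dict(zip(p.conditions, p.values))}
            for gid, p in profiles.items()]
    df = pd.DataFrame(rows, columns=["gene_id", *CONDITION_LABELS])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
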