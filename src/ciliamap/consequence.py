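"""Variant consequence annotation under the ciliate nuclear genetic code.

Ciliates of the Tetrahymena lineage translate TAA and TAG as glutamine;
TGA is the sole stop codon (NCBI translation table 6). Classification under
the standard code would therefore mislabel most stop-related effects in
this organism — the table is a first-class parameter, defaulting to 6.

A stop-loss at a gene's terminal codon is further annotated with the
read-through extension: the number of residues appended to the wild-type
product, counting the new residue at the former stop plus every in-frame
sense codon up to (and excluding) the next downstream stop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

from .errors import ContractError, DataError, ModelError, ReferenceMismatchError
from .io import GeneModel, VariantRecord

CILIATE_TABLE_ID = 6
STANDARD_TABLE_ID = 1

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class Effect(Enum):
    INTERGENIC = "intergenic"
    INTRONIC = "intronic"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"


@dataclass(frozen=True)
class CodonTable:
    """Codon -> one-letter residue map ('*' for stop) for one genetic code."""

    table_id: int
    forward: Mapping[str, str]
    stop_codons: tuple[str, ...]

    def translate(self, codon: str) -> str:
        try:
            return self.forward[codon.upper()]
        except KeyError:
            raise DataError(f"not a codon: {codon!r}") from None

    def translate_cds(self, cds: str) -> str:
        if len(cds) % 3 != 0:
            raise DataError("CDS length not divisible by 3")
        return "".join(self.translate(cds[i:i + 3]) for i in range(0, len(cds), 3))


def codon_table(table_id: int = CILIATE_TABLE_ID) -> CodonTable:
    """Build a CodonTable from the named NCBI genetic code."""
    try:
        t = _BioCodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        raise DataError(f"unknown genetic code id {table_id}") from None
    forward = dict(t.forward_table)
    for c in t.stop_codons:
        forward[c] = "*"
    return CodonTable(table_id, forward, tuple(t.stop_codons))


@dataclass(frozen=True)
class ConsequenceRecord:
    """Predicted effect of one alt allele of one variant."""

    variant: VariantRecord
    alt_allele: str
    gene_id: str | None
    effect: Effect
    codon_change: tuple[str, str] | None = None
    residue_change: tuple[str, str] | None = None
    extension_aa: int | None = None
    no_downstream_stop: bool = False
    gene_model: GeneModel | None = None
    table_id: int = CILIATE_TABLE_ID


def extension_length(conseq: ConsequenceRecord, genome: Mapping[str, str],
                     table: CodonTable | None = None) -> int | None:
    """Residues appended by a stop-loss, or None if no downstream stop exists.

    Counts the read-through residue at the former stop, then scans in-frame
    3' codons on the gene's strand until the next stop; running off the
    chromosome end yields None rather than an exception.
    """
    if conseq.effect is not Effect.STOP_LOSS:
        raise ContractError("extension_length requires a stop_loss consequence")
    if conseq.gene_model is None:
        raise ContractError("consequence record carries no gene model")
    table = table if table is not None else codon_table(conseq.table_id)
    model = conseq.gene_model
    seq = genome[model.chrom]
    count = 1  # the new residue read through the former stop
    j = 0
    while True:
        if model.strand == "+":
            end = model.cds_segments[-1][1]  # 1-based end of terminal codon
            lo = end + 3 * j
            codon = seq[lo:lo + 3]
        else:
            start = model.cds_segments[-1][0]
            lo = start - 4 - 3 * j
            if lo < 0:
                return None
            codon = "".join(_COMPLEMENT[b] for b in reversed(seq[lo:lo + 3]))
        if len(codon) < 3:
            return None
        if codon in table.stop_codons:
            return count
        count += 1
        j += 1


def annotate_variant(variant: VariantRecord, models: Sequence[GeneModel],
                     genome: Mapping[str, str],
                     table: CodonTable | None = None) -> list[ConsequenceRecord]:
    """Annotate an SNV against gene models: one ConsequenceRecord per alt allele.

    Coding changes are located strand-aware within the spliced CDS and
    translated under the given code; a position inside a gene's span but
    outside its CDS is intronic.
    """
    table = table if table is not None else codon_table(CILIATE_TABLE_ID)
    if not variant.is_snv:
        raise ContractError(
            f"annotation requires length-1 alleles at {variant.chrom}:{variant.pos}")
    seq = genome.get(variant.chrom)
    if seq is None or variant.pos > len(seq):
        raise DataError(f"genome does not cover {variant.chrom}:{variant.pos}")
    genome_base = seq[variant.pos - 1].upper()
    if genome_base != variant.ref_allele:
        raise ReferenceMismatchError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: genome has "
            f"{genome_base}, record has {variant.ref_allele}")

    coding_model: GeneModel | None = None
    containing_model: GeneModel | None = None
    for m in models:
        if m.chrom != variant.chrom or not m.contains(variant.pos):
            continue
        if containing_model is None:
            containing_model = m
        if m.cds_offset(variant.pos) is not None:
            coding_model = m
            break

    out: list[ConsequenceRecord] = []
    for alt in variant.alt_alleles:
        if coding_model is None:
            if containing_model is None:
                out.append(ConsequenceRecord(variant, alt, None, Effect.INTERGENIC,
                                             table_id=table.table_id))
            else:
                out.append(ConsequenceRecord(variant, alt, containing_model.gene_id,
                                             Effect.INTRONIC, gene_model=containing_model,
                                             table_id=table.table_id))
            continue
        m = coding_model
        off = m.cds_offset(variant.pos)
        cds = m.cds_sequence(genome)
        codon_idx, within = divmod(off, 3)
        ref_codon = cds[3 * codon_idx:3 * codon_idx + 3]
        sub = alt if m.strand == "+" else _COMPLEMENT[alt]
        alt_codon = ref_codon[:within] + sub + ref_codon[within + 1:]
        ref_res = table.translate(ref_codon)
        alt_res = table.translate(alt_codon)
        terminal = codon_idx == len(cds) // 3 - 1
        if ref_res == "*" and alt_res != "*":
            if not terminal:
                raise ModelError(
                    f"gene {m.gene_id}: internal stop codon at CDS codon {codon_idx + 1}")
            effect = Effect.STOP_LOSS
        elif alt_res == "*" and ref_res != "*":
            effect = Effect.STOP_GAIN
        elif ref_res == alt_res:
            effect = Effect.SYNONYMOUS
        else:
            effect = Effect.MISSENSE
        rec = ConsequenceRecord(variant, alt, m.gene_id, effect,
                                (ref_codon, alt_codon), (ref_res, alt_res),
                                gene_model=m, table_id=table.table_id)
        if effect is Effect.STOP_LOSS:
            ext = extension_length(rec, genome, table)
            rec = replace(rec, extension_aa=ext, no_downstream_stop=ext is None)
        out.append(rec)
    return out


def annotate_variants(records: Iterable[VariantRecord], models: Sequence[GeneModel],
                      genome: Mapping[str, str],
                      table: CodonTable | None = None) -> list[ConsequenceRecord]:
    """Annotate many records (SNVs only); flat list over records x alt alleles."""
    table = table if table is not None else codon_table(CILIATE_TABLE_ID)
    out: list[ConsequenceRecord] = []
    for r in records:
        out.extend(annotate_variant(r, models, genome, table))
    return out


def write_consequences(conseqs: Sequence[ConsequenceRecord], path) -> Path:
    rows = []
    for c in conseqs:
        rows.append({
            "chrom": c.variant.chrom,
            "pos": c.variant.pos,
            "ref": c.variant.ref_allele,
            "alt": c.alt_allele,
            "gene_id": c.gene_id if c.gene_id is not None else ".",
            "effect": c.effect.value,
            "codon_change": "/".join(c.codon_change) if c.codon_change else ".",
            "residue_change": "/".join(c.residue_change) if c.residue_change else ".",
            "extension_aa": c.extension_aa if c.extension_aa is not None else ".",
            "no_downstream_stop": str(c.no_downstream_stop).lower(),
        })
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene_id", "effect",
                                "codon_change", "residue_change", "extension_aa",
                                "no_downstream_stop"]).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_consequences(path) -> list[ConsequenceRecord]:
    """Read a consequence TSV back into (variant-call-free) ConsequenceRecords."""
    df = pd.read_csv(path, sep="\t", dtype={"extension_aa": str})
    out: list[ConsequenceRecord] = []
    for r in df.itertuples():
        variant = VariantRecord(r.chrom, int(r.pos), r.ref, (r.alt,), {})
        gene_id = None if r.gene_id == "." else r.gene_id
        codon = tuple(r.codon_change.split("/")) if r.codon_change != "." else None
        residue = tuple(r.residue_change.split("/")) if r.residue_change != "." else None
        ext = None if str(r.extension_aa) in (".", "nan") else int(float(r.extension_aa))
        out.append(ConsequenceRecord(variant, r.alt, gene_id, Effect(r.effect),
                                     codon, residue, ext,
                                     str(r.no_downstream_stop).lower() == "true"))
    return out
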