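"""Worked-example variant fixtures, generated in memory.

``candidate_screen_records`` builds the canonical screening example: 28
planted candidate sites distributed 10/7/4/1/4 over the five placed
chromosomes plus 2 on unplaced scaffolds, interleaved with decoy records
that violate each screening clause (an uncertain genotype, a heterozygous
mutant pool, and a mutant homozygote shared with a reference strain).
"""

from __future__ import annotations

from .io import GenotypeCall, VariantRecord

SAMPLES = ("mutant_pool", "parental", "outcross_1", "outcross_2")

_DEPTHS = {"mutant_pool": 70, "parental": 256, "outcross_1": 65, "outcross_2": 73}

#: Planted candidates per chromosome: the per-chromosome tally of the screen.
CANDIDATE_DISTRIBUTION = {
    "chr1": 10, "chr2": 7, "chr3": 4, "chr4": 1, "chr5": 4,
    "scaffold_12": 1, "scaffold_31": 1,
}


def _call(kind: str, depth: int, alt_frac: float = 0.0) -> GenotypeCall:
    alt = round(depth * alt_frac)
    ad = (depth - alt, alt)
    if kind == "hom_ref":
        return GenotypeCall.hom_ref(depth, ad)
    if kind == "hom_alt":
        return GenotypeCall.hom_alt(1, depth, ad)
    if kind == "het":
        return GenotypeCall.het(1, depth, ad)
    return GenotypeCall.missing(depth, ad)


def _candidate(chrom: str, pos: int) -> VariantRecord:
    calls = {"mutant_pool": _call("hom_alt", _DEPTHS["mutant_pool"], 1.0)}
    for s in SAMPLES[1:]:
        calls[s] = _call("hom_ref", _DEPTHS[s])
    return VariantRecord(chrom, pos, "G", ("A",), calls)


def candidate_screen_records() -> tuple[list[VariantRecord], tuple[str, ...], set[tuple[str, int]]]:
    """Return (records, samples, expected surviving (chrom, pos) keys).

    The record list holds the 28 planted candidates plus three decoys, one
    per filtering clause, interleaved deterministically.
    """
    records: list[VariantRecord] = []
    expected: set[tuple[str, int]] = set()
    for chrom, n in CANDIDATE_DISTRIBUTION.items():
        for i in range(n):
            pos = 1_000 * (i + 1) + 137
            records.append(_candidate(chrom, pos))
            expected.add((chrom, pos))

    # Decoy 1: uncertain genotype in one reference strain.
    decoy_missing = VariantRecord("chr2", 99_137, "C", ("T",), {
        "mutant_pool": _call("hom_alt", 70, 1.0),
        "parental": _call("missing", 5),
        "outcross_1": _call("hom_ref", 65),
        "outcross_2": _call("hom_ref", 73),
    })
    # Decoy 2: mutant pool heterozygous (incomplete assortment signature).
    decoy_het = VariantRecord("chr1", 99_137, "A", ("G",), {
        "mutant_pool": _call("het", 70, 0.48),
        "parental": _call("hom_ref", 256),
        "outcross_1": _call("hom_ref", 65),
        "outcross_2": _call("hom_ref", 73),
    })
    # Decoy 3: mutant homozygote shared with an outcross strain (a strain
    # polymorphism, not a mutagenesis product).
    decoy_shared = VariantRecord("chr3", 99_137, "T", ("C",), {
        "mutant_pool": _call("hom_alt", 70, 1.0),
        "parental": _call("hom_ref", 256),
        "outcross_1": _call("hom_alt", 65, 1.0),
        "outcross_2": _call("hom_ref", 73),
    })
    records[5:5] = [decoy_missing]
    records[17:17] = [decoy_het]
    records[25:25] = [decoy_shared]
    return records, SAMPLES, expected
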