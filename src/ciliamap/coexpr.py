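"""Coexpression-based candidate prioritization.

Candidate genes are ranked by how closely their expression profile tracks
those of known pathway genes. Profiles are first normalized to each gene's
own maximum (so only the *shape* of the trace matters), then compared by
Pearson correlation (cosine and Spearman are available); each candidate's
score is its best similarity over the reference gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consequence import ConsequenceRecord
from .errors import ConfigError, ContractError, DataError
from .io import CONDITION_LABELS, ExpressionProfile

SIMILARITY_METHODS = ("pearson", "cosine", "spearman")


@dataclass(frozen=True)
class NormalizedProfile:
    """Expression profile scaled to the gene's maximum (values in [0, 1])."""

    gene_id: str
    values: tuple[float, ...]
    no_signal: bool = False
    conditions: tuple[str, ...] = CONDITION_LABELS


@dataclass(frozen=True)
class RankedCandidate:
    gene_id: str | None
    variant: ConsequenceRecord
    similarity: float | None
    rank: int
    flags: frozenset[str]


def normalize_profile(profile: ExpressionProfile) -> NormalizedProfile:
    """Divide by the profile maximum; an all-zero profile is flagged no_signal."""
    v = np.asarray(profile.values, dtype=float)
    if not np.all(np.isfinite(v)) or (v < 0).any():
        raise DataError(f"gene {profile.gene_id}: values must be finite and >= 0")
    m = v.max()
    if m == 0:
        return NormalizedProfile(profile.gene_id, tuple(v), no_signal=True,
                                 conditions=profile.conditions)
    return NormalizedProfile(profile.gene_id, tuple(float(x) for x in v / m),
                             conditions=profile.conditions)


def profile_similarity(a: NormalizedProfile, b: NormalizedProfile,
                       method: str = "pearson") -> float:
    """Similarity of two normalized profiles in [-1, 1].

    Pearson (default) and Spearman are undefined for a constant profile; such
    comparisons score 0. Profiles must share the same condition order.
    """
    if a.conditions != b.conditions:
        raise ContractError(
            f"condition labels differ between {a.gene_id} and {b.gene_id}")
    va = np.asarray(a.values, dtype=float)
    vb = np.asarray(b.values, dtype=float)
    if method == "pearson":
        if va.std() == 0 or vb.std() == 0:
            return 0.0
        return float(stats.pearsonr(va, vb).statistic)
    if method == "spearman":
        if va.std() == 0 or vb.std() == 0:
            return 0.0
        return float(stats.spearmanr(va, vb).statistic)
    if method == "cosine":
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))
    raise ConfigError(f"unknown similarity method {method!r}; "
                      f"choose one of {SIMILARITY_METHODS}")


def flag_low_expression(profile: ExpressionProfile, background: float) -> bool:
    """True iff the gene's raw maximum sits below twice the background level.

    Annotative only: the flag never alters a candidate's rank.
    """
    if background <= 0:
        raise ConfigError("background must be positive")
    return max(profile.values) < 2.0 * background


def rank_candidates(candidates: Sequence[ConsequenceRecord],
                    table: Mapping[str, ExpressionProfile],
                    references: Sequence[str],
                    method: str = "pearson",
                    aggregate: str = "max",
                    background: float | None = None) -> list[RankedCandidate]:
    """Rank candidate genes by best profile similarity to the reference set.

    Candidates without a profile are flagged ``no_profile`` and placed after
    all scored candidates. Ties break by descending similarity, then
    ascending gene_id (stable and documented).
    """
    if not references:
        raise ConfigError("reference gene set must be nonempty")
    missing = [g for g in references if g not in table]
    if missing:
        raise ConfigError(f"reference genes absent from expression table: {missing}")
    if aggregate not in ("max", "mean"):
        raise ConfigError(f"unknown aggregation {aggregate!r}")
    ref_norm = [normalize_profile(table[g]) for g in references]

    scored: list[tuple[float, str, ConsequenceRecord, set[str]]] = []
    unscored: list[tuple[str, ConsequenceRecord, set[str]]] = []
    for cand in candidates:
        gid = cand.gene_id
        flags: set[str] = set()
        if gid is None or gid not in table:
            flags.add("no_profile")
            unscored.append((gid if gid is not None else "", cand, flags))
            continue
        profile = table[gid]
        norm = normalize_profile(profile)
        if norm.no_signal:
            flags.add("no_signal")
        sims = [profile_similarity(norm, r, method) for r in ref_norm]
        sim = max(sims) if aggregate == "max" else float(np.mean(sims))
        if background is not None and flag_low_expression(profile, background):
            flags.add("low_expression")
        scored.append((sim, gid, cand, flags))

    scored.sort(key=lambda t: (-t[0], t[1]))
    unscored.sort(key=lambda t: t[0])
    ranked: list[RankedCandidate] = []
    rank = 1
    for sim, gid, cand, flags in scored:
        ranked.append(RankedCandidate(gid, cand, sim, rank, frozenset(flags)))
        rank += 1
    for gid, cand, flags in unscored:
        ranked.append(RankedCandidate(cand.gene_id, cand, None, rank, frozenset(flags)))
        rank += 1
    return ranked


def write_ranked(ranked: Sequence[RankedCandidate], path) -> Path:
    rows = []
    for r in ranked:
        rows.append({
            "rank": r.rank,
            "gene_id": r.gene_id if r.gene_id is not None else ".",
            "chrom": r.variant.variant.chrom,
            "pos": r.variant.variant.pos,
            "ref": r.variant.variant.ref_allele,
            "alt": r.variant.alt_allele,
            "effect": r.variant.effect.value,
            "similarity": f"{r.similarity:.6f}" if r.similarity is not None else ".",
            "flags": ",".join(sorted(r.flags)) if r.flags else ".",
        })
    pd.DataFrame(rows, columns=["rank", "gene_id", "chrom", "pos", "ref", "alt",
                                "effect", "similarity", "flags"]
                 ).to_csv(path, sep="\t", index=False)
    return Path(path)
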