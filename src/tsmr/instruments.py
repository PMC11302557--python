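"""Instrument-selection filters for two-sample MR.

Filters follow the usual screening sequence for summary-level instruments:
genome-wide-suggestive significance (p < 1e-5 by default), minor-allele
frequency >= 0.01, greedy LD clumping (r² < 0.01 within a 10,000 kb window),
and an F >= 10 instrument-strength screen.  Each filter partitions its input
exhaustively; every dropped record carries exactly one reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .io import LDMatrix, SummaryStatRecord

logger = logging.getLogger(__name__)


class DropReason(str, Enum):
    PVALUE = "pvalue"
    MAF = "maf"
    CLUMPED = "clumped"
    WEAK = "weak"
    PALINDROME = "palindrome"
    UNMATCHED = "unmatched"


@dataclass
class InstrumentStats:
    """Per-record selection outcome: F statistic, kept flag, drop reason."""

    record: SummaryStatRecord
    f_stat: float | None = None
    kept: bool = True
    drop_reason: DropReason | None = None

    def __post_init__(self):
        if self.kept == (self.drop_reason is not None):
            raise ValueError("kept flag must match absence of drop_reason")


@dataclass
class Partition:
    """Exhaustive, disjoint split of records into kept and dropped."""

    kept: list[SummaryStatRecord]
    dropped: list[tuple[SummaryStatRecord, DropReason]]
    warnings: list[str] = field(default_factory=list)


def filter_by_pvalue(
    records: Sequence[SummaryStatRecord], threshold: float = 1e-5
) -> Partition:
    """Keep records with p strictly below ``threshold`` (boundary dropped)."""
    kept, dropped = [], []
    for rec in records:
        if rec.pvalue < threshold:
            kept.append(rec)
        else:
            dropped.append((rec, DropReason.PVALUE))
    return Partition(kept, dropped)


def filter_by_maf(
    records: Sequence[SummaryStatRecord], maf_min: float = 0.01
) -> Partition:
    """Keep records with MAF = min(eaf, 1-eaf) >= ``maf_min``.

    Records without an allele frequency are kept with a warning: frequency is
    routinely absent from consortium exports, and dropping them wholesale
    would gut the instrument set.
    """
    kept, dropped, warnings = [], [], []
    for rec in records:
        if rec.eaf is None:
            warnings.append(f"{rec.variant_id}: no eaf; MAF filter skipped")
            kept.append(rec)
        elif min(rec.eaf, 1.0 - rec.eaf) >= maf_min:
            kept.append(rec)
        else:
            dropped.append((rec, DropReason.MAF))
    if warnings:
        logger.warning(
            "%d record(s) lack eaf and bypassed the MAF filter", len(warnings)
        )
    return Partition(kept, dropped, warnings)


def f_statistic(
    record: SummaryStatRecord, method: str = "wald"
) -> float:
    """Single-SNP instrument-strength F statistic.

    ``wald`` (default): F = (beta/se)², the square of the Wald z.
    ``r2``: F = R²(N-2)/(1-R²) with R² the variance explained computed from
    beta, se, eaf and N; requires eaf and n.
    """
    if method == "wald":
        return (record.beta / record.se) ** 2
    if method == "r2":
        if record.eaf is None or record.n is None:
            raise ValueError("r2-based F requires eaf and n")
        p, n = record.eaf, record.n
        var_g = 2.0 * p * (1.0 - p)
        num = record.beta**2 * var_g
        r2 = num / (num + record.se**2 * var_g * n)
        return r2 * (n - 2) / (1.0 - r2)
    raise ValueError(f"unknown F-statistic method {method!r}")


def filter_by_f(
    records: Sequence[SummaryStatRecord],
    f_min: float = 10.0,
    method: str = "wald",
) -> tuple[Partition, dict[str, float]]:
    """Drop weak instruments (F < ``f_min``); returns per-id F values too."""
    kept, dropped, f_stats = [], [], {}
    for rec in records:
        f = f_statistic(rec, method=method)
        f_stats[rec.variant_id] = f
        if f >= f_min:
            kept.append(rec)
        else:
            dropped.append((rec, DropReason.WEAK))
    return Partition(kept, dropped), f_stats


def ld_clump(
    records: Sequence[SummaryStatRecord],
    ld: LDMatrix | None = None,
    r2_max: float = 0.01,
    window_kb: float = 10_000.0,
) -> Partition:
    """Greedy LD clumping: keep the most significant SNP per correlated region.

    Candidates are taken in ascending p-value order; each index SNP removes
    every remaining SNP on the same chromosome within ``window_kb`` of it
    whose r² with it is >= ``r2_max``.  Records without positions are treated
    as always within the window (conservative).  Without an LD matrix the
    filter is a no-op with a prominent warning, since computing LD from a
    reference panel is outside this package's scope.
    """
    if ld is None:
        logger.warning(
            "LD matrix not provided: clumping skipped, all %d records retained",
            len(records),
        )
        return Partition(list(records), [], ["clumping skipped: no LD matrix"])
    idx = {v: i for i, v in enumerate(ld.variant_ids)}
    missing = [r.variant_id for r in records if r.variant_id not in idx]
    if missing:
        raise KeyError(f"variant id(s) missing from LD matrix: {missing[:5]}")

    order = sorted(range(len(records)), key=lambda i: (records[i].pvalue, i))
    removed: dict[int, DropReason] = {}
    kept_idx: list[int] = []
    for i in order:
        if i in removed:
            continue
        kept_idx.append(i)
        ri = records[i]
        for j in order:
            if j == i or j in removed or j in kept_idx:
                continue
            rj = records[j]
            same_chrom = (
                ri.chromosome is None
                or rj.chromosome is None
                or ri.chromosome == rj.chromosome
            )
            if not same_chrom:
                continue
            if ri.position is not None and rj.position is not None:
                if abs(ri.position - rj.position) > window_kb * 1000.0:
                    continue
            if ld.r2[idx[ri.variant_id], idx[rj.variant_id]] >= r2_max:
                removed[j] = DropReason.CLUMPED
    kept_set = set(kept_idx)
    kept = [records[i] for i in range(len(records)) if i in kept_set]
    dropped = [(records[i], removed[i]) for i in range(len(records)) if i in removed]
    return Partition(kept, dropped)


@dataclass
class SelectionResult:
    """Outcome of the full instrument-selection cascade."""

    kept: list[SummaryStatRecord]
    stats: list[InstrumentStats]
    warnings: list[str]

    @property
    def dropped(self) -> list[InstrumentStats]:
        return [s for s in self.stats if not s.kept]


def select_instruments(
    records: Sequence[SummaryStatRecord],
    pval_threshold: float = 1e-5,
    maf_min: float = 0.01,
    f_min: float = 10.0,
    ld: LDMatrix | None = None,
    clump_r2: float = 0.01,
    clump_kb: float = 10_000.0,
    f_method: str = "wald",
) -> SelectionResult:
    """Run the selection cascade: p-value -> MAF -> LD clump -> F screen.

    The p/MAF/F filters are per-record and commute; clumping runs before the
    F screen so that index-SNP choice is not affected by strength filtering.
    """
    reasons: dict[str, DropReason] = {}
    warnings: list[str] = []

    part = filter_by_pvalue(records, pval_threshold)
    reasons.update({r.variant_id: why for r, why in part.dropped})
    part2 = filter_by_maf(part.kept, maf_min)
    warnings += part2.warnings
    reasons.update({r.variant_id: why for r, why in part2.dropped})
    part3 = ld_clump(part2.kept, ld=ld, r2_max=clump_r2, window_kb=clump_kb)
    warnings += part3.warnings
    reasons.update({r.variant_id: why for r, why in part3.dropped})
    part4, f_stats = filter_by_f(part3.kept, f_min, method=f_method)
    reasons.update({r.variant_id: why for r, why in part4.dropped})

    kept_ids = {r.variant_id for r in part4.kept}
    stats = [
        InstrumentStats(
            record=rec,
            f_stat=f_stats.get(rec.variant_id),
            kept=rec.variant_id in kept_ids,
            drop_reason=reasons.get(rec.variant_id),
        )
        for rec in records
    ]
    return SelectionResult(kept=part4.kept, stats=stats, warnings=warnings)


__all__ = [
    "DropReason",
    "InstrumentStats",
    "Partition",
    "SelectionResult",
    "filter_by_pvalue",
    "filter_by_maf",
    "f_statistic",
    "filter_by_f",
    "ld_clump",
    "select_instruments",
]
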