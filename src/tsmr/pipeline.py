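"""End-to-end per-pair analysis, multiple-testing policy, and reporting.

``run_pair`` chains instrument selection, harmonization, the five estimators
and the sensitivity battery for one exposure/outcome pair; ``summarize``
applies the nominal and per-rank Bonferroni significance policies across many
pairs and counts causal directions; ``render_tables`` emits the standard
published layout (Group, Bacterial, Nsnp, Methods, SE, OR (95% CI), P-value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import (
    METHOD_LABELS,
    Method,
    MREstimate,
    all_estimates,
)
from .harmonize import harmonize
from .instruments import select_instruments
from .io import LDMatrix, SummaryStatRecord, TINY_PVALUE
from .sensitivity import SensitivityReport, run_sensitivity

_LABEL_TO_METHOD = {v: k for k, v in METHOD_LABELS.items()}


@dataclass
class PipelineConfig:
    """Thresholds and simulation settings for one study run."""

    pval_threshold: float = 1e-5
    maf_min: float = 0.01
    f_min: float = 10.0
    clump_r2: float = 0.01
    clump_kb: float = 10_000.0
    alpha: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int | None = 0


@dataclass
class PairResult:
    """Everything computed for one exposure/outcome pair."""

    exposure_label: str
    outcome_label: str
    estimates: dict[Method, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    n_snp_initial: int = 0
    n_snp_final: int = 0
    rank: str | None = None  # taxonomic rank of the exposure (phylum..genus)
    status: str = "ok"  # or "insufficient instruments"
    drop_counts: dict[str, int] = field(default_factory=dict)
    estimates_post_presso: dict[Method, MREstimate] | None = None

    @property
    def ivw(self) -> MREstimate | None:
        return self.estimates.get(Method.IVW)


def run_pair(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    config: PipelineConfig | None = None,
    ld: LDMatrix | None = None,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
    rank: str | None = None,
) -> PairResult:
    """Select instruments, harmonize, estimate, and run diagnostics.

    If the outlier test removes instruments, all estimates are recomputed on
    the survivors (kept in ``estimates_post_presso``) while the pre-removal
    estimates remain in ``estimates``.  Fewer than 2 usable instruments marks
    the pair ``insufficient instruments`` instead of raising.
    """
    cfg = config or PipelineConfig()
    result = PairResult(
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        rank=rank,
        n_snp_initial=len(exposure),
    )
    sel = select_instruments(
        exposure,
        pval_threshold=cfg.pval_threshold,
        maf_min=cfg.maf_min,
        f_min=cfg.f_min,
        ld=ld,
        clump_r2=cfg.clump_r2,
        clump_kb=cfg.clump_kb,
    )
    for s in sel.stats:
        if not s.kept:
            key = s.drop_reason.value
            result.drop_counts[key] = result.drop_counts.get(key, 0) + 1

    snps, exclusions = harmonize(sel.kept, outcome)
    for e in exclusions:
        result.drop_counts[e.reason] = result.drop_counts.get(e.reason, 0) + 1
    result.n_snp_final = len(snps)
    if len(snps) < 2:
        result.status = "insufficient instruments"
        return result

    result.estimates = all_estimates(snps, n_boot=cfg.n_boot, seed=cfg.seed)
    result.sensitivity = run_sensitivity(
        snps, n_sim=cfg.n_sim, significance=cfg.alpha, seed=cfg.seed
    )
    presso = result.sensitivity.presso
    if presso is not None and presso.removed_ids:
        survivors = [s for s in snps if s.variant_id not in set(presso.removed_ids)]
        result.estimates_post_presso = all_estimates(
            survivors, n_boot=cfg.n_boot, seed=cfg.seed
        )
        result.n_snp_final = len(survivors)
    return result


def classify_direction(estimate: MREstimate) -> str:
    """``positive`` when OR > 1, ``negative`` when OR < 1; OR = 1 counts positive."""
    return "positive" if estimate.or_ >= 1.0 else "negative"


def bonferroni_threshold(n_taxa_at_level: int, alpha: float = 0.05) -> float:
    """Per-rank multiple-testing threshold alpha / n."""
    if n_taxa_at_level < 1:
        raise ValueError("n_taxa_at_level must be >= 1")
    return alpha / n_taxa_at_level


@dataclass
class StudySummary:
    """Headline counts of IVW-significant pairs across a study."""

    per_outcome: dict[str, dict[str, int]]
    total_significant: int
    bonferroni_thresholds: dict[str, float]
    bonferroni_survivors: list[tuple[str, str]]  # (outcome, exposure) pairs

    def counts(self, outcome: str) -> tuple[int, int]:
        c = self.per_outcome[outcome]
        return c["positive"], c["negative"]


def summarize(
    results: Sequence[PairResult],
    alpha: float = 0.05,
    taxa_per_rank: Mapping[str, int] | None = None,
) -> StudySummary:
    """Count IVW-significant pairs per outcome, split by causal direction.

    A pair is significant when its IVW p-value is below ``alpha``.  Rank-level
    Bonferroni thresholds use ``taxa_per_rank`` when given, otherwise the
    number of distinct exposures of each rank present in ``results``.
    """
    if not results:
        raise ValueError("results must be nonempty")
    if taxa_per_rank is None:
        seen: dict[str, set[str]] = {}
        for r in results:
            if r.rank:
                seen.setdefault(r.rank.lower(), set()).add(r.exposure_label)
        taxa_per_rank = {k: len(v) for k, v in seen.items()}
    thresholds = {
        rank: bonferroni_threshold(n, alpha) for rank, n in taxa_per_rank.items() if n
    }

    per_outcome: dict[str, dict[str, int]] = {}
    survivors: list[tuple[str, str]] = []
    total = 0
    for r in results:
        est = r.ivw
        if est is None:
            continue
        bucket = per_outcome.setdefault(
            r.outcome_label, {"positive": 0, "negative": 0, "total": 0}
        )
        if est.pvalue < alpha:
            bucket[classify_direction(est)] += 1
            bucket["total"] += 1
            total += 1
            rank_key = (r.rank or "").lower()
            if rank_key in thresholds and est.pvalue < thresholds[rank_key]:
                survivors.append((r.outcome_label, r.exposure_label))
    return StudySummary(
        per_outcome=per_outcome,
        total_significant=total,
        bonferroni_thresholds=thresholds,
        bonferroni_survivors=survivors,
    )


def pair_results_from_table(df: pd.DataFrame, outcome_label: str) -> list[PairResult]:
    """Rehydrate PairResults from a result table in the published layout.

    Expects tidy columns (group, taxon, nsnp, method, se, or, ci_low, ci_high,
    pvalue), one row per (taxon, method).  OR/CI/p are taken as printed; the
    log-OR is recovered as ln(OR).
    """
    results: list[PairResult] = []
    for (group, taxon, nsnp), sub in df.groupby(
        ["group", "taxon", "nsnp"], sort=False
    ):
        pr = PairResult(
            exposure_label=str(taxon),
            outcome_label=outcome_label,
            rank=str(group),
            n_snp_initial=int(nsnp),
            n_snp_final=int(nsnp),
        )
        for _, row in sub.iterrows():
            method = _LABEL_TO_METHOD[str(row["method"])]
            or_ = float(row["or"])
            pr.estimates[method] = MREstimate(
                method=method,
                n_snp=int(nsnp),
                beta=math.log(or_),
                se=float(row["se"]),
                pvalue=max(float(row["pvalue"]), TINY_PVALUE),
                or_=or_,
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
            )
        results.append(pr)
    return results


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def render_tables(
    results: Sequence[PairResult], post_presso: bool = False
) -> dict[str, pd.DataFrame]:
    """Per-outcome result tables in the published layout.

    One row per (pair, method); OR, CI bounds and p rounded to 3 decimals,
    the OR cell formatted ``x.xxx (x.xxx, x.xxx)``.
    """
    by_outcome: dict[str, list[dict]] = {}
    for r in results:
        estimates = (
            r.estimates_post_presso
            if post_presso and r.estimates_post_presso
            else r.estimates
        )
        for method, est in estimates.items():
            if method == Method.EGGER_INTERCEPT:
                continue
            by_outcome.setdefault(r.outcome_label, []).append(
                {
                    "Group": (r.rank or "").capitalize(),
                    "Bacterial": r.exposure_label,
                    "Nsnp": est.n_snp,
                    "Methods": METHOD_LABELS[method],
                    "SE": _fmt(est.se),
                    "OR (95% CI)": f"{_fmt(est.or_)} ({_fmt(est.ci_low)}, {_fmt(est.ci_high)})",
                    "P-value": _fmt(est.pvalue),
                }
            )
    columns = ["Group", "Bacterial", "Nsnp", "Methods", "SE", "OR (95% CI)", "P-value"]
    return {
        outcome: pd.DataFrame(rows, columns=columns)
        for outcome, rows in by_outcome.items()
    }


__all__ = [
    "PipelineConfig",
    "PairResult",
    "StudySummary",
    "run_pair",
    "classify_direction",
    "bonferroni_threshold",
    "summarize",
    "pair_results_from_table",
    "render_tables",
]
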