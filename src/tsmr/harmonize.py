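"""Allele harmonization between exposure and outcome summary statistics.

Both studies must report each variant's effect on the same allele before any
ratio of effects is meaningful.  Matching is by variant id; outcome alleles
are reconciled to the exposure's effect allele by direct copy, allele swap
(beta negated, frequency complemented), strand flip (base complement, sign
preserved), or flip-and-swap.  Palindromic variants (A/T or C/G) are excluded
unconditionally: their strand cannot be resolved from the alleles alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import SummaryStatRecord, drop_duplicate_ids

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class HarmonizedSNP:
    """One instrument with exposure and outcome effects on a shared allele."""

    variant_id: str
    bx: float
    sx: float
    by: float
    sy: float
    eaf_x: float | None = None
    eaf_y: float | None = None

    def __post_init__(self):
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("standard errors must be positive")


@dataclass(frozen=True)
class Exclusion:
    variant_id: str
    reason: str  # palindrome | unmatched | missing | duplicate


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return COMPLEMENT.get(effect_allele) == other_allele


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
) -> tuple[list[HarmonizedSNP], list[Exclusion]]:
    """Align outcome effects to the exposure effect allele per variant.

    Returns harmonized instruments (in exposure order) plus an exclusion log;
    every id present in either input appears exactly once across the two.
    Duplicate ids within one table keep the smallest-p instance.
    """
    exclusions: list[Exclusion] = []
    exposure, dup_x = drop_duplicate_ids(exposure)
    outcome, dup_y = drop_duplicate_ids(outcome)
    for rec in dup_x + dup_y:
        exclusions.append(Exclusion(rec.variant_id, "duplicate"))

    out_by_id = {r.variant_id: r for r in outcome}
    exp_ids = {r.variant_id for r in exposure}
    harmonized: list[HarmonizedSNP] = []

    for ex in exposure:
        oc = out_by_id.get(ex.variant_id)
        if oc is None:
            exclusions.append(Exclusion(ex.variant_id, "missing"))
            continue
        if is_palindromic(ex.effect_allele, ex.other_allele) or is_palindromic(
            oc.effect_allele, oc.other_allele
        ):
            exclusions.append(Exclusion(ex.variant_id, "palindrome"))
            continue

        ea, oa = ex.effect_allele, ex.other_allele
        cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
        o_pair = (oc.effect_allele, oc.other_allele)
        if o_pair == (ea, oa):  # already aligned
            by, eaf_y = oc.beta, oc.eaf
        elif o_pair == (oa, ea):  # swapped
            by = -oc.beta
            eaf_y = None if oc.eaf is None else 1.0 - oc.eaf
        elif o_pair == (cea, coa):  # strand flip
            by, eaf_y = oc.beta, oc.eaf
        elif o_pair == (coa, cea):  # flipped and swapped
            by = -oc.beta
            eaf_y = None if oc.eaf is None else 1.0 - oc.eaf
        else:
            exclusions.append(Exclusion(ex.variant_id, "unmatched"))
            continue
        harmonized.append(
            HarmonizedSNP(
                variant_id=ex.variant_id,
                bx=ex.beta,
                sx=ex.se,
                by=by,
                sy=oc.se,
                eaf_x=ex.eaf,
                eaf_y=eaf_y,
            )
        )

    for oc in outcome:
        if oc.variant_id not in exp_ids:
            exclusions.append(Exclusion(oc.variant_id, "missing"))
    return harmonized, exclusions


__all__ = ["HarmonizedSNP", "Exclusion", "COMPLEMENT", "is_palindromic", "harmonize"]
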