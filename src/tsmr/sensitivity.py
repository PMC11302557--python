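"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Cochran's Q (about the IVW or MR-Egger fit), the MR-Egger intercept test for
directional pleiotropy, a simulation-based residual-sum-of-squares outlier
test with iterative removal (MR-PRESSO style global and per-SNP components),
and leave-one-out influence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    InsufficientInstruments,
    Method,
    MREstimate,
    cochran_q_ivw,
    ivw,
    egger,
    _arrays,
    _wls_with_intercept,
)
from .harmonize import HarmonizedSNP


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float
    reference: str  # "ivw" or "egger"


def cochran_q(
    snps: Sequence[HarmonizedSNP], reference: str = "ivw"
) -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic about the chosen reference fit.

    ``ivw``: Q = sum of bx²/sy² weighted squared deviations of the Wald ratios
    from the fixed-effect estimate, chi-square with J-1 df.  ``egger``: the
    residual-based analogue about the fitted Egger line (Rucker's Q'), J-2 df.
    """
    J = len(snps)
    bx, _, by, sy = _arrays(snps)
    if reference == "ivw":
        if J < 2:
            raise InsufficientInstruments("Q about IVW requires at least 2 instruments")
        q = cochran_q_ivw(bx, by, sy)
        df = J - 1
    elif reference == "egger":
        if J < 3:
            raise InsufficientInstruments("Q about Egger requires at least 3 instruments")
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        x, y, w = bx * flip, by * flip, 1.0 / sy**2
        a, b, _, _, _ = _wls_with_intercept(x, y, w)
        q = float(np.sum(w * (y - a - b * x) ** 2))
        df = J - 2
    else:
        raise ValueError(f"unknown reference {reference!r}")
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(Q=q, df=df, pvalue=max(p, np.finfo(float).tiny), reference=reference)


def egger_intercept_test(
    snps: Sequence[HarmonizedSNP], alpha: float = 0.05
) -> tuple[MREstimate, bool]:
    """MR-Egger intercept estimate and a pleiotropy flag at ``alpha``.

    A non-zero intercept with p below alpha indicates average directional
    pleiotropy across the instruments.
    """
    _, intercept = egger(snps)
    return intercept, intercept.pvalue < alpha


@dataclass
class PressoResult:
    """Global RSS test, per-SNP outlier p-values, and the removal trace."""

    global_rss: float
    global_p: float
    outlier_pvalues: dict[str, float]  # Bonferroni-adjusted, from the first pass
    removed_ids: list[str]
    corrected_estimate: MREstimate | None
    original_estimate: MREstimate
    n_sim: int
    seed: int | None
    distortion: float | None = None  # relative shift of the corrected estimate


def _loo_ivw_vec(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates for every j, vectorized.

    Accepts 1-D arrays or (n_sim, J) stacks; returns the same shape.
    """
    sxx = np.sum(w * bx**2, axis=-1, keepdims=True)
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def _rss_components(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-SNP weighted squared leave-one-out residuals w_j (by_j - b(-j) bx_j)²."""
    beta_loo = _loo_ivw_vec(bx, by, w)
    return w * (by - beta_loo * bx) ** 2


def mr_presso(
    snps: Sequence[HarmonizedSNP],
    n_sim: int = 1000,
    significance: float = 0.05,
    seed: int | None = None,
    fix_exposure: bool = False,
) -> PressoResult:
    """Simulation-based pleiotropy residual test with iterative outlier removal.

    The observed statistic is the weighted residual sum of squares about
    leave-one-out IVW predictions.  Its null distribution is built by drawing,
    per replicate, by*_j ~ N(b(-j)·bx_j, sy_j) and (unless ``fix_exposure``)
    bx*_j ~ N(bx_j, sx_j), then recomputing the statistic on the simulated
    data.  Empirical p-values use the add-one rule.  While the global test is
    significant and some Bonferroni-adjusted per-SNP p is below the threshold,
    the worst SNP is removed and everything recomputed; removal stops once the
    global test is non-significant or fewer than 4 instruments would remain.
    """
    if len(snps) < 4:
        raise InsufficientInstruments("MR-PRESSO requires at least 4 instruments")
    rng = np.random.default_rng(seed)
    original = ivw(snps)
    current = list(snps)
    removed: list[str] = []
    first_pass: dict[str, float] | None = None
    global_rss_first: float | None = None
    global_p = 1.0

    while True:
        J = len(current)
        bx, sx, by, sy = _arrays(current)
        w = 1.0 / sy**2
        comp_obs = _rss_components(bx, by, w)
        rss_obs = float(np.sum(comp_obs))

        beta_loo = _loo_ivw_vec(bx, by, w)
        by_sim = beta_loo * bx + rng.standard_normal((n_sim, J)) * sy
        if fix_exposure:
            bx_sim = np.broadcast_to(bx, (n_sim, J))
        else:
            bx_sim = bx + rng.standard_normal((n_sim, J)) * sx
        comp_sim = _rss_components(bx_sim, by_sim, w)
        rss_sim = comp_sim.sum(axis=1)

        global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
        p_out = (1 + np.sum(comp_sim >= comp_obs, axis=0)) / (n_sim + 1)
        p_adj = np.minimum(1.0, p_out * J)

        if first_pass is None:
            first_pass = {s.variant_id: float(p) for s, p in zip(current, p_adj)}
            global_rss_first = rss_obs

        worst = int(np.argmin(p_adj))
        if (
            global_p < significance
            and p_adj[worst] < significance
            and J - 1 >= 4
        ):
            removed.append(current[worst].variant_id)
            del current[worst]
            continue
        break

    corrected = ivw(current) if removed else None
    distortion = None
    if corrected is not None and original.beta != 0:
        distortion = float((corrected.beta - original.beta) / abs(original.beta))
    return PressoResult(
        global_rss=float(global_rss_first),
        global_p=global_p,
        outlier_pvalues=first_pass,
        removed_ids=removed,
        corrected_estimate=corrected,
        original_estimate=original,
        n_sim=n_sim,
        seed=seed,
        distortion=distortion,
    )


def leave_one_out(
    snps: Sequence[HarmonizedSNP], min_snps: int = 3
) -> pd.DataFrame:
    """IVW recomputed with each instrument left out in turn, plus the full fit.

    Returns a DataFrame with one row per excluded SNP and a final "All" row;
    forest-plot ready (excluded_id, beta, se, pvalue, or_, ci_low, ci_high).
    """
    J = len(snps)
    if J < min_snps:
        raise InsufficientInstruments(f"leave-one-out requires at least {min_snps} instruments")
    rows = []
    for i in range(J):
        sub = [s for k, s in enumerate(snps) if k != i]
        est = ivw(sub)
        rows.append((snps[i].variant_id, est))
    rows.append(("All", ivw(snps)))
    return pd.DataFrame(
        {
            "excluded_id": [r[0] for r in rows],
            "beta": [r[1].beta for r in rows],
            "se": [r[1].se for r in rows],
            "pvalue": [r[1].pvalue for r in rows],
            "or_": [r[1].or_ for r in rows],
            "ci_low": [r[1].ci_low for r in rows],
            "ci_high": [r[1].ci_high for r in rows],
        }
    )


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure/outcome pair."""

    q_ivw: HeterogeneityResult | None = None
    q_egger: HeterogeneityResult | None = None
    egger_intercept: MREstimate | None = None
    pleiotropy_flag: bool | None = None
    presso: PressoResult | None = None
    loo: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d: dict = {"notes": list(self.notes)}
        if self.q_ivw:
            d["cochran_q_ivw"] = {
                "Q": self.q_ivw.Q, "df": self.q_ivw.df, "pvalue": self.q_ivw.pvalue,
            }
        if self.q_egger:
            d["cochran_q_egger"] = {
                "Q": self.q_egger.Q, "df": self.q_egger.df, "pvalue": self.q_egger.pvalue,
            }
        if self.egger_intercept:
            d["egger_intercept"] = {
                "beta": self.egger_intercept.beta,
                "se": self.egger_intercept.se,
                "pvalue": self.egger_intercept.pvalue,
                "significant": bool(self.pleiotropy_flag),
            }
        if self.presso:
            d["mr_presso"] = {
                "global_rss": self.presso.global_rss,
                "global_p": self.presso.global_p,
                "removed_ids": list(self.presso.removed_ids),
                "outlier_pvalues": dict(self.presso.outlier_pvalues),
                "n_sim": self.presso.n_sim,
                "distortion": self.presso.distortion,
            }
        if self.loo is not None:
            d["leave_one_out"] = self.loo.to_dict(orient="records")
        return d


def run_sensitivity(
    snps: Sequence[HarmonizedSNP],
    n_sim: int = 1000,
    significance: float = 0.05,
    seed: int | None = None,
) -> SensitivityReport:
    """Run every applicable diagnostic, degrading gracefully at small J."""
    report = SensitivityReport()
    J = len(snps)
    if J >= 2:
        report.q_ivw = cochran_q(snps, "ivw")
    if J >= 3:
        report.q_egger = cochran_q(snps, "egger")
        report.egger_intercept, report.pleiotropy_flag = egger_intercept_test(
            snps, alpha=significance
        )
        report.loo = leave_one_out(snps)
    if J >= 4:
        report.presso = mr_presso(
            snps, n_sim=n_sim, significance=significance, seed=seed
        )
    else:
        report.notes.append(f"MR-PRESSO skipped: {J} < 4 instruments")
    return report


__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "run_sensitivity",
]
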