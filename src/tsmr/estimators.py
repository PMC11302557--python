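"""Causal-effect estimators for two-sample MR on harmonized instruments.

Implements the Wald ratio, inverse-variance weighted (IVW) regression through
the origin with multiplicative random-effects scaling, MR-Egger regression
(slope and pleiotropy intercept), the weighted median, and mode-based
estimators (simple and weighted), plus conversion of log-scale estimates to
odds ratios with 95% confidence bounds.

Conventions, since summary-level MR papers rarely state them: IVW, median and
mode p-values use a standard-normal reference; MR-Egger uses Student t with
J - 2 degrees of freedom.  Median and mode standard errors come from a seeded
parametric bootstrap perturbing both exposure and outcome betas by their
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSNP

Z975 = float(stats.norm.ppf(0.975))


class Method(str, Enum):
    WALD = "wald"
    IVW = "ivw"
    EGGER_SLOPE = "egger_slope"
    EGGER_INTERCEPT = "egger_intercept"
    WEIGHTED_MEDIAN = "weighted_median"
    SIMPLE_MODE = "simple_mode"
    WEIGHTED_MODE = "weighted_mode"


#: Human-readable method labels matching published MR result tables.
METHOD_LABELS = {
    Method.WALD: "Wald ratio",
    Method.IVW: "Inverse variance weighted",
    Method.EGGER_SLOPE: "MR Egger",
    Method.EGGER_INTERCEPT: "MR Egger intercept",
    Method.WEIGHTED_MEDIAN: "Weighted median",
    Method.SIMPLE_MODE: "Simple mode",
    Method.WEIGHTED_MODE: "Weighted mode",
}


class InsufficientInstruments(ValueError):
    """Fewer instruments than the estimator requires."""


class DegenerateInstrument(ValueError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds (beta) and OR scales."""

    method: Method
    n_snp: int
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    se_fixed: float | None = None  # fixed-effect se, kept for transparency (IVW)

    @classmethod
    def from_beta_se(
        cls,
        method: Method,
        n_snp: int,
        beta: float,
        se: float,
        pvalue: float | None = None,
        df: int | None = None,
        se_fixed: float | None = None,
    ) -> "MREstimate":
        if pvalue is None:
            if se == 0:
                pvalue = np.finfo(float).tiny if beta != 0 else 1.0
            elif df is not None:
                pvalue = 2.0 * stats.t.sf(abs(beta) / se, df)
            else:
                pvalue = 2.0 * stats.norm.sf(abs(beta) / se)
        or_, lo, hi = to_or_ci(beta, se)
        return cls(
            method=method,
            n_snp=n_snp,
            beta=float(beta),
            se=float(se),
            pvalue=float(max(pvalue, np.finfo(float).tiny)),
            or_=or_,
            ci_low=lo,
            ci_high=hi,
            se_fixed=se_fixed,
        )


def to_or_ci(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio exp(beta) with 95% Wald bounds exp(beta ∓ 1.96·se)."""
    if se < 0:
        raise ValueError("se must be >= 0")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z975 * se)),
        float(np.exp(beta + Z975 * se)),
    )


def _arrays(snps: Sequence[HarmonizedSNP]):
    bx = np.array([s.bx for s in snps], dtype=float)
    sx = np.array([s.sx for s in snps], dtype=float)
    by = np.array([s.by for s in snps], dtype=float)
    sy = np.array([s.sy for s in snps], dtype=float)
    return bx, sx, by, sy


def wald_ratio(snp: HarmonizedSNP) -> MREstimate:
    """Single-SNP ratio estimate by/bx with first-order se sy/|bx|."""
    if snp.bx == 0:
        raise DegenerateInstrument(f"{snp.variant_id}: exposure beta is 0")
    beta = snp.by / snp.bx
    se = snp.sy / abs(snp.bx)
    return MREstimate.from_beta_se(Method.WALD, 1, beta, se)


def ivw_fixed_effect(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    """Fixed-effect IVW slope and se: WLS of by on bx through the origin, weights 1/sy²."""
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / sxx
    return beta, float(np.sqrt(1.0 / sxx))


def cochran_q_ivw(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    """Cochran's Q about the fixed-effect IVW estimate, weights bx²/sy²."""
    beta, _ = ivw_fixed_effect(bx, by, sy)
    theta = by / bx
    w = bx**2 / sy**2
    return float(np.sum(w * (theta - beta) ** 2))


def ivw(snps: Sequence[HarmonizedSNP]) -> MREstimate:
    """Inverse-variance weighted estimate with multiplicative random effects.

    The reported se is the fixed-effect se inflated by max(1, sqrt(Q/(J-1))),
    so under-dispersion never shrinks it; both are retained on the result.
    A single instrument reduces exactly to its Wald ratio.
    """
    J = len(snps)
    if J == 0:
        raise InsufficientInstruments("IVW requires at least one instrument")
    if J == 1:
        est = wald_ratio(snps[0])
        return MREstimate.from_beta_se(
            Method.IVW, 1, est.beta, est.se, se_fixed=est.se
        )
    bx, _, by, sy = _arrays(snps)
    beta, se_fixed = ivw_fixed_effect(bx, by, sy)
    q = cochran_q_ivw(bx, by, sy)
    scale = max(1.0, np.sqrt(q / (J - 1)))
    return MREstimate.from_beta_se(
        Method.IVW, J, beta, se_fixed * scale, se_fixed=se_fixed
    )


def _wls_with_intercept(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Weighted least squares y ~ a + b·x; returns (a, b, se_a, se_b, sigma).

    Coefficient ses include the multiplicative overdispersion factor
    max(1, sigma) where sigma² is the weighted residual mean square.
    """
    J = len(x)
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    b = sxy / sxx
    a = ybar - b * xbar
    resid = y - a - b * x
    sigma2 = float(np.sum(w * resid**2) / (J - 2)) if J > 2 else 0.0
    sigma = np.sqrt(sigma2)
    infl = max(1.0, sigma)
    se_b = float(np.sqrt(1.0 / sxx)) * infl
    se_a = float(np.sqrt(1.0 / sw + xbar**2 / sxx)) * infl
    return float(a), float(b), se_a, se_b, float(sigma)


def egger(snps: Sequence[HarmonizedSNP]) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    Each instrument is oriented so its exposure effect is non-negative before
    the weighted regression with a free intercept (weights 1/sy²); the slope
    estimates the causal effect under InSIDE and the intercept the average
    directional pleiotropy.  P-values use t with J-2 df.
    """
    J = len(snps)
    if J < 3:
        raise InsufficientInstruments("MR-Egger requires at least 3 instruments")
    bx, _, by, sy = _arrays(snps)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x, y = bx * flip, by * flip
    w = 1.0 / sy**2
    a, b, se_a, se_b, _ = _wls_with_intercept(x, y, w)
    slope = MREstimate.from_beta_se(Method.EGGER_SLOPE, J, b, se_b, df=J - 2)
    intercept = MREstimate.from_beta_se(Method.EGGER_INTERCEPT, J, a, se_a, df=J - 2)
    return slope, intercept


def weighted_quantile(
    theta: np.ndarray, weights: np.ndarray, q: float = 0.5
) -> float:
    """Weighted quantile by linear interpolation of cumulative midpoint weights.

    With normalized weights w_j over ascending theta, the j-th plotting
    position is cumsum(w)_j - w_j/2; the quantile interpolates theta against
    these positions at q.
    """
    order = np.argsort(theta)
    th = theta[order]
    w = weights[order] / np.sum(weights)
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, p, th))


def _ratio_weights(bx: np.ndarray, sy: np.ndarray) -> np.ndarray:
    # First-order inverse-variance weights of the per-SNP ratio estimates.
    return bx**2 / sy**2


def _bootstrap_se(
    snps: Sequence[HarmonizedSNP],
    point_fn,
    n_boot: int,
    seed: int | None,
) -> float:
    """SD of ``point_fn`` over parametric resamples of (bx, by)."""
    bx, sx, by, sy = _arrays(snps)
    rng = np.random.default_rng(seed)
    J = len(snps)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + rng.standard_normal(J) * sx
        bys = by + rng.standard_normal(J) * sy
        est[b] = point_fn(bxs, bys, sy)
    return float(np.std(est, ddof=1))


def weighted_median(
    snps: Sequence[HarmonizedSNP],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimator: consistent if valid SNPs carry ≥50% of weight."""
    J = len(snps)
    if J < 3:
        raise InsufficientInstruments("weighted median requires at least 3 instruments")
    bx, _, by, sy = _arrays(snps)

    def point(bx_, by_, sy_):
        return weighted_quantile(by_ / bx_, _ratio_weights(bx_, sy_), 0.5)

    beta = point(bx, by, sy)
    se = _bootstrap_se(snps, point, n_boot, seed)
    return MREstimate.from_beta_se(Method.WEIGHTED_MEDIAN, J, beta, se)


def _mode_point(
    theta: np.ndarray,
    weights: np.ndarray,
    bandwidth_factor: float,
) -> float:
    """Argmax of a Gaussian-kernel density over the ratio estimates.

    Bandwidth h = phi * 0.9 * min(sd, 1.4826*MAD) * J^(-1/5) (modified
    Silverman rule with a MAD guard against outlier-inflated sd); ties on the
    512-point grid are averaged.  Identical ratios return that common value.
    """
    J = len(theta)
    sd = float(np.std(theta, ddof=1)) if J > 1 else 0.0
    mad = 1.4826 * float(np.median(np.abs(theta - np.median(theta))))
    spread = min(sd, mad) if min(sd, mad) > 0 else max(sd, mad)
    h = bandwidth_factor * 0.9 * spread * J ** (-0.2)
    if h == 0 or not np.isfinite(h):
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    w = weights / np.sum(weights)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2),
        axis=0,
    )
    peak = dens == dens.max()
    return float(np.mean(grid[peak]))


def mode_estimate(
    snps: Sequence[HarmonizedSNP],
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimator (simple or weighted) of the causal effect.

    Consistent when the largest cluster of instruments is valid (ZEMPA).
    ``weighted`` uses inverse-variance ratio weights in the kernel density;
    the simple mode weights every instrument equally.
    """
    J = len(snps)
    if J < 3:
        raise InsufficientInstruments("mode estimator requires at least 3 instruments")
    bx, _, by, sy = _arrays(snps)

    def point(bx_, by_, sy_):
        th = by_ / bx_
        w = _ratio_weights(bx_, sy_) if weighted else np.ones_like(th)
        return _mode_point(th, w, bandwidth_factor)

    beta = point(bx, by, sy)
    se = _bootstrap_se(snps, point, n_boot, seed)
    method = Method.WEIGHTED_MODE if weighted else Method.SIMPLE_MODE
    return MREstimate.from_beta_se(method, J, beta, se)


def all_estimates(
    snps: Sequence[HarmonizedSNP],
    n_boot: int = 1000,
    seed: int | None = None,
    bandwidth_factor: float = 1.0,
) -> dict[Method, MREstimate]:
    """IVW, MR-Egger slope+intercept, weighted median, simple and weighted mode."""
    out: dict[Method, MREstimate] = {Method.IVW: ivw(snps)}
    if len(snps) >= 3:
        slope, intercept = egger(snps)
        out[Method.EGGER_SLOPE] = slope
        out[Method.EGGER_INTERCEPT] = intercept
        out[Method.WEIGHTED_MEDIAN] = weighted_median(snps, n_boot=n_boot, seed=seed)
        out[Method.SIMPLE_MODE] = mode_estimate(
            snps, weighted=False, bandwidth_factor=bandwidth_factor,
            n_boot=n_boot, seed=seed,
        )
        out[Method.WEIGHTED_MODE] = mode_estimate(
            snps, weighted=True, bandwidth_factor=bandwidth_factor,
            n_boot=n_boot, seed=seed,
        )
    return out


__all__ = [
    "Method",
    "METHOD_LABELS",
    "MREstimate",
    "InsufficientInstruments",
    "DegenerateInstrument",
    "to_or_ci",
    "wald_ratio",
    "ivw",
    "ivw_fixed_effect",
    "cochran_q_ivw",
    "egger",
    "weighted_quantile",
    "weighted_median",
    "mode_estimate",
    "all_estimates",
    "Z975",
]
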