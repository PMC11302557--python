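"""Synthetic exposure/outcome GWAS summary-statistic pairs with known ground truth.

The generator emulates a two-sample MR design: J variants with true exposure
effects b_x, an outcome built as ``causal_effect * b_x`` plus optional
per-variant horizontal pleiotropy (balanced or directional, with an optional
violation of the InSIDE condition), planted outliers, palindromic allele
pairs, and Gaussian sampling noise on both sides.  Every realized per-SNP
quantity is recorded so downstream assertions can compare estimates against
truth.

Sign convention: the reported effect allele is the exposure-increasing allele,
so true exposure effects are non-negative (|Normal| draws).  This mirrors the
common practice of orienting instruments to the trait-raising allele and keeps
directional pleiotropy identifiable by MR-Egger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .io import LDMatrix, SummaryStatRecord

#: Two-sided z threshold matching the instrument screen p < 1e-5.
RELEVANCE_Z = float(stats.norm.isf(1e-5 / 2))

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: Base-pair spacing between independent loci; far outside any clumping window.
_LOCUS_SPACING_BP = 50_000_000
#: Spacing between variants within one LD block; well inside any window.
_WITHIN_BLOCK_BP = 10_000


@dataclass
class TruthParams:
    """Generative parameters of one synthetic exposure/outcome pair.

    Defaults describe a strong-instrument null study: J=30 independent
    variants, no causal effect, no pleiotropy, exposure |z| far above the
    relevance screen.
    """

    J: int = 30
    causal_effect: float = 0.0
    bx_sd: float = 0.1
    se_x: float | Sequence[float] = 0.005
    se_y: float | Sequence[float] = 0.02
    invalid_fraction: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.05
    pleio_bx_corr: float = 0.0  # rho: alpha = rho*bx + noise; breaks InSIDE
    outlier_ids: Sequence[int] = field(default_factory=tuple)
    outlier_shift: float = 10.0  # in multiples of the local se_y
    palindrome_fraction: float = 0.0
    eaf_range: tuple[float, float] = (0.05, 0.95)
    n_exposure: int = 18_340
    n_outcome: int = 450_000
    ld_blocks: Sequence[tuple[int, float]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        for name in ("invalid_fraction", "palindrome_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("se_x", "se_y"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(arr < 0):
                raise ValueError(f"{name} must be >= 0 (0 = noise-free limit)")
            if arr.size not in (1, self.J):
                raise ValueError(f"{name} must be scalar or length J")
        lo, hi = self.eaf_range
        if not (0.01 <= lo < hi <= 0.99):
            raise ValueError("eaf_range must lie within (0.01, 0.99)")
        if self.ld_blocks is not None:
            if sum(b for b, _ in self.ld_blocks) != self.J:
                raise ValueError("ld_blocks sizes must sum to J")


@dataclass
class SyntheticPair:
    """A simulated exposure/outcome dataset plus its full generative truth."""

    exposure: list[SummaryStatRecord]
    outcome: list[SummaryStatRecord]
    truth: TruthParams
    bx_true: np.ndarray  # realized true exposure effects
    alpha: np.ndarray  # realized per-SNP pleiotropic effects (incl. outlier shifts)
    invalid_mask: np.ndarray  # True where pleiotropy was added
    palindromic_mask: np.ndarray

    def truth_dict(self) -> dict:
        d = asdict(self.truth)
        d["ld_blocks"] = list(map(list, self.truth.ld_blocks)) if self.truth.ld_blocks else None
        d["outlier_ids"] = list(self.truth.outlier_ids)
        d["bx_true"] = self.bx_true.tolist()
        d["alpha"] = self.alpha.tolist()
        d["invalid_mask"] = self.invalid_mask.astype(bool).tolist()
        d["palindromic_mask"] = self.palindromic_mask.astype(bool).tolist()
        return d


def _per_snp(value, J: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    return np.full(J, arr[0]) if arr.size == 1 else arr.copy()


def simulate_pair(truth: TruthParams) -> SyntheticPair:
    """Draw one exposure/outcome summary-statistic pair from ``truth``.

    True exposure effects are |Normal(0, bx_sd²)| draws, resampled until the
    expected |z| = b_x / se_x clears the relevance screen (p < 1e-5), mirroring
    a pre-selected instrument set.  Outcome effects are
    ``causal_effect * b_x + alpha`` with alpha = 0 for valid SNPs and
    Normal(pleio_mean, pleio_sd²) (plus the optional rho * b_x InSIDE-breaking
    term) for invalid ones; planted outliers get an extra ±outlier_shift·se_y.
    Observed betas add Normal sampling noise; p-values are two-sided normal.
    Fixing the seed makes the output bitwise reproducible.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    J = truth.J
    se_x = _per_snp(truth.se_x, J)
    se_y = _per_snp(truth.se_y, J)

    # True exposure effects: exposure-increasing orientation, relevance floor.
    # se of 0 is the noise-free limit: every draw clears the screen.
    bx_true = np.abs(rng.normal(0.0, truth.bx_sd, size=J))
    for _ in range(1000):
        with np.errstate(divide="ignore"):
            weak = bx_true / se_x < RELEVANCE_Z
        if not weak.any():
            break
        bx_true[weak] = np.abs(rng.normal(0.0, truth.bx_sd, size=int(weak.sum())))
    else:
        raise RuntimeError(
            "relevance floor unreachable: bx_sd too small relative to se_x"
        )

    n_invalid = int(round(truth.invalid_fraction * J))
    invalid = np.zeros(J, dtype=bool)
    invalid[rng.choice(J, size=n_invalid, replace=False)] = True
    alpha = np.zeros(J)
    alpha[invalid] = rng.normal(truth.pleio_mean, truth.pleio_sd, size=n_invalid)
    if truth.pleio_bx_corr != 0.0:
        alpha[invalid] += truth.pleio_bx_corr * bx_true[invalid]
    outliers = np.asarray(truth.outlier_ids, dtype=int)
    if outliers.size:
        signs = rng.choice([-1.0, 1.0], size=outliers.size)
        alpha[outliers] += signs * truth.outlier_shift * se_y[outliers]

    by_true = truth.causal_effect * bx_true + alpha
    bx_obs = bx_true + rng.normal(0.0, 1.0, size=J) * se_x
    by_obs = by_true + rng.normal(0.0, 1.0, size=J) * se_y

    # Alleles: palindromic pairs only for the requested fraction.
    n_pal = int(round(truth.palindrome_fraction * J))
    pal_mask = np.zeros(J, dtype=bool)
    pal_mask[rng.choice(J, size=n_pal, replace=False)] = True
    pairs = []
    for j in range(J):
        pool = _PALINDROMIC_PAIRS if pal_mask[j] else _NONPALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])
    eaf = rng.uniform(*truth.eaf_range, size=J)

    # Positions: LD blocks share a locus; independent SNPs sit far apart.
    positions = np.empty(J, dtype=int)
    if truth.ld_blocks:
        j = 0
        for k, (size, _) in enumerate(truth.ld_blocks):
            base = (k + 1) * _LOCUS_SPACING_BP
            for i in range(size):
                positions[j] = base + i * _WITHIN_BLOCK_BP
                j += 1
    else:
        positions[:] = (np.arange(J) + 1) * _LOCUS_SPACING_BP

    # Reported SEs stay strictly positive even in the noise-free limit so the
    # records satisfy the se > 0 invariant and inverse-variance weights exist.
    se_x_rep = np.maximum(se_x, 1e-8)
    se_y_rep = np.maximum(se_y, 1e-8)
    px = 2 * stats.norm.sf(np.abs(bx_obs) / se_x_rep)
    py = 2 * stats.norm.sf(np.abs(by_obs) / se_y_rep)

    exposure, outcome = [], []
    for j in range(J):
        ea, oa = pairs[j]
        common = dict(
            variant_id=f"rs{j + 1:06d}",
            effect_allele=ea,
            other_allele=oa,
            eaf=float(eaf[j]),
            chromosome="1",
            position=int(positions[j]),
        )
        exposure.append(
            SummaryStatRecord(
                beta=float(bx_obs[j]), se=float(se_x_rep[j]),
                pvalue=float(max(px[j], np.finfo(float).tiny)),
                n=truth.n_exposure, **common,
            )
        )
        outcome.append(
            SummaryStatRecord(
                beta=float(by_obs[j]), se=float(se_y_rep[j]),
                pvalue=float(max(py[j], np.finfo(float).tiny)),
                n=truth.n_outcome, **common,
            )
        )
    return SyntheticPair(
        exposure=exposure, outcome=outcome, truth=truth,
        bx_true=bx_true, alpha=alpha, invalid_mask=invalid,
        palindromic_mask=pal_mask,
    )


def simulate_ld(truth: TruthParams) -> LDMatrix:
    """Block-diagonal r² matrix matching ``truth.ld_blocks``."""
    if truth.ld_blocks is None:
        raise ValueError("truth.ld_blocks must be given")
    truth.validate()
    J = truth.J
    m = np.zeros((J, J))
    j = 0
    for size, r2 in truth.ld_blocks:
        m[j : j + size, j : j + size] = r2
        j += size
    np.fill_diagonal(m, 1.0)
    ids = tuple(f"rs{i + 1:06d}" for i in range(J))
    return LDMatrix(variant_ids=ids, r2=m)


def write_truth_json(pair: SyntheticPair, path: str | Path) -> None:
    Path(path).write_text(json.dumps(pair.truth_dict(), indent=1))


__all__ = [
    "TruthParams",
    "SyntheticPair",
    "simulate_pair",
    "simulate_ld",
    "write_truth_json",
    "RELEVANCE_Z",
]
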