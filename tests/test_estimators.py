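import numpy as np
import pytest

from tsmr.estimators import (
    DegenerateInstrument,
    InsufficientInstruments,
    Method,
    _wls_with_intercept,
    all_estimates,
    egger,
    ivw,
    ivw_fixed_effect,
    mode_estimate,
    to_or_ci,
    wald_ratio,
    weighted_median,
    weighted_quantile,
)
from tsmr.harmonize import harmonize
from tsmr.synth import TruthParams, simulate_pair

from conftest import make_snps


class TestWaldRatio:
    def test_arithmetic(self):
        snp = make_snps([0.1], [0.05], sy=0.1)[0]
        est = wald_ratio(snp)
        assert est.beta == pytest.approx(0.5) and est.se == pytest.approx(1.0)

    def test_zero_outcome_effect(self):
        assert wald_ratio(make_snps([0.1], [0.0])[0]).beta == 0.0

    def test_sign_symmetry(self):
        a = wald_ratio(make_snps([0.1], [0.05])[0])
        b = wald_ratio(make_snps([-0.1], [-0.05])[0])
        assert a.beta == b.beta and a.se == b.se

    def test_degenerate_instrument(self):
        with pytest.raises(DegenerateInstrument):
            wald_ratio(make_snps([0.0], [0.05])[0])


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        snps = make_snps([0.1], [0.05], sy=0.1)
        est = ivw(snps)
        wald = wald_ratio(snps[0])
        assert est.beta == wald.beta and est.se == wald.se

    def test_two_snp_closed_form(self):
        # Hand WLS: equal weights 1/sy^2-scaled, beta = 0.25, fixed se = 1/sqrt(200).
        snps = make_snps([0.1, 0.2], [0.02, 0.06], sy=[0.01, 0.02])
        est = ivw(snps)
        assert est.beta == pytest.approx(0.25)
        assert est.se_fixed == pytest.approx(1 / np.sqrt(200))

    def test_matches_meta_analysis_of_wald_ratios(self, rng):
        """IVW is the inverse-variance meta-analysis of per-SNP ratio estimates."""
        for _ in range(20):
            J = rng.integers(3, 12)
            snps = make_snps(
                rng.uniform(0.05, 0.3, J),
                rng.normal(0, 0.05, J),
                sy=rng.uniform(0.01, 0.1, J),
            )
            ests = [wald_ratio(s) for s in snps]
            w = np.array([1 / e.se**2 for e in ests])
            meta = np.sum(w * [e.beta for e in ests]) / np.sum(w)
            assert ivw(snps).beta == pytest.approx(meta, rel=1e-10)

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientInstruments):
            ivw([])

    def test_paper_style_report(self):
        # A published IVW row: beta = ln(1.354), se 0.121 -> OR/CI/p as printed.
        from tsmr.estimators import MREstimate

        est = MREstimate.from_beta_se(Method.IVW, 7, np.log(1.354), 0.121)
        assert round(est.or_, 3) == 1.354
        assert round(est.ci_low, 3) == 1.068 and round(est.ci_high, 3) == 1.716
        assert round(est.pvalue, 3) == 0.012


class TestEgger:
    def test_exact_fit_recovers_slope_and_zero_intercept(self):
        bx = np.array([0.1, 0.15, 0.2, 0.3])
        snps = make_snps(bx, 0.4 * bx)
        slope, intercept = egger(snps)
        assert slope.beta == pytest.approx(0.4)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_two_point_regression_unit(self):
        # Internal WLS on (0.1, 0.03), (0.2, 0.05): line through both.
        a, b, _, _, _ = _wls_with_intercept(
            np.array([0.1, 0.2]), np.array([0.03, 0.05]), np.ones(2)
        )
        assert b == pytest.approx(0.2) and a == pytest.approx(0.01)

    def test_forcing_intercept_zero_reproduces_fixed_ivw(self, rng):
        """Origin-constrained weighted regression equals fixed-effect IVW."""
        for _ in range(10):
            J = rng.integers(3, 10)
            bx = rng.uniform(0.05, 0.3, J)
            by = rng.normal(0, 0.05, J)
            sy = rng.uniform(0.01, 0.1, J)
            beta, _ = ivw_fixed_effect(bx, by, sy)
            # independent oracle: weighted lstsq through the origin
            sw = 1 / sy
            oracle = np.linalg.lstsq((bx * sw)[:, None], by * sw, rcond=None)[0][0]
            assert beta == pytest.approx(oracle, rel=1e-10)

    def test_intercept_recovers_directional_pleiotropy(self):
        """Mean intercept across replicates tracks the planted pleiotropy mean."""
        ints = []
        for i in range(200):
            t = TruthParams(
                J=50, causal_effect=0.2, invalid_fraction=1.0,
                pleio_mean=0.05, pleio_sd=0.02, seed=40_000 + i,
            )
            pair = simulate_pair(t)
            snps, _ = harmonize(pair.exposure, pair.outcome)
            ints.append(egger(snps)[1].beta)
        ints = np.array(ints)
        mcse = ints.std(ddof=1) / np.sqrt(len(ints))
        assert abs(ints.mean() - 0.05) < 3 * mcse

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstruments):
            egger(make_snps([0.1, 0.2], [0.02, 0.05]))


class TestWeightedMedian:
    def test_equal_weight_interpolation(self):
        # Ratios {0.1, 0.2, 0.3}: midpoint weights {1/6, 1/2, 5/6} -> 0.2 at 0.5.
        assert weighted_quantile(np.array([0.1, 0.2, 0.3]), np.ones(3)) == pytest.approx(0.2)

    def test_constant_ratios_return_constant(self):
        snps = make_snps([0.1, 0.2, 0.4], [0.05, 0.1, 0.2])
        est = weighted_median(snps, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_seeded_bootstrap_reproducible(self):
        snps = make_snps([0.1, 0.2, 0.3], [0.03, 0.05, 0.12])
        a = weighted_median(snps, n_boot=200, seed=5)
        b = weighted_median(snps, n_boot=200, seed=5)
        c = weighted_median(snps, n_boot=200, seed=6)
        assert a.se == b.se and a.se != c.se

    def test_duplicate_snp_with_halved_weight_invariant(self):
        # Splitting an off-median SNP's weight across two copies leaves the
        # interpolated median unchanged (the plotting positions of all other
        # points are preserved).
        theta = np.array([0.1, 0.25, 0.4])
        w = np.array([1.0, 2.0, 1.5])
        base = weighted_quantile(theta, w)
        dup = weighted_quantile(
            np.array([0.1, 0.1, 0.25, 0.4]), np.array([0.5, 0.5, 2.0, 1.5])
        )
        assert dup == pytest.approx(base)

    def test_robust_to_minority_contamination(self):
        """With <=50% invalid weight (balanced pleiotropy), the estimate stays
        centered on the causal effect at large J, unlike IVW under directional
        contamination."""
        wm, iv = [], []
        for i in range(60):
            t = TruthParams(
                J=200, causal_effect=0.4, invalid_fraction=0.4,
                pleio_mean=0.0, pleio_sd=0.1, seed=60_000 + i,
            )
            pair = simulate_pair(t)
            snps, _ = harmonize(pair.exposure, pair.outcome)
            wm.append(weighted_median(snps, n_boot=30, seed=i).beta)
        wm = np.array(wm)
        mcse = wm.std(ddof=1) / np.sqrt(len(wm))
        assert abs(wm.mean() - 0.4) < 3 * mcse

    def test_less_biased_than_ivw_under_directional_contamination(self):
        wm, iv = [], []
        for i in range(30):
            t = TruthParams(
                J=200, causal_effect=0.4, invalid_fraction=0.3,
                pleio_mean=0.1, pleio_sd=0.05, seed=61_000 + i,
            )
            pair = simulate_pair(t)
            snps, _ = harmonize(pair.exposure, pair.outcome)
            wm.append(weighted_median(snps, n_boot=30, seed=i).beta)
            iv.append(ivw(snps).beta)
        assert abs(np.mean(wm) - 0.4) < 0.5 * abs(np.mean(iv) - 0.4)


class TestMode:
    def test_identical_ratios(self):
        snps = make_snps([0.1, 0.2, 0.3], [0.07, 0.14, 0.21])
        est = mode_estimate(snps, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.7)

    def test_majority_cluster_wins(self):
        snps = make_snps([0.1, 0.1, 0.1, 0.1], [0.05, 0.0501, 0.0499, 0.2])
        est = mode_estimate(snps, weighted=False, bandwidth_factor=0.5, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_weighted_equals_simple_with_equal_weights(self):
        snps = make_snps([0.1, 0.1, 0.1, 0.1], [0.03, 0.05, 0.06, 0.09])
        simple = mode_estimate(snps, weighted=False, n_boot=10, seed=1)
        weighted = mode_estimate(snps, weighted=True, n_boot=10, seed=1)
        assert simple.beta == pytest.approx(weighted.beta)

    def test_grid_argmax_against_direct_density(self):
        snps = make_snps([0.1, 0.12, 0.2, 0.15], [0.03, 0.05, 0.02, 0.06])
        est = mode_estimate(snps, weighted=True, n_boot=10, seed=0)
        theta = np.array([s.by / s.bx for s in snps])
        w = np.array([s.bx**2 / s.sy**2 for s in snps])
        w = w / w.sum()
        sd = theta.std(ddof=1)
        mad = 1.4826 * np.median(np.abs(theta - np.median(theta)))
        h = 0.9 * min(sd, mad) * len(theta) ** -0.2
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
        dens = np.array(
            [np.sum(w * np.exp(-0.5 * ((g - theta) / h) ** 2)) for g in grid]
        )
        assert est.beta == pytest.approx(grid[np.argmax(dens)])


class TestORConversion:
    @pytest.mark.parametrize(
        "or_printed,se,lo,hi",
        [(1.354, 0.121, 1.068, 1.716), (0.731, 0.139, 0.557, 0.960)],
    )
    def test_published_rows_reconstruct(self, or_printed, se, lo, hi):
        or_, ci_low, ci_high = to_or_ci(np.log(or_printed), se)
        assert round(ci_low, 3) == lo and round(ci_high, 3) == hi

    def test_zero_beta_zero_se(self):
        assert to_or_ci(0.0, 0.0) == (1.0, 1.0, 1.0)


def test_scale_equivariance():
    """Scaling every outcome effect and SE by k scales every estimate and SE by k."""
    snps = make_snps([0.1, 0.2, 0.15, 0.3], [0.03, 0.05, 0.02, 0.09], sy=0.04)
    k = 2.5
    scaled = make_snps([0.1, 0.2, 0.15, 0.3], np.array([0.03, 0.05, 0.02, 0.09]) * k, sy=0.04 * k)
    base = all_estimates(snps, n_boot=100, seed=3)
    scl = all_estimates(scaled, n_boot=100, seed=3)
    for method in base:
        assert scl[method].beta == pytest.approx(k * base[method].beta, rel=1e-6)
        assert scl[method].se == pytest.approx(k * base[method].se, rel=1e-6)
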