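"""Correlated meta-analysis: correlation estimation and p-value combination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiocma.assoc import genomic_lambda
from pleiocma.cma import (
    ScanCorrelation,
    brown_combine,
    brown_combine_many,
    cma_scan,
    dichotomize_scans,
    folded_normal_correlation,
    scan_correlation,
    stouffer_combine,
    tetrachoric,
    tetrachoric_cosine,
)


def scan_frame(p, snp=None):
    p = np.asarray(p, dtype=float)
    return pd.DataFrame({
        "SNP": snp if snp is not None else [f"v{i}" for i in range(p.size)],
        "CHR": 1,
        "POS": np.arange(1, p.size + 1) * 1000,
        "P": p,
    })


class TestDichotomize:
    def test_identical_scans_fully_concordant(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=1000)
        a, b, c, d = dichotomize_scans(p, p, trim=0)
        assert b == 0 and c == 0 and a + d == 1000

    def test_independent_scans_quarter_cells(self):
        rng = np.random.default_rng(1)
        m = 40_000
        a, b, c, d = dichotomize_scans(rng.uniform(size=m), rng.uniform(size=m), trim=0)
        for cell in (a, b, c, d):
            assert cell == pytest.approx(m / 4, rel=0.05)

    def test_trim_zero_conserves_counts(self):
        rng = np.random.default_rng(2)
        m = 500
        counts = dichotomize_scans(rng.uniform(size=m), rng.uniform(size=m), trim=0)
        assert sum(counts) == m

    def test_trim_removes_significant_markers(self):
        p1 = np.array([1e-6, 0.3, 0.7])
        p2 = np.array([0.2, 0.4, 0.8])
        assert sum(dichotomize_scans(p1, p2, trim=1e-4)) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_scans(np.array([]), np.array([]))


class TestTetrachoric:
    def test_independence_gives_zero(self):
        assert tetrachoric(250, 250, 250, 250) == pytest.approx(0.0, abs=1e-6)

    def test_perfect_association_capped(self):
        assert tetrachoric(500, 0, 0, 500) == pytest.approx(0.999)
        assert tetrachoric(0, 500, 500, 0) == pytest.approx(-0.999)

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.5, 0.8])
    def test_recovery_from_median_dichotomized_normal(self, rho):
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=100_000)
        x, y = z[:, 0] < 0, z[:, 1] < 0
        a = int((x & y).sum()); b = int((x & ~y).sum())
        c = int((~x & y).sum()); d = int((~x & ~y).sum())
        assert tetrachoric(a, b, c, d) == pytest.approx(rho, abs=0.02)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            tetrachoric(0, 0, 10, 10)

    def test_cosine_approximation_close_to_ml(self):
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=50_000)
        x, y = z[:, 0] < 0, z[:, 1] < 0
        a = int((x & y).sum()); b = int((x & ~y).sum())
        c = int((~x & y).sum()); d = int((~x & ~y).sum())
        assert tetrachoric_cosine(a, b, c, d) == pytest.approx(0.5, abs=0.05)


class TestFoldedCorrelation:
    @pytest.mark.parametrize("rho", [0.25, 0.5, 0.7, 0.9])
    def test_recovers_z_correlation_from_two_sided_p(self, rho):
        rng = np.random.default_rng(11)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=200_000)
        P = 2 * stats.norm.sf(np.abs(z))
        counts = dichotomize_scans(P[:, 0], P[:, 1], trim=0)
        assert folded_normal_correlation(*counts) == pytest.approx(rho, abs=0.02)

    def test_sign_of_latent_correlation_is_folded(self):
        rng = np.random.default_rng(12)
        z = rng.multivariate_normal([0, 0], [[1, -0.6], [-0.6, 1]], size=100_000)
        P = 2 * stats.norm.sf(np.abs(z))
        counts = dichotomize_scans(P[:, 0], P[:, 1], trim=0)
        assert folded_normal_correlation(*counts) == pytest.approx(0.6, abs=0.03)


class TestBrown:
    def test_independent_equals_fisher(self):
        rec = brown_combine([0.05, 0.05], np.eye(2))
        fisher = stats.chi2.sf(rec.statistic, 4)
        assert rec.p_cma == pytest.approx(fisher, rel=1e-12)
        assert rec.p_cma == pytest.approx(0.0175, abs=2e-4)

    @pytest.mark.parametrize("q", [0.7, 0.05, 1e-4, 1e-9])
    def test_duplicate_scan_identity(self, q):
        rec = brown_combine([q, q], np.ones((2, 2)))
        assert rec.p_cma == pytest.approx(q, rel=1e-10)

    def test_matches_monte_carlo_at_intermediate_correlation(self):
        """Brown's scaled chi-square tail matches simulation of correlated
        one-sided chi-square pairs at rho = 0.5."""
        rho = 0.5
        rec = brown_combine([0.01, 0.01], np.array([[1, rho], [rho, 1]]))
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=1_000_000)
        T = (-2 * np.log(stats.norm.sf(z))).sum(axis=1)
        mc = (T >= rec.statistic).mean()
        assert rec.p_cma == pytest.approx(mc, rel=0.10)

    def test_monotone_in_correlation(self):
        p = [0.01, 0.001]
        vals = [brown_combine(p, np.array([[1, r], [r, 1]])).p_cma
                for r in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(x <= y + 1e-15 for x, y in zip(vals, vals[1:]))

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            brown_combine([0.0, 0.5], np.eye(2))
        brown_combine([1e-300, 1.0], np.eye(2))  # p = 1 allowed

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            brown_combine([0.1, 0.1], np.array([[1, 1.5], [1.5, 1]]))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(4)
        P = rng.uniform(1e-6, 1, size=(50, 3))
        R = np.array([[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1]])
        pv, c, f = brown_combine_many(P, R)
        for i in range(0, 50, 7):
            rec = brown_combine(P[i], R)
            assert pv[i] == pytest.approx(rec.p_cma, rel=1e-12)
            assert (c, f) == (pytest.approx(rec.scale), pytest.approx(rec.dof))


class TestStouffer:
    def test_duplicate_scan_identity(self):
        q = 0.02
        rec = stouffer_combine([q, q], [1, 1], np.ones((2, 2)))
        assert rec.p_cma == pytest.approx(q, rel=1e-10)

    def test_independent_normal_oracle(self):
        p = 2 * stats.norm.sf(1.96)
        rec = stouffer_combine([p, p], [1, 1], np.eye(2))
        assert rec.statistic == pytest.approx(2 * 1.96 / np.sqrt(2), rel=1e-6)
        assert rec.p_cma == pytest.approx(0.0056, abs=1e-4)

    def test_opposite_signs_cancel(self):
        rec = stouffer_combine([0.05, 0.05], [1, -1], np.eye(2))
        assert rec.statistic == pytest.approx(0.0)
        assert rec.p_cma == pytest.approx(1.0)


class TestScanCorrelation:
    def test_duplicated_scan_near_one(self):
        rng = np.random.default_rng(5)
        t = scan_frame(rng.uniform(size=3000))
        corr = scan_correlation({"s1": t, "s2": t.copy()})
        assert corr.rho[0, 1] >= 0.99

    def test_disjoint_null_scans_near_zero(self):
        rng = np.random.default_rng(6)
        m = 20_000
        t1 = scan_frame(2 * stats.norm.sf(np.abs(rng.standard_normal(m))))
        t2 = scan_frame(2 * stats.norm.sf(np.abs(rng.standard_normal(m))))
        corr = scan_correlation({"s1": t1, "s2": t2})
        assert abs(corr.rho[0, 1]) < 0.05

    def test_increases_with_sample_overlap(self):
        """Between-scan correlation rises with the shared-sample fraction
        when traits are residually correlated (r = 0.7)."""
        rng = np.random.default_rng(8)
        m = 30_000
        n = 400
        estimates = []
        for overlap in (0.0, 0.5, 1.0):
            n_shared = int(overlap * n)
            y = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], size=(m,))
            # z-statistics of two scans sharing a fraction of samples:
            # corr(z1, z2) = overlap * trait corr under the null
            z_shared = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], size=m)
            z_own = rng.standard_normal((m, 2))
            w = n_shared / n
            z = np.sqrt(w) * z_shared + np.sqrt(1 - w) * z_own
            t1 = scan_frame(2 * stats.norm.sf(np.abs(z[:, 0])))
            t2 = scan_frame(2 * stats.norm.sf(np.abs(z[:, 1])))
            estimates.append(scan_correlation({"a": t1, "b": t2}).rho[0, 1])
        assert estimates[0] < estimates[1] < estimates[2]
        assert estimates[2] == pytest.approx(0.7, abs=0.05)

    def test_requires_two_scans(self):
        with pytest.raises(ValueError):
            scan_correlation({"only": scan_frame([0.5, 0.5])})

    def test_counts_recorded_and_matrix_valid(self):
        rng = np.random.default_rng(9)
        scans = {s: scan_frame(rng.uniform(size=2000)) for s in ("a", "b", "c")}
        corr = scan_correlation(scans)
        assert set(corr.counts) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert np.allclose(np.diag(corr.rho), 1.0)
        assert np.linalg.eigvalsh(corr.rho).min() > -1e-9


class TestCmaScan:
    def make_scans(self, p_by_trait):
        m = len(next(iter(p_by_trait.values())))
        return {t: scan_frame(p, snp=[f"v{i}" for i in range(m)]) for t, p in p_by_trait.items()}

    def identity_corr(self, ids):
        return ScanCorrelation(scan_ids=list(ids), rho=np.eye(len(ids)), counts={})

    def test_ineligible_trait_excluded_from_headline(self):
        scans = self.make_scans({
            "eGFRcr": [1e-9, 0.9], "eGFRcys": [1e-6, 0.9], "sRAGE": [0.5, 0.9],
        })
        headline, long = cma_scan(scans, self.identity_corr(scans), eligibility_cut=0.01)
        assert len(headline) == 1
        assert headline["SUBSET"].iloc[0] == "eGFRcr_eGFRcys"
        assert set(long["SUBSET"]) == {"eGFRcr_eGFRcys"}

    def test_no_record_when_all_above_cut(self):
        scans = self.make_scans({"a": [0.02, 0.5], "b": [0.9, 0.3]})
        headline, long = cma_scan(scans, self.identity_corr(scans))
        assert headline.empty and long.empty

    def test_headline_minimizes_p_over_subsets(self):
        scans = self.make_scans({"a": [1e-8], "b": [1e-8], "c": [5e-3]})
        headline, long = cma_scan(scans, self.identity_corr(scans))
        assert len(long) == 4  # ab, ac, bc, abc
        assert headline["P_CMA"].iloc[0] == long["P_CMA"].min()

    def test_combined_signal_beats_each_scan(self):
        """A marker strong in two scans combines to a smaller p than either."""
        scans = self.make_scans({"a": [2.34e-4], "b": [2.34e-10]})
        headline, _ = cma_scan(scans, self.identity_corr(scans))
        assert headline["P_CMA"].iloc[0] < 2.34e-10

    def test_stouffer_combiner_available(self):
        scans = self.make_scans({"a": [1e-4], "b": [1e-4]})
        headline, _ = cma_scan(scans, self.identity_corr(scans), combiner="stouffer")
        assert headline["P_CMA"].iloc[0] < 1e-4


def test_null_cma_lambda_calibrated():
    """Combined p-values over correlated null scans keep lambda in [0.9, 1.1]."""
    rng = np.random.default_rng(10)
    m = 200_000
    C = np.array([[1, 0.7], [0.7, 1]])
    z = rng.multivariate_normal([0, 0], C, size=m)
    P = 2 * stats.norm.sf(np.abs(z))
    scans = {"cr": scan_frame(P[:, 0]), "cys": scan_frame(P[:, 1])}
    corr = scan_correlation(scans)
    p_cma, _, _ = brown_combine_many(P, corr.rho)
    assert 0.9 < genomic_lambda(p_cma) < 1.1
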