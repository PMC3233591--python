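"""Twin ACE decomposition: ML fits, profile intervals, liability machinery."""

import numpy as np
import pytest
from scipy import stats

from twinglyc.ace import (ACEModel, TwinCorrelations, compare_models,
                          concordance_from_correlation, fit_ace_continuous,
                          fit_ace_liability, orthant_probability,
                          tetrachoric_from_concordance,
                          threshold_from_prevalence, twin_correlation)
from twinglyc.ace import _deviance


def _fit(r_mz, r_dz, n_mz=218, n_dz=141, **kw):
    return fit_ace_continuous(r_mz=r_mz, r_dz=r_dz, n_mz=n_mz, n_dz=n_dz, **kw)


class TestTwinCorrelation:
    def test_identical_within_pairs(self, rng):
        v = rng.standard_normal(50)
        pairs = np.column_stack([v, v])
        zyg = np.array(["MZ"] * 25 + ["DZ"] * 25)
        corr = twin_correlation(pairs, zyg)
        assert corr.r_mz == pytest.approx(1.0)
        assert corr.r_dz == pytest.approx(1.0)

    def test_independent_members_near_zero(self, rng):
        pairs = rng.standard_normal((4000, 2))
        zyg = np.array(["MZ"] * 2000 + ["DZ"] * 2000)
        corr = twin_correlation(pairs, zyg)
        assert abs(corr.r_mz) < 0.05 and abs(corr.r_dz) < 0.05

    def test_double_entry_is_order_invariant(self, rng):
        pairs = rng.standard_normal((200, 2)) @ np.array([[1.0, 0.5], [0.0, 0.8]])
        zyg = np.array(["MZ"] * 100 + ["DZ"] * 100)
        a = twin_correlation(pairs, zyg)
        b = twin_correlation(pairs[:, ::-1], zyg)
        assert a.r_mz == pytest.approx(b.r_mz, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            twin_correlation(np.ones((3, 3)), np.array(["MZ"] * 3))
        with pytest.raises(ValueError):
            TwinCorrelations(r_mz=1.5, r_dz=0.2, n_mz_pairs=10, n_dz_pairs=10)


class TestContinuousFit:
    def test_no_familial_correlation_gives_pure_e(self):
        fit = _fit(0.0, 0.0)
        assert fit.a2_ == pytest.approx(0.0, abs=1e-6)
        assert fit.c2_ == pytest.approx(0.0, abs=1e-6)
        assert fit.e2_ == pytest.approx(1.0, abs=1e-6)

    def test_components_sum_to_one(self):
        for r_mz, r_dz in [(0.63, 0.42), (0.58, 0.18), (0.3, 0.25), (0.9, 0.5)]:
            fit = _fit(r_mz, r_dz)
            assert fit.a2_ + fit.c2_ + fit.e2_ == pytest.approx(1.0, abs=1e-8)
            assert min(fit.a2_, fit.c2_, fit.e2_) >= 0

    def test_interior_solution_matches_observed_correlations(self):
        # with both components interior the ML fit reproduces the group
        # correlations exactly: a2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ
        fit = _fit(0.63, 0.42)
        assert fit.a2_ == pytest.approx(2 * (0.63 - 0.42), abs=1e-5)
        assert fit.c2_ == pytest.approx(2 * 0.42 - 0.63, abs=1e-5)

    def test_rdz_larger_than_half_rmz_pushes_a2_to_boundary(self):
        fit = _fit(0.30, 0.40)  # rMZ < rDZ: no additive-genetic signal
        assert fit.a2_ == pytest.approx(0.0, abs=1e-5)

    def test_shared_environment_boundary(self):
        # rDZ well under half rMZ: c2 pinned at 0, as for insulin resistance
        fit = _fit(0.58, 0.18)
        assert fit.c2_ == pytest.approx(0.0, abs=1e-6)
        assert fit.a2_ == pytest.approx(0.57, abs=0.03)
        assert fit.ci95_["c2"][0] == 0.0

    def test_grid_oracle_never_beats_ml_fit(self):
        """Brute-force 0.01-step scan of the (a2, c2) simplex."""
        for r_mz, r_dz in [(0.63, 0.42), (0.58, 0.18), (0.71, 0.50), (0.2, 0.35)]:
            corr = TwinCorrelations(r_mz, r_dz, 218, 141)
            fit = fit_ace_continuous(corr, compute_ci=False)
            a = np.arange(0.0, 1.0001, 0.01)
            aa, cc = np.meshgrid(a, a)
            mask = aa + cc <= 1.0
            grid_min = min(_deviance(x, y, corr)
                           for x, y in zip(aa[mask], cc[mask]))
            assert fit.deviance_ <= grid_min + 1e-8

    def test_fit_from_raw_pairs_equals_fit_from_their_correlations(self, rng):
        cov_mz = np.array([[1.0, 0.6], [0.6, 1.0]])
        cov_dz = np.array([[1.0, 0.35], [0.35, 1.0]])
        pairs = np.vstack([
            rng.multivariate_normal([0, 0], cov_mz, size=500),
            rng.multivariate_normal([0, 0], cov_dz, size=400)])
        zyg = np.array(["MZ"] * 500 + ["DZ"] * 400)
        from_raw = ACEModel(compute_ci=False).fit(pairs, zyg)
        corr = twin_correlation(pairs, zyg)
        from_summary = fit_ace_continuous(corr, compute_ci=False)
        assert from_raw.a2_ == pytest.approx(from_summary.a2_, abs=1e-5)
        assert from_raw.c2_ == pytest.approx(from_summary.c2_, abs=1e-5)

    def test_falconer_agreement_in_the_interior(self):
        for r_mz, r_dz in [(0.6, 0.4), (0.5, 0.3), (0.7, 0.45)]:
            fit = _fit(r_mz, r_dz, n_mz=1000, n_dz=1000, compute_ci=False)
            assert fit.a2_ == pytest.approx(2 * (r_mz - r_dz), abs=0.02)


class TestProfileCI:
    def test_interval_brackets_estimate(self):
        fit = _fit(0.63, 0.42)
        for comp, est in (("a2", fit.a2_), ("c2", fit.c2_), ("e2", fit.e2_)):
            lo, hi = fit.ci95_[comp]
            assert 0.0 <= lo <= est <= hi <= 1.0

    def test_published_interval_for_fasting_glucose(self):
        # reported male FPG heritability interval is (0.19, 0.70)
        lo, hi = _fit(0.63, 0.42).ci95_["a2"]
        assert lo == pytest.approx(0.19, abs=0.06)
        assert hi == pytest.approx(0.70, abs=0.06)

    def test_boundary_component_reports_zero_lower_bound(self):
        fit = _fit(0.58, 0.18)
        assert fit.ci95_["c2"][0] == 0.0

    def test_endpoints_match_deviance_scan(self):
        """Bisection endpoints agree with a 0.001-step profile-deviance scan."""
        fit = _fit(0.63, 0.42)
        cut = fit.deviance_ + stats.chi2.ppf(0.95, 1)
        from twinglyc.ace import _profile
        grid = np.arange(0.0, 1.0005, 0.001)
        for comp in ("a2", "e2"):
            prof = np.array([_profile(comp, v, fit.corr_, "ACE") for v in grid])
            inside = grid[prof <= cut]
            lo, hi = fit.ci95_[comp]
            assert abs(lo - inside.min()) < 0.005
            assert abs(hi - inside.max()) < 0.005


class TestLiability:
    @pytest.mark.parametrize("prev, z", [(0.5, 0.0), (0.282, 0.577), (0.975, -1.96)])
    def test_threshold_from_prevalence(self, prev, z):
        assert threshold_from_prevalence(prev) == pytest.approx(z, abs=0.001)

    def test_threshold_rejects_out_of_range(self):
        for p in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                threshold_from_prevalence(p)

    def test_orthant_against_independent_double_integration(self):
        # oracle: scipy's bivariate normal CDF via inclusion-exclusion
        from scipy.stats import multivariate_normal
        for z in (0.0, 0.577, 1.2):
            for r in (0.0, 0.3, 0.7, -0.4):
                mvn = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]])
                oracle = mvn.cdf([-z, -z])  # P(X>z, Y>z) by symmetry
                assert orthant_probability(z, r) == pytest.approx(oracle, abs=5e-6)

    def test_independence_concordance_equals_prevalence(self):
        assert concordance_from_correlation(0.0, 0.282) == pytest.approx(0.282, abs=1e-9)
        assert tetrachoric_from_concordance(0.282, 0.282) == pytest.approx(0.0, abs=1e-6)

    def test_perfect_concordance_gives_unit_correlation(self):
        assert tetrachoric_from_concordance(1.0, 0.3) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("r", [0.0, 0.2, 0.5, 0.8, 0.95])
    @pytest.mark.parametrize("kind", ["probandwise", "pairwise"])
    def test_round_trip_identity(self, r, kind):
        c = concordance_from_correlation(r, 0.282, kind)
        assert tetrachoric_from_concordance(c, 0.282, kind) == pytest.approx(r, abs=1e-6)

    def test_subindependence_clamped_when_requested(self):
        with pytest.warns(UserWarning, match="clamped"):
            r = tetrachoric_from_concordance(0.10, 0.282, nonnegative=True)
        assert r == 0.0

    def test_concordance_at_prevalence_gives_pure_e(self):
        fit = fit_ace_liability(conc_mz=0.3, conc_dz=0.3, prevalence=0.3,
                                n_mz=218, n_dz=141)
        assert fit.e2_ == pytest.approx(1.0, abs=1e-4)

    def test_fit_from_raw_binary_pairs(self, rng):
        # generate liabilities with a2=0.5, c2=0.2, threshold at prevalence 0.3
        a2, c2, prev, n = 0.5, 0.2, 0.3, 20000
        thr = threshold_from_prevalence(prev)
        X, zyg = [], []
        for z, n_pairs in (("MZ", n), ("DZ", n)):
            rho = a2 + c2 if z == "MZ" else a2 / 2 + c2
            liab = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n_pairs)
            X.append((liab > thr).astype(float))
            zyg += [z] * n_pairs
        from twinglyc.ace import LiabilityACEModel
        fit = LiabilityACEModel(compute_ci=False).fit(np.vstack(X), np.array(zyg))
        assert fit.a2_ == pytest.approx(a2, abs=0.05)
        assert fit.c2_ == pytest.approx(c2, abs=0.05)


class TestModelComparison:
    @staticmethod
    def _all_fits(corr):
        return {m: ACEModel(model=m, compute_ci=False).fit_from_correlations(corr)
                for m in ("ACE", "AE", "CE", "E")}

    def test_nesting_monotonicity(self):
        corr = TwinCorrelations(0.63, 0.42, 218, 141)
        fits = self._all_fits(corr)
        assert fits["ACE"].deviance_ <= fits["AE"].deviance_ + 1e-9
        assert fits["AE"].deviance_ <= fits["E"].deviance_ + 1e-9
        assert fits["CE"].deviance_ <= fits["E"].deviance_ + 1e-9

    def test_refuses_mismatched_data(self):
        fits = self._all_fits(TwinCorrelations(0.63, 0.42, 218, 141))
        fits["AE"] = ACEModel(model="AE", compute_ci=False).fit_from_correlations(
            TwinCorrelations(0.5, 0.3, 100, 100))
        with pytest.raises(ValueError, match="identical data"):
            compare_models(fits)

    def test_ae_preferred_and_lrt_superuniform_when_c2_is_zero(self, rng):
        """200 cohorts simulated with c2 truly 0: AIC should prefer AE in the
        majority, and the boundary-mixture LRT p-value should reject at most
        ~5% of the time."""
        a2, n = 0.6, 500
        n_ae, n_reject = 0, 0
        reps = 200
        for _ in range(reps):
            X, zyg = [], []
            for z in ("MZ", "DZ"):
                rho = a2 if z == "MZ" else a2 / 2
                X.append(rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n))
                zyg += [z] * n
            corr = twin_correlation(np.vstack(X), np.array(zyg))
            fits = self._all_fits(corr)
            report = compare_models(fits)
            if report.loc[report["preferred"], "model"].iloc[0] == "AE":
                n_ae += 1
            p = report.set_index("model").loc["AE", "p_boundary"]
            if p < 0.05:
                n_reject += 1
        assert n_ae > reps / 2
        # super-uniform null: rejections at alpha=0.05 within binomial noise of 5%
        assert n_reject <= 0.05 * reps + 3 * np.sqrt(reps * 0.05 * 0.95)
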