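import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metaconf as mc
from metaconf.cohort import BetweenSubjectSD, posterior_confidence, simulate_trials
from metaconf.efficiency import (
    ConfidenceModelFit,
    EfficiencyError,
    PopulationConfidenceModel,
    Type1Fit,
    _eta_from_aucs,
    _weighted_auc,
    bivariate_normal_cdf,
    bootstrap_efficiency,
    confidence_bin_edges,
    confidence_likelihood,
    efficiency,
    efficiency_contrast,
    fit_confidence_model,
    fit_type1,
    reference_model,
)

from conftest import make_observer


def _trials_from_counts(yes_counts, totals, sid="a", task="detection"):
    rows = []
    for s, (k, n) in enumerate(zip(yes_counts, totals)):
        for i in range(n):
            resp = "yes" if i < k else "no"
            rows.append((sid, "control", task, s, resp, int((resp == "yes") == (s > 0)), 70.0))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "task", "strength", "response", "accuracy", "confidence"]
    )


class TestType1Fit:
    def test_recovery_with_many_trials_per_cell(self):
        obs = make_observer(mu=(0.9, 1.4, 1.8, 2.3), criterion=0.7, foil=0.0)
        rng = np.random.default_rng(0)
        sim = simulate_trials(obs, "detection", np.repeat(np.arange(5), 10_000), rng)
        sim["subject_id"] = "a"
        sim["group"] = "control"
        sim["task"] = "detection"
        fit = fit_type1(sim)
        assert abs(fit.c_hat - 0.7) < 0.05
        np.testing.assert_allclose(fit.mu_hat, obs.mu["detection"], atol=0.05)
        assert fit.foil_hat == 0.0

    def test_all_no_responder_is_boundary_flagged(self):
        fit = fit_type1(_trials_from_counts([0, 0, 0, 0, 0], [20] * 5))
        assert fit.boundary
        assert fit.c_hat > 1.5  # criterion pushed to the conservative edge

    def test_isotonic_tie_when_catch_matches_lowest_strength(self):
        fit = fit_type1(_trials_from_counts([5, 5, 10, 14, 18], [20] * 5))
        assert fit.mu_hat[0] == pytest.approx(fit.foil_hat, abs=1e-12)
        assert np.all(np.diff(fit.mu_hat) >= -1e-12)

    def test_isotonic_pooling_of_inverted_rates(self):
        fit = fit_type1(_trials_from_counts([4, 14, 10, 15, 18], [20] * 5))
        assert fit.mu_hat[0] == pytest.approx(fit.mu_hat[1])
        assert np.all(np.diff(fit.mu_hat) >= -1e-12)

    def test_missing_strength_cell_raises(self):
        df = _trials_from_counts([2, 10, 12, 15, 18], [20] * 5)
        with pytest.raises(EfficiencyError, match="strength 3"):
            fit_type1(df[df.strength != 3])


class TestBivariateNormal:
    @pytest.mark.parametrize("rho", [-0.95, -0.3, 0.0, 0.5, 0.9, 0.999999])
    def test_matches_scipy_reference(self, rho):
        rng = np.random.default_rng(abs(hash(rho)) % 2**31)
        for _ in range(20):
            h, k = rng.normal(0, 2, 2)
            ref = stats.multivariate_normal(
                mean=[0, 0], cov=[[1, rho], [rho, 1]]
            ).cdf([h, k])
            assert float(bivariate_normal_cdf(h, k, rho)) == pytest.approx(ref, abs=5e-7)

    def test_singular_correlation_limits(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            h, k = rng.normal(0, 2, 2)
            assert float(bivariate_normal_cdf(h, k, 1.0)) == pytest.approx(
                stats.norm.cdf(min(h, k)), abs=1e-12
            )
            assert float(bivariate_normal_cdf(h, k, -1.0)) == pytest.approx(
                max(0.0, stats.norm.cdf(h) + stats.norm.cdf(k) - 1), abs=1e-12
            )

    def test_axis_values(self):
        assert float(bivariate_normal_cdf(0, 0, 0.5)) == pytest.approx(
            0.25 + np.arcsin(0.5) / (2 * np.pi)
        )


class TestConfidenceLikelihood:
    def _fit(self):
        return Type1Fit("a", "detection", np.array([1.2, 1.5, 1.9, 2.2]), 0.8, 0.0, 0.0)

    def test_rows_normalize_for_random_parameters(self):
        rng = np.random.default_rng(1)
        edges = np.linspace(0, 100, 11)
        for _ in range(10):
            table = confidence_likelihood(
                self._fit(), rng.uniform(0, 3), rng.uniform(0, 1), edges
            )
            sums = np.nansum(table, axis=-1)
            defined = ~np.isnan(table[..., 0])
            np.testing.assert_allclose(sums[defined], 1.0, atol=1e-6)

    def test_high_certainty_mass_in_top_bins(self):
        t1 = Type1Fit("a", "detection", np.array([3.0, 3.0, 3.0, 3.0]), 0.0, 0.0, 0.0)
        table = confidence_likelihood(t1, 0.0, 0.0, np.linspace(0, 100, 11))
        assert table[4, 0, -2:].sum() > 0.9  # strength 4, response yes

    def test_agrees_with_monte_carlo_simulation(self):
        obs = make_observer(mu=(1.2, 1.5, 1.9, 2.2), criterion=0.8, sigma_c=0.8, alpha=0.3)
        edges = np.linspace(0, 100, 11)
        table = confidence_likelihood(self._fit(), 0.8, 0.3, edges)
        rng = np.random.default_rng(2)
        n = 300_000
        for s in (0, 3):
            sim = simulate_trials(obs, "detection", np.full(n, s), rng)
            for ri, resp in [(0, "yes"), (1, "no")]:
                sel = sim[sim.response == resp]
                if len(sel) < n * 0.02:
                    continue
                emp, _ = np.histogram(sel["confidence"], bins=edges)
                tv = 0.5 * np.abs(emp / emp.sum() - table[s, ri]).sum()
                assert tv < 0.012

    def test_invalid_parameters_rejected(self):
        with pytest.raises(EfficiencyError):
            confidence_likelihood(self._fit(), -0.5, 0.2, np.linspace(0, 100, 11))


class TestBinEdges:
    def test_deciles_cover_full_scale(self):
        rng = np.random.default_rng(0)
        conf = rng.uniform(0, 100, 5000)
        edges = confidence_bin_edges(conf)
        assert edges[0] == 0 and edges[-1] == 100
        assert len(edges) == 11

    def test_small_bins_are_merged(self):
        conf = np.concatenate([np.full(980, 99.5), np.linspace(0, 50, 20)])
        edges = confidence_bin_edges(conf)
        counts, _ = np.histogram(conf, bins=edges)
        assert (counts / counts.sum() >= 0.02).all() or len(edges) == 3


class TestEta:
    def test_weighted_auc_brute_force(self):
        vp, wp = np.array([1.0, 3.0, 3.0]), np.array([1.0, 2.0, 1.0])
        vn, wn = np.array([2.0, 3.0]), np.array([1.0, 1.0])
        # pairs: (1,2):0 (1,3):0 | (3,2):1 (3,3):.5 weights...
        brute = 0.0
        for v, w in zip(vp, wp):
            for u, x in zip(vn, wn):
                brute += w * x * ((v > u) + 0.5 * (v == u))
        brute /= wp.sum() * wn.sum()
        assert _weighted_auc(vp, wp, vn, wn) == pytest.approx(brute)

    def test_ideal_fit_gives_unit_efficiency(self):
        fits = [Type1Fit("a", "detection", np.array([1.2, 1.5, 1.9, 2.2]), 0.8, 0.0, 0.0)]
        fit = ConfidenceModelFit(0.0, 0.0, 10, tuple(np.linspace(0, 100, 11)), 0.0)
        est = efficiency(fits, fit)
        assert est.eta == pytest.approx(1.0, abs=1e-9)
        assert est.auc2_ideal > 0.5

    def test_eta_decreases_with_confidence_noise(self):
        ref = reference_model()
        ai = ref.auc2(0.0, 0.0)
        etas = [_eta_from_aucs(ref.auc2(s, 0.0), ai) for s in (0, 0.5, 1, 2, 4)]
        assert all(a > b for a, b in zip(etas, etas[1:]))

    def test_eta_rises_with_boost_and_exceeds_one_at_full_resampling(self):
        ref = reference_model()
        ai = ref.auc2(0.0, 0.0)
        rising = [_eta_from_aucs(ref.auc2(0.0, a), ai) for a in (0, 0.1, 0.2, 0.3, 0.4, 0.5)]
        assert all(a < b for a, b in zip(rising, rising[1:]))
        assert _eta_from_aucs(ref.auc2(0.0, 1.0), ai) > 1

    def test_first_order_invariance_of_reference_eta(self):
        """Pure first-order changes of the analyzed population leave the
        reference-evaluated eta untouched (it depends only on the fitted
        metacognitive parameters)."""
        fit = ConfidenceModelFit(1.0, 0.2, 10, tuple(np.linspace(0, 100, 11)), 0.0)
        base = [Type1Fit("a", "detection", np.array([1.2, 1.5, 1.9, 2.2]), 0.8, 0.0, 0.0)]
        shifted = [Type1Fit("a", "detection", np.array([0.4, 0.7, 1.1, 1.4]), 0.8, 0.0, 0.0)]
        assert efficiency(base, fit).eta == efficiency(shifted, fit).eta


class TestFitConfidenceModel:
    def test_ideal_population_fits_near_origin(self):
        """A noiseless population fits back to (sigma_c, alpha) ~ (0, 0).

        Near the ideal corner the likelihood is flat in sigma_c (its effect
        on the rating distribution is second order), so pinning the corner
        needs trial counts well above session scale; 12 subjects x 2000
        trials with known type-1 parameters isolate the layer under test.
        """
        import pandas as pd

        from metaconf.cohort import simulate_trials

        rng = np.random.default_rng(0)
        frames, fits = [], []
        for i in range(12):
            mu = np.array([1.2, 1.5, 1.9, 2.2]) + rng.normal(0, 0.3)
            c = rng.normal(0.84, 0.25)
            obs = make_observer(mu=mu, criterion=c, sigma_c=0.0, alpha=0.0, subject_id=f"s{i}")
            df = simulate_trials(obs, "detection", rng.integers(0, 5, 2000), rng)
            df["subject_id"] = f"s{i}"
            df["group"] = "control"
            df["task"] = "detection"
            frames.append(df)
            fits.append(Type1Fit(f"s{i}", "detection", mu, c, 0.0, 0.0))
        trials = pd.concat(frames, ignore_index=True)
        fit = fit_confidence_model(trials, fits, seed=0)
        assert fit.sigma_c_hat <= 0.1
        assert fit.alpha_hat <= 0.05

    def test_needs_two_subjects(self, homogeneous_population):
        trials, _ = homogeneous_population
        one = trials[trials.subject_id == trials.subject_id.iloc[0]]
        with pytest.raises(EfficiencyError, match="2 subjects"):
            fit_confidence_model(one, [fit_type1(one)], seed=0)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def boot(self, homogeneous_population):
        trials, _ = homogeneous_population
        return bootstrap_efficiency(trials, B=40, seed=5)

    def test_distribution_shape_and_ci(self, boot):
        assert len(boot.bootstrap_etas) == 40
        assert boot.ci95[0] <= np.median(boot.bootstrap_etas) <= boot.ci95[1]
        assert boot.task == "detection" and boot.group == "control"

    def test_same_seed_reproduces_distribution(self, homogeneous_population, boot):
        trials, _ = homogeneous_population
        again = bootstrap_efficiency(trials, B=40, seed=5)
        np.testing.assert_array_equal(again.bootstrap_etas, boot.bootstrap_etas)

    def test_contrast_self_is_zero_and_antisymmetric(self, boot):
        self_con = efficiency_contrast(boot, boot)
        assert self_con.mean_diff == 0
        assert np.all(self_con.diffs == 0)

    def test_mismatched_bootstrap_sizes_rejected(self, homogeneous_population, boot):
        trials, _ = homogeneous_population
        other = bootstrap_efficiency(trials, B=20, seed=6)
        with pytest.raises(EfficiencyError, match="sizes differ"):
            efficiency_contrast(boot, other)
        rev = efficiency_contrast(other, other)
        assert rev.mean_diff == 0
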