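import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtr

import metaconf as mc
from metaconf.cohort import (
    BetweenSubjectSD,
    confidence_from_evidence,
    posterior_confidence,
    sample_observer,
    simulate_trial,
    simulate_trials,
    truncated_normal_mean,
)

from conftest import make_observer


class TestSampleObserver:
    def test_zero_between_subject_sd_gives_group_means(self):
        spec = mc.GroupSpec(
            n_subjects=5, between_subject_sd=BetweenSubjectSD(0, 0, 0, 0, 0)
        )
        obs = sample_observer(spec, np.random.default_rng(0))
        assert obs.criterion == spec.criterion
        assert obs.sigma_c == spec.sigma_c_value
        assert obs.alpha == spec.alpha_value
        np.testing.assert_allclose(
            obs.mu["detection"], np.asarray(spec.mu_base)
        )
        assert obs.foil_mu["recollection"] == spec.foil_recollection

    def test_mu_shift_lowers_average_evidence(self):
        rng = np.random.default_rng(1)
        base = [sample_observer(mc.GroupSpec(n_subjects=5), rng) for _ in range(200)]
        rng = np.random.default_rng(1)
        shifted = [
            sample_observer(mc.GroupSpec(n_subjects=5, mu_shift=-0.8), rng)
            for _ in range(200)
        ]
        d = np.mean(
            [b.mu["detection"].mean() - s.mu["detection"].mean() for b, s in zip(base, shifted)]
        )
        assert d == pytest.approx(0.8, abs=1e-12)  # same rng stream, exact offset

    def test_sigma_c_sampling_matches_truncated_normal(self):
        spec = mc.GroupSpec(n_subjects=5, sigma_c_value=0.5)
        sd = spec.between_subject_sd.sigma_c
        rng = np.random.default_rng(2)
        draws = np.array([sample_observer(spec, rng).sigma_c for _ in range(10_000)])
        expect = truncated_normal_mean(0.5, sd)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expect) < 3 * se
        assert draws.min() >= 0


class TestSimulateTrial:
    def test_very_liberal_criterion_always_yes(self):
        obs = make_observer(criterion=-12.0)
        rng = np.random.default_rng(0)
        df = simulate_trials(obs, "detection", np.tile(np.arange(5), 200), rng)
        assert (df["response"] == "yes").all()
        assert df.loc[df.strength > 0, "accuracy"].eq(1).all()
        assert df.loc[df.strength == 0, "accuracy"].eq(0).all()

    def test_separable_stimuli_give_certain_correct_answers(self):
        obs = make_observer(mu=(5, 5, 5, 5), criterion=0.0, sigma_c=0.0, alpha=0.0)
        df = simulate_trials(obs, "detection", np.full(500, 3), np.random.default_rng(1))
        assert df["accuracy"].mean() == 1.0
        assert df["confidence"].median() > 99
        assert (df["confidence"] > 90).mean() > 0.95

    def test_yes_rates_match_phi_closed_forms(self):
        # d' = 1.5, c = 0.5: hit rate Phi(1.0), false-alarm rate Phi(-0.5)
        obs = make_observer(mu=(1.5, 1.5, 1.5, 1.5), criterion=0.5)
        rng = np.random.default_rng(2)
        n = 100_000
        sig = simulate_trials(obs, "detection", np.full(n, 1), rng)
        catch = simulate_trials(obs, "detection", np.zeros(n, int), rng)
        for frame, p in [(sig, ndtr(1.0)), (catch, ndtr(-0.5))]:
            rate = (frame["response"] == "yes").mean()
            assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_invalid_strength_rejected(self):
        obs = make_observer()
        with pytest.raises(ValueError, match="strength"):
            simulate_trial(obs, "detection", 5, np.random.default_rng(0))


class TestConfidenceFromEvidence:
    def test_limits_and_bounds(self):
        obs = make_observer(sigma_c=0.7, alpha=0.3)
        hi = confidence_from_evidence(30.0, "yes", obs, "detection")
        lo = confidence_from_evidence(-30.0, "yes", obs, "detection")
        assert hi > 99.999
        assert lo < 50
        z = np.linspace(-6, 6, 201)
        c = confidence_from_evidence(z, "no", obs, "detection")
        assert np.all((c >= 0) & (c <= 100))

    def test_nonfinite_evidence_rejected(self):
        obs = make_observer()
        with pytest.raises(ValueError, match="finite"):
            confidence_from_evidence(np.nan, "yes", obs, "detection")

    @pytest.mark.parametrize(
        "sigma_c,alpha", [(0.5, 0.0), (1.0, 0.3), (0.0, 0.6), (2.0, 0.1)]
    )
    def test_monotone_in_evidence(self, sigma_c, alpha):
        obs = make_observer(sigma_c=sigma_c, alpha=alpha)
        z = np.linspace(-8, 8, 400)
        cy = confidence_from_evidence(z, "yes", obs, "detection")
        cn = confidence_from_evidence(z, "no", obs, "detection")
        assert np.all(np.diff(cy) > -1e-9)
        assert np.all(np.diff(cn) < 1e-9)

    def test_matches_monte_carlo_posterior(self):
        """The rating equals the simulation-estimated P(correct | z, resp)."""
        obs = make_observer(mu=(1.0, 1.4, 1.8, 2.2), criterion=0.6, sigma_c=0.8, alpha=0.25)
        rng = np.random.default_rng(3)
        n = 10**6
        strengths = rng.integers(0, 5, n)
        means = obs.class_means("detection")[strengths]
        x = rng.normal(means, 1.0)
        x2 = rng.normal(means, 1.0)
        z = (1 - obs.alpha) * x + obs.alpha * x2 + rng.normal(0, obs.sigma_c, n)
        yes = x > obs.criterion
        correct = yes == (strengths > 0)
        for z0 in (-0.5, 0.8, 2.0):
            for resp, mask in [("yes", yes), ("no", ~yes)]:
                sel = mask & (np.abs(z - z0) < 0.05)
                if sel.sum() < 2000:
                    continue
                emp = correct[sel].mean()
                pred = float(confidence_from_evidence(z0, resp, obs, "detection")) / 100
                assert abs(emp - pred) < 0.02

    def test_calibration_of_ideal_observer(self):
        """With no confidence noise or boost the rating is the true
        posterior: accuracy within a confidence band matches the band."""
        obs = make_observer(sigma_c=0.0, alpha=0.0)
        rng = np.random.default_rng(4)
        df = simulate_trials(obs, "detection", rng.integers(0, 5, 200_000), rng)
        for p in (60, 75, 90):
            band = df[(df.confidence > p - 3) & (df.confidence < p + 3)]
            assert len(band) > 1000
            assert abs(band["accuracy"].mean() - p / 100) < 0.02


class TestSimulateCohort:
    def test_study_sized_cohort_shape(self):
        cfg = mc.default_cohort_config(master_seed=0)
        assert cfg.control.n_subjects == 36
        assert cfg.patient.n_subjects == 34

    def test_cohort_shape_and_determinism(self, small_cohort):
        trials, manifest = small_cohort
        assert len(trials) == 16 * 300
        assert trials.groupby("subject_id").size().eq(300).all()
        assert len(manifest) == 16
        cfg = mc.CohortConfig(
            control=mc.GroupSpec(n_subjects=8),
            patient=mc.GroupSpec(n_subjects=8, mu_shift=-0.3, foil_shift_recollection=0.6),
            master_seed=42,
        )
        again, _ = mc.simulate_cohort(cfg)
        assert again.to_csv(index=False) == trials.to_csv(index=False)

    def test_recollection_foil_shift_raises_false_alarms(self):
        """Planted foil shift reproduces the elevated false-recognition
        rate; closed form Phi(foil - c) is the oracle."""
        rng = np.random.default_rng(5)
        lo = make_observer(foil=0.25, criterion=0.84)
        hi = make_observer(foil=0.85, criterion=0.84)
        n = 10_000
        fa = {}
        for name, obs in [("lo", lo), ("hi", hi)]:
            df = simulate_trials(obs, "recollection", np.zeros(n, int), rng)
            fa[name] = (df["response"] == "yes").mean()
        assert fa["hi"] > fa["lo"]
        assert abs(fa["lo"] - ndtr(0.25 - 0.84)) < 0.02
        assert abs(fa["hi"] - ndtr(0.85 - 0.84)) < 0.02
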