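"""Likelihood, MLE fits, AIC bookkeeping and comparison statistics."""

import math

import numpy as np
import pandas as pd
import pytest

import kappafit as kf
from kappafit.fitting import PENALTY, comparison_table
from kappafit.models import production_log_density

from conftest import make_trials


class TestNegLogLikelihood:
    def test_single_trial_closed_form(self):
        params = kf.ClassicalParams({0.8: 1.0}, v0=0.2, wp=0.2)
        trials = make_trials([0.8], t_s=0.8, distance=0.0)
        expected = -math.log(1.0 / (0.2 * 0.8 * math.sqrt(2 * math.pi)))
        assert kf.neg_log_likelihood(trials, params) == pytest.approx(expected)

    def test_duplicated_dataset_doubles(self, exp1_classical_small, mean_classical):
        one = kf.neg_log_likelihood(exp1_classical_small, mean_classical)
        two = kf.neg_log_likelihood(
            pd.concat([exp1_classical_small] * 2, ignore_index=True), mean_classical
        )
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_matches_per_trial_loop(self, mean_classical):
        """Vectorised likelihood equals a naive per-trial summation."""
        rng = np.random.default_rng(17)
        n = 100
        t_s = rng.choice([0.8, 1.2], n)
        l = rng.choice(np.arange(17) * 1.414, n)
        t_p = rng.uniform(0.3, 2.5, n)
        trials = pd.DataFrame(
            {
                "subject_id": "S1",
                "experiment": "exp1",
                "sample_interval_s": t_s,
                "distance_deg": l,
                "location_deg": 0.0,
                "trial_index": np.arange(1, n + 1),
                "production_time_s": t_p,
            }
        )
        loop = 0.0
        for i in range(n):
            te = mean_classical.estimate(t_s[i], l[i])
            loop -= production_log_density(t_p[i], te, mean_classical.wp)
        assert kf.neg_log_likelihood(trials, mean_classical) == pytest.approx(loop, abs=1e-10)

    def test_invalid_parameters_return_penalty(self):
        params = kf.ClassicalParams({0.8: -10.0}, v0=0.2, wp=0.2)  # t_e < 0 at l = 0
        trials = make_trials([0.8], t_s=0.8, distance=0.0)
        assert kf.neg_log_likelihood(trials, params) == PENALTY


class TestAicBookkeeping:
    def test_aic_values(self):
        assert kf.aic(0.0, 4) == 8.0
        # positive log-likelihoods (densities > 1) give the published table's
        # negative AIC magnitudes
        assert kf.aic(329.0, 4) == pytest.approx(-650.0)

    def test_aic_additivity_over_conditions(self):
        l1, l2, k = -120.0, -80.0, 4
        assert kf.aic(l1 + l2, k) == pytest.approx(kf.aic(l1, k) + kf.aic(l2, k) - 2 * k)

    def test_delta_published_row(self):
        deltas = kf.delta_aic({"CM": -650.0, "SMV": -666.0, "SMG": -666.0})
        assert deltas == {"CM": 16.0, "SMV": 0.0, "SMG": 0.0}

    def test_delta_identical(self):
        assert set(kf.delta_aic({"a": 3.0, "b": 3.0}).values()) == {0.0}

    @pytest.mark.parametrize(
        "delta, label",
        [(0.0, "substantial"), (2.0, "substantial"), (3.0, "intermediate"),
         (5.0, "considerably less"), (8.5, "intermediate"), (12.0, "essentially none")],
    )
    def test_support_labels(self, delta, label):
        assert kf.support_label(delta) == label

    def test_comparison_table_has_one_zero_per_row(self, exp1_classical_small):
        fits = kf.fit_all_subjects(
            exp1_classical_small, models=("classical", "slowness_vernier"), n_restarts=2, seed=0
        )
        table = comparison_table(fits)
        for (_, _), grp in table.groupby(["subject_id", "condition"]):
            assert (grp["delta"] >= 0).all()
            assert np.isclose(grp["delta"].min(), 0.0)


class TestComparisonStats:
    def test_sign_test_all_positive(self):
        out = kf.sign_test(np.ones(9))
        assert out["p"] == pytest.approx(2 * 0.5**9)

    def test_sign_test_drops_ties(self):
        out = kf.sign_test([1.0, -1.0, 0.0, 0.0, 2.0])
        assert out["n"] == 3

    def test_published_aic_columns_sign_test(self):
        """The reported 0.8-s classical-vs-slowness AIC columns differ
        consistently across all nine subjects: exact p < 0.01."""
        t = kf.published.AIC_TABLE
        t08 = t[t["condition"] == 0.8]
        out = kf.sign_test(t08["CM_aic"].to_numpy(), t08["SMV_aic"].to_numpy())
        assert out["p"] == pytest.approx(0.00390625)

    def test_zero_mean_difference(self):
        out = kf.paired_t([1.0, 2.0, 3.0], [1.5, 1.5, 3.0])
        assert out["mean_diff"] == pytest.approx(0.0)
        assert out["t"] == pytest.approx(0.0)
        assert out["cohen_d"] == pytest.approx(0.0)

    def test_small_n_raises(self):
        with pytest.raises(ValueError):
            kf.one_sample_t([1.0])


class TestFitClassical:
    def test_noiseless_mean_structure_identified(self):
        """With vanishing production noise the fitted estimates reproduce
        every cell's t_e almost exactly."""
        truth = kf.ClassicalParams({0.8: 0.995, 1.2: 0.997}, v0=0.5, wp=1e-4)
        design = kf.DesignSpec(n_subjects=1, trials_per_cell=3, seed=2)
        df = kf.generate_exp1(design, kf.GeneratorSpec(model="classical", params=truth))
        res = kf.fit_classical(df, n_restarts=3, seed=1)
        for t_s in (0.8, 1.2):
            l = np.array(sorted(df["distance_deg"].unique()))
            assert np.allclose(res.params.estimate(t_s, l), truth.estimate(t_s, l), atol=1e-3)

    def test_weber_fraction_and_kappa_slope_recovered(self, exp1_classical_full, mean_classical):
        """The statistically identified quantities — w_p and the Kappa slope
        (1 − ω)/v0 — are recovered from a full-design synthetic subject."""
        corrected = kf.correct_bias(exp1_classical_full, kf.response_bias_table(exp1_classical_full))
        res = kf.fit_classical(corrected, n_restarts=5, seed=3)
        assert res.converged
        assert res.params.wp == pytest.approx(mean_classical.wp, rel=0.10)
        # the fitted slope should track the dataset's own empirical slope
        # (the MLE and OLS estimate the same mean structure)
        for t_s in (0.8, 1.2):
            grp = corrected[corrected["sample_interval_s"] == t_s]
            ols_slope = np.polyfit(grp["distance_deg"], grp["production_time_s"], 1)[0]
            fit_slope = (1 - res.params.omega_by_condition[t_s]) / res.params.v0
            assert fit_slope == pytest.approx(ols_slope, rel=0.25)

    def test_likelihood_at_optimum_beats_truth(self, exp1_classical_full, mean_classical):
        res = kf.fit_classical(exp1_classical_full, n_restarts=3, seed=3)
        assert -res.loglik <= kf.neg_log_likelihood(exp1_classical_full, mean_classical) + 1e-6

    def test_duplication_invariance(self, exp1_classical_small):
        a = kf.fit_classical(exp1_classical_small, n_restarts=2, seed=5)
        b = kf.fit_classical(
            pd.concat([exp1_classical_small] * 2, ignore_index=True), n_restarts=2, seed=5
        )
        assert b.params.wp == pytest.approx(a.params.wp, rel=1e-3)
        assert b.loglik == pytest.approx(2 * a.loglik, rel=1e-6)


@pytest.fixture(scope="module")
def slowness_data(mean_slowness):
    design = kf.DesignSpec(
        n_subjects=1, distances=tuple(1.414 * i for i in range(0, 17, 2)), trials_per_cell=20, seed=31
    )
    return kf.generate_exp1(design, kf.GeneratorSpec(model="slowness", params=mean_slowness))


class TestFitSlowness:
    def test_weber_fraction_recovered(self, slowness_data, mean_slowness):
        res = kf.fit_slowness(slowness_data, acuity="vernier", n_restarts=3, seed=2)
        assert res.params.wp == pytest.approx(mean_slowness.wp, rel=0.10)

    def test_vernier_and_grating_curves_nearly_identical(self, slowness_data, mean_slowness):
        """Either acuity law yields nearly the same fitted estimated-time
        curve (differences small against the production SD)."""
        rv = kf.fit_slowness(slowness_data, acuity="vernier", n_restarts=3, seed=2)
        rg = kf.fit_slowness(slowness_data, acuity="grating", n_restarts=3, seed=2)
        l = np.array(sorted(slowness_data["distance_deg"].unique()))
        for t_s in (0.8, 1.2):
            te_v = np.atleast_1d(rv.params.estimate(t_s, l))
            te_g = np.atleast_1d(rg.params.estimate(t_s, l))
            sd = mean_slowness.wp * t_s
            assert np.max(np.abs(te_v - te_g)) < 0.25 * sd

    def test_no_illusion_limit(self):
        truth = kf.SlownessParams({0.8: 0.01, 1.2: 0.02}, sigma_v=1e4, wp=0.15)
        design = kf.DesignSpec(n_subjects=1, distances=(0.0, 5.656, 11.312, 22.624), trials_per_cell=150, seed=3)
        df = kf.generate_exp1(design, kf.GeneratorSpec(model="slowness", params=truth))
        res = kf.fit_slowness(df, n_restarts=3, seed=4)
        l = np.array([0.0, 5.656, 11.312, 22.624])
        # any fitted illusion must stay within a few per-cell SEs of zero
        cell_se = 0.15 * 1.2 / np.sqrt(design.trials_per_cell)
        for t_s in (0.8, 1.2):
            assert np.allclose(np.atleast_1d(res.params.estimate(t_s, l)), t_s, atol=3 * cell_se)


class TestFitWithBias:
    def test_bias_recovered(self):
        truth = kf.ClassicalParams({0.8: 0.95, 1.2: 0.95}, v0=1.0, wp=0.15)
        gen = kf.GeneratorSpec(model="classical", params=truth, bias_by_condition={0.8: 0.15, 1.2: 0.15})
        df = kf.generate_exp1(kf.DesignSpec(n_subjects=1, seed=8), gen)
        res = kf.fit_with_bias(df, model="classical", n_restarts=5, seed=3)
        for t_s in (0.8, 1.2):
            assert res.params.bias_by_condition[t_s] == pytest.approx(0.15, abs=0.05)

    def test_degenerate_omega_flagged_not_rejected(self):
        """A generator outside the standard parameter range (ω > 1) drives
        the unconstrained fit to ω ≥ 1, which is flagged, not discarded."""
        truth = kf.ClassicalParams({0.8: 1.05, 1.2: 1.05}, v0=1.0, wp=0.08)
        gen = kf.GeneratorSpec(model="classical", params=truth)
        design = kf.DesignSpec(n_subjects=1, distances=(0.0, 2.828, 5.656, 8.484), trials_per_cell=40, seed=9)
        df = kf.generate_exp1(design, gen)
        res = kf.fit_with_bias(df, model="classical", n_restarts=5, seed=5)
        assert res.degenerate
        assert any(w >= 1.0 for w in res.params.omega_by_condition.values())

    def test_zero_bias_data_prefer_four_parameter_fit(self, mean_classical):
        """Without a true bias, the 6-parameter variant's extra parameters
        cost more AIC than they buy in fit, in most replicates."""
        design_distances = tuple(1.414 * i for i in range(0, 17, 4))
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            design = kf.DesignSpec(n_subjects=1, distances=design_distances, trials_per_cell=10, seed=seed)
            df = kf.generate_exp1(design, kf.GeneratorSpec(model="classical", params=mean_classical))
            corrected = kf.correct_bias(df, kf.response_bias_table(df))
            aic4 = kf.fit_classical(corrected, n_restarts=2, seed=seed).aic_total
            aic6 = kf.fit_with_bias(df, model="classical", n_restarts=2, seed=seed).aic_total
            wins += aic6 >= aic4
        assert wins > n_rep / 2
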