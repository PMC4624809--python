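"""Wiener first-passage density, DDM likelihood, hierarchical fit and DIC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from accumaint import _wfpt
from accumaint.design import ExperimentDesign
from accumaint.ddm import (
    DDMModelSpec,
    MCMCConfig,
    ddm_loglik,
    dic,
    fit_hddm,
    posterior_predictive,
    wfpt_density,
)
from accumaint.posterior import group_chain, prob_greater
from accumaint.synthetic_data import (
    GenParamsDDM,
    default_ddm_params,
    sample_subject_ddm_params,
    simulate_ddm_dataset,
)
from conftest import flat_ddm_params


def p_lower(v, a, z_rel=0.5):
    """Closed-form lower-boundary absorption probability (s = 1)."""
    if v == 0:
        return 1.0 - z_rel
    return (math.exp(-2 * v * a * z_rel) - math.exp(-2 * v * a)) / (1 - math.exp(-2 * v * a))


class TestWfptDensity:
    @pytest.mark.parametrize(
        "v,a,z_rel",
        [(0.0, 2.0, 0.5), (1.0, 2.0, 0.5), (0.5, 1.5, 0.3), (2.0, 1.0, 0.5),
         (1.0, 2.5, 0.7), (-1.0, 1.5, 0.5), (0.6, 1.5, 0.5), (2.2, 1.5, 0.5), (1.5, 3.0, 0.4)],
    )
    def test_integrates_to_hit_probability(self, v, a, z_rel):
        mass = quad(lambda t: wfpt_density(t, v, a, z_rel), 1e-6, 60, limit=300)[0]
        assert mass == pytest.approx(p_lower(v, a, z_rel), abs=1e-3)

    def test_symmetric_case_splits_mass(self):
        mass = quad(lambda t: wfpt_density(t, 0.0, 2.0, 0.5), 1e-6, 80, limit=300)[0]
        assert mass == pytest.approx(0.5, abs=1e-4)

    def test_drifted_lower_mass(self):
        mass = quad(lambda t: wfpt_density(t, 1.0, 2.0, 0.5), 1e-6, 60, limit=300)[0]
        assert mass == pytest.approx(0.1192, abs=1e-4)

    def test_small_and_large_time_series_agree(self):
        """Force each representation by the error target and compare on a
        time range where both are usable."""
        for t in np.linspace(0.2, 2.0, 25):
            tt = t / 4.0  # a = 2
            small = _wfpt.wfpt_series(tt, 0.5, 1e-30)  # huge K -> both series exact
            loose = _wfpt.wfpt_series(tt, 0.5, 1e-7)
            assert loose == pytest.approx(small, abs=1e-6)

    def test_matches_simulation_histogram(self):
        """Density against an Euler-Maruyama first-passage histogram."""
        v, a = 1.0, 2.0
        design = ExperimentDesign(n_subjects=1, trials_per_run=200_000, runs=("RT",), stimulus_window_s=8.0)
        df = simulate_ddm_dataset(design, flat_ddm_params(v=v, a=a, t_nd=0.0), seed=17, dt=0.0005)
        dec = df.loc[df["correct"], "rt"].to_numpy()  # upper boundary
        assert dec.size > 0
        width = 0.01
        for t0 in (0.3, 0.5, 0.8, 1.2):
            frac = np.mean(
                (df["rt"] >= t0 - width / 2) & (df["rt"] < t0 + width / 2) & df["correct"]
            )
            dens = wfpt_density(t0, v, a, boundary="upper") * width
            se = np.sqrt(dens * (1 - dens) / len(df))
            assert abs(frac - dens) < 3 * se + 1e-5

    def test_zero_time_zero_density(self):
        assert wfpt_density(-0.1, 1.0, 2.0) == 0.0

    def test_invalid_boundary_rejected(self):
        with pytest.raises(ValueError):
            wfpt_density(0.5, 1.0, -2.0)


@pytest.fixture(scope="module")
def sim_trials():
    design = ExperimentDesign(n_subjects=1, trials_per_run=2000, runs=("RT",), stimulus_window_s=6.0)
    return simulate_ddm_dataset(design, flat_ddm_params(v=1.2, a=1.8), seed=31)


class TestDdmLoglik:

    def test_no_variability_reduces_to_plain_wfpt(self, sim_trials):
        t = sim_trials[sim_trials["choice"] != "missed"].head(50)
        drift = {l: 1.2 for l in (1, 2, 3, 4)}
        bound = {l: 1.8 for l in (1, 2, 3, 4)}
        ll = ddm_loglik(t, drift, bound, t_nd=0.3, sv=0.0, st=0.0)
        manual = sum(
            np.log(
                wfpt_density(
                    row.rt - 0.3, 1.2, 1.8,
                    boundary="upper" if row.correct else "lower",
                )
            )
            for row in t.itertuples()
        )
        assert ll == pytest.approx(manual, rel=1e-10)

    def test_profile_peaks_at_generating_drift(self, sim_trials):
        bound = {l: 1.8 for l in (1, 2, 3, 4)}
        lls = [
            ddm_loglik(sim_trials, {l: v for l in (1, 2, 3, 4)}, bound, t_nd=0.3)
            for v in (0.4, 0.8, 1.2, 1.6, 2.0)
        ]
        assert np.argmax(lls) == 2
        assert lls[0] < lls[1] < lls[2] > lls[3] > lls[4]

    def test_empty_trials_zero(self):
        empty = pd.DataFrame(columns=["condition", "choice", "rt", "correct", "coherence_level"])
        assert ddm_loglik(empty, {}, {}, 0.3) == 0.0

    def test_rt_below_nondecision_time_is_minus_inf(self, sim_trials):
        t = sim_trials[sim_trials["choice"] != "missed"].head(5)
        assert ddm_loglik(t, {l: 1.2 for l in (1, 2, 3, 4)},
                          {l: 1.8 for l in (1, 2, 3, 4)}, t_nd=10.0) == -np.inf


@pytest.fixture(scope="module")
def recovery_fit():
    """Small but uncensored hierarchical recovery setup (fit once, checked
    by several tests)."""
    design = ExperimentDesign(n_subjects=8, trials_per_run=240, runs=("RT",), stimulus_window_s=3.0)
    group = default_ddm_params()
    params = sample_subject_ddm_params(group, 8, seed=11)
    trials = simulate_ddm_dataset(design, params, seed=1)
    post = fit_hddm(trials, "m1", MCMCConfig(n_chains=3, n_samples=2000, n_burn=1000), seed=5)
    return trials, post


class TestFitHddm:
    def test_drift_ordering_recovered(self, recovery_fit):
        _, post = recovery_fit
        means = [post.chains.pooled(f"mu_v(level{l})").mean() for l in (1, 2, 3, 4)]
        assert means[0] > means[2] and means[1] > means[3]
        easy = group_chain([post.chains.pooled("mu_v(level1)"), post.chains.pooled("mu_v(level2)")])
        hard = group_chain([post.chains.pooled("mu_v(level3)"), post.chains.pooled("mu_v(level4)")])
        assert prob_greater(easy, hard) == 1.0

    def test_boundary_recovered_within_ten_percent(self, recovery_fit):
        _, post = recovery_fit
        for l in (1, 2, 3, 4):
            assert 1.35 <= post.chains.pooled(f"a_group(level{l})").mean() <= 1.65

    def test_nondecision_time_recovered(self, recovery_fit):
        _, post = recovery_fit
        assert post.chains.pooled("t_group").mean() == pytest.approx(0.3, abs=0.05)

    def test_determinism(self, recovery_fit):
        trials, post = recovery_fit
        again = fit_hddm(trials, "m1", MCMCConfig(n_chains=2, n_samples=50, n_burn=50), seed=5)
        third = fit_hddm(trials, "m1", MCMCConfig(n_chains=2, n_samples=50, n_burn=50), seed=5)
        for name in again.chains.names():
            assert np.array_equal(again.chains[name], third.chains[name])

    def test_dr_trials_rejected(self, recovery_fit):
        trials, _ = recovery_fit
        bad = trials.copy()
        bad.loc[bad.index[:10], "condition"] = "DR"
        with pytest.raises(ValueError, match="delayed-response"):
            fit_hddm(bad, "m1", MCMCConfig(1, 10, 10), seed=0)

    def test_single_subject_rejected(self, recovery_fit):
        trials, _ = recovery_fit
        solo = trials[trials["subject"] == 1]
        with pytest.raises(ValueError, match="2 subjects"):
            fit_hddm(solo, "m1", MCMCConfig(1, 10, 10), seed=0)

    def test_invalid_model_name_rejected(self):
        with pytest.raises(ValueError):
            DDMModelSpec("m5")


class TestDic:
    def test_identical_posterior_identical_dic(self, recovery_fit):
        trials, post = recovery_fit
        r1 = dic(post, trials)
        r2 = dic(post, trials)
        assert r1 == r2
        assert r1.dic == pytest.approx(r1.mean_deviance + r1.p_d)

    def test_effective_parameters_positive(self, recovery_fit):
        trials, post = recovery_fit
        assert dic(post, trials).p_d > 0

    def test_too_few_samples_rejected(self, recovery_fit):
        trials, post = recovery_fit
        import dataclasses

        small = dataclasses.replace(post, deviance=post.deviance[:, :10])
        with pytest.raises(ValueError):
            dic(small, trials)


class TestPosteriorPredictive:
    def test_zero_draws_empty(self, recovery_fit, default_design):
        _, post = recovery_fit
        assert len(posterior_predictive(post, default_design, n_draws=0)) == 0

    def test_replicates_accuracy_and_quantiles(self, recovery_fit):
        trials, post = recovery_fit
        design = ExperimentDesign(stimulus_window_s=3.0)  # matches the fitted data's window
        pred = posterior_predictive(post, design, n_draws=40, seed=3, trials_per_level=30)
        assert (pred.loc[~pred["correct"], "rt"] < 0).all()
        obs = trials[trials["choice"] != "missed"]
        for l in (1, 4):
            acc_obs = obs[obs["coherence_level"] == l]["correct"].mean()
            acc_pred = pred[pred["coherence_level"] == l]["correct"].mean()
            assert acc_pred == pytest.approx(acc_obs, abs=0.05)
            q_obs = obs.loc[obs["correct"] & (obs["coherence_level"] == l), "rt"].quantile([0.1, 0.5, 0.9]).to_numpy()
            q_pred = pred.loc[pred["correct"] & (pred["coherence_level"] == l), "rt"].quantile([0.1, 0.5, 0.9]).to_numpy()
            # the empirical .9 quantile carries ~0.04 s sampling error at
            # ~500 trials per level; allow it on top of the model tolerance
            assert np.allclose(q_obs[:2], q_pred[:2], atol=0.05)
            assert q_obs[2] == pytest.approx(q_pred[2], abs=0.075)
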