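"""Model evaluation: HDI, group differences, comparison tables, PPC."""

import numpy as np
import pandas as pd
import pytest

from prlkit.evaluate import (
    compare_models,
    group_difference,
    hdi,
    posterior_predictive_choices,
    parameter_recovery,
    ppc_behavior,
)
from prlkit.behavior import summarize
from prlkit.inference import FitResult, MCMCConfig


def fake_fit(param_draws: dict, subjects=None, model="rp", group="HC",
             data_hash="h", subject_theta=None, n_chains=2):
    """Construct a FitResult with hand-specified posterior draws."""
    posterior = {}
    some = next(iter(param_draws.values()))
    total = len(np.ravel(some))
    d = total // n_chains
    for k, v in param_draws.items():
        posterior[f"mu_{k}"] = np.asarray(v, dtype=float).reshape(n_chains, d)
    subjects = subjects or ["s0", "s1"]
    names = ("a_rew", "a_pun", "beta") if model == "rp" else ("a", "rho", "beta")
    for j, name in enumerate(names):
        if subject_theta is not None:
            arr = np.tile(np.asarray(subject_theta)[None, None, :, j], (n_chains, d, 1))
        else:
            arr = np.full((n_chains, d, len(subjects)), 0.5)
        posterior[name] = arr
    pll = np.full((n_chains, d, len(subjects)), -1.0)
    return FitResult(
        model=model, group=group, subjects=list(subjects), posterior=posterior,
        pointwise_loglik=pll, rhat={"mu_raw": np.array(1.0)}, looic=float(-2 * pll.sum(axis=2).mean() * 0 + 2.0 * len(subjects)),
        elpd_loo_i=np.full(len(subjects), -1.0), pareto_k=np.zeros(len(subjects)),
        diagnostics={}, config=MCMCConfig(n_samples=2 * d, n_warmup=d, n_chains=n_chains),
        data_hash=data_hash,
    )


class TestHdi:
    def test_point_mass(self):
        iv = hdi(np.full(500, 2.5))
        assert (iv.lower, iv.upper) == (2.5, 2.5)
        assert iv.excludes_zero

    def test_uniform_width(self):
        rng = np.random.default_rng(0)
        iv = hdi(rng.uniform(size=10_000), mass=0.95)
        assert iv.upper - iv.lower == pytest.approx(0.95, abs=0.02)

    def test_standard_normal_bounds(self):
        rng = np.random.default_rng(1)
        iv = hdi(rng.standard_normal(50_000), mass=0.95)
        assert iv.lower == pytest.approx(-1.96, abs=0.05)
        assert iv.upper == pytest.approx(1.96, abs=0.05)
        assert not iv.excludes_zero

    def test_mass_property(self):
        rng = np.random.default_rng(2)
        x = rng.standard_gamma(2.0, size=3000)
        iv = hdi(x, mass=0.9)
        inside = np.mean((x >= iv.lower) & (x <= iv.upper))
        assert inside >= 0.9 - 1 / len(x)

    def test_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(3)
        x = rng.standard_normal(20_000) * 2 + 1
        iv = hdi(x, mass=0.94)
        lo, hi = az.hdi(x, hdi_prob=0.94)
        assert iv.lower == pytest.approx(lo, abs=0.02)
        assert iv.upper == pytest.approx(hi, abs=0.02)

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            hdi(np.zeros(50))


class TestGroupDifference:
    def test_identical_fits_straddle_zero(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(1000) * 0.1 + 0.4
        f = fake_fit({"a_pun": draws})
        iv = group_difference(f, f, "a_pun")
        assert iv.lower <= 0 <= iv.upper
        assert not iv.excludes_zero

    def test_separated_fits_exclude_zero(self):
        rng = np.random.default_rng(1)
        fa = fake_fit({"a_pun": rng.normal(0.45, 0.02, 1000)}, data_hash="a", group="AUDP")
        fb = fake_fit({"a_pun": rng.normal(0.25, 0.02, 1000)}, data_hash="b", group="HC")
        iv = group_difference(fa, fb, "a_pun")
        assert iv.excludes_zero and iv.lower > 0

    def test_antisymmetry_under_same_pairing_seed(self):
        rng = np.random.default_rng(2)
        fa = fake_fit({"beta": rng.normal(2.0, 0.3, 1000)}, data_hash="a", group="AUDP")
        fb = fake_fit({"beta": rng.normal(3.0, 0.3, 1000)}, data_hash="b", group="HC")
        ab = group_difference(fa, fb, "beta", pairing_seed=9)
        ba = group_difference(fb, fa, "beta", pairing_seed=9)
        assert ab.lower == pytest.approx(-ba.upper, abs=1e-12)
        assert ab.upper == pytest.approx(-ba.lower, abs=1e-12)

    def test_missing_parameter_raises(self):
        f = fake_fit({"a_pun": np.random.default_rng(0).normal(size=1000)})
        with pytest.raises(KeyError):
            group_difference(f, f, "nonexistent")


class TestCompareModels:
    def test_single_fit_delta_zero(self):
        f = fake_fit({"a_pun": np.zeros(200)})
        f.looic = 100.0
        table = compare_models([f])
        assert table["delta_looic"].tolist() == [0.0]

    def test_sorted_with_ties_broken_by_name(self):
        f1 = fake_fit({"a_pun": np.zeros(200)}, model="rp")
        f2 = fake_fit({"a": np.zeros(200)}, model="ewa")
        f1.looic = f2.looic = 50.0
        table = compare_models([f2, f1])
        assert table["model"].tolist() == ["ewa", "rp"]

    def test_mismatched_data_rejected(self):
        f1 = fake_fit({"a_pun": np.zeros(200)}, data_hash="x")
        f2 = fake_fit({"a_pun": np.zeros(200)}, data_hash="y")
        with pytest.raises(ValueError):
            compare_models([f1, f2])


@pytest.fixture(scope="module")
def hc_tiny(tiny_study):
    data, truth, schedules = tiny_study
    hc = data[data["group"] == "HC"]
    return hc, truth, {s: schedules[s] for s in hc["subject"].unique()}


class TestPosteriorPredictive:
    def test_random_point_mass_posterior_gives_half(self, hc_tiny):
        hc, _, schedules = hc_tiny
        subjects = sorted(hc["subject"].unique())
        theta = np.array([[0.5, 0.5, 0.0]] * len(subjects))  # beta = 0
        fit = fake_fit({"a_pun": np.zeros(40)}, subjects=subjects,
                       subject_theta=theta)
        ppc = posterior_predictive_choices(fit, hc, schedules, n_draws=40, seed=0)
        assert ppc["p_choice1"].mean() == pytest.approx(0.5, abs=0.05)
        assert np.all((ppc["p_choice1"] >= 0) & (ppc["p_choice1"] <= 1))

    def test_sharp_posterior_tracks_correct_stimulus(self, hc_tiny):
        hc, _, schedules = hc_tiny
        subjects = sorted(hc["subject"].unique())
        theta = np.array([[0.9, 0.9, 10.0]] * len(subjects))
        fit = fake_fit({"a_pun": np.zeros(40)}, subjects=subjects,
                       subject_theta=theta)
        ppc = posterior_predictive_choices(fit, hc, schedules, n_draws=40, seed=0)
        # before the first reversal (trials 3-9 of stage 0) simulated runs and
        # the empirical grid are guaranteed to sit in the same stage, and a
        # sharp fast learner should have locked onto the correct stimulus
        corr_stim = np.where(ppc["correct"], ppc["choice"], 1 - ppc["choice"])
        early = (ppc["stage"] == 0) & ppc["trial"].between(3, 9)
        agree = (ppc["modal_choice"].to_numpy() == corr_stim)[early.to_numpy()]
        assert agree.mean() > 0.8

    def test_subject_mismatch_rejected(self, hc_tiny):
        hc, _, schedules = hc_tiny
        fit = fake_fit({"a_pun": np.zeros(40)}, subjects=["nope"])
        with pytest.raises(ValueError):
            posterior_predictive_choices(fit, hc, schedules)


class TestPpcBehavior:
    def test_exact_probabilities_reduce_to_empirical_statistics(self, hc_tiny):
        hc, _, _ = hc_tiny
        ppc = hc.copy()
        ppc["p_choice1"] = ppc["choice"].astype(float)
        ppc["modal_choice"] = ppc["choice"]
        emp = summarize(hc)
        for mode in ("weighted", "modal"):
            out = ppc_behavior(ppc, mode=mode)
            for s in emp.index:
                assert out.loc[s, "p_winstay"] == pytest.approx(emp.loc[s, "p_winstay"])
                assert out.loc[s, "p_loseshift"] == pytest.approx(emp.loc[s, "p_loseshift"])
                assert out.loc[s, "n_persev_errors"] == emp.loc[s, "n_persev_errors"]

    def test_uniform_probabilities_give_half(self, hc_tiny):
        hc, _, _ = hc_tiny
        ppc = hc.copy()
        ppc["p_choice1"] = 0.5
        ppc["modal_choice"] = 0
        out = ppc_behavior(ppc, mode="weighted")
        assert np.allclose(out["p_winstay"], 0.5)
        assert np.allclose(out["p_loseshift"], 0.5)

    def test_unknown_mode_rejected(self, hc_tiny):
        hc, _, _ = hc_tiny
        with pytest.raises(ValueError):
            ppc_behavior(hc.assign(p_choice1=0.5, modal_choice=0), mode="mean")


def test_parameter_recovery_smoke_and_empty_error(hc_tiny):
    hc, truth, schedules = hc_tiny
    subjects = sorted(hc["subject"].unique())
    theta = np.array([[0.35, 0.3, 3.0], [0.3, 0.4, 2.0]])
    fit = fake_fit({"a_pun": np.zeros(40)}, subjects=subjects, subject_theta=theta)
    with pytest.raises(ValueError):
        parameter_recovery(fit, hc.iloc[0:0], schedules)
    cfg = MCMCConfig(n_samples=300, n_warmup=120, n_chains=1, seed=5)
    rep = parameter_recovery(fit, hc, schedules, mcmc_config=cfg,
                             n_ppc_draws=30, seed=1,
                             ground_truth=truth[truth["subject"].isin(subjects)])
    assert set(rep.correlations) == {"a_rew", "a_pun", "beta"}
    assert rep.true_means.shape == rep.recovered_means.shape
    assert rep.ground_truth_correlations is not None
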