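import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import tacticlearn as tl
from tacticlearn import hierarchical_models as hm
from _oracles import naive_waic


def _zero_params(spec):
    return {
        "alpha_home": 0.0, "alpha_away": 0.0,
        "beta": {t: 0.0 for t in spec.fixed_terms},
        "manager_effects": {e: 0.0 for e in spec.manager_effects},
        "division_effects": {e: 0.0 for e in spec.division_effects},
    }


class TestLikelihood:
    def test_all_zero_parameters_give_half(self):
        spec = hm.ModelSpec.named("full")
        row = {t: 0.3 for t in spec.fixed_terms}
        row["is_home"] = True
        assert hm.likelihood(_zero_params(spec), row, spec) == 0.5

    def test_home_intercept_closed_form(self):
        spec = hm.ModelSpec.named("null")
        params = _zero_params(spec)
        params["alpha_home"] = 1.0
        row = {t: 0.0 for t in spec.fixed_terms}
        assert hm.likelihood(params, dict(row, is_home=True), spec) \
            == pytest.approx(expit(1.0))
        assert hm.likelihood(params, dict(row, is_home=False), spec) == 0.5

    def test_hand_evaluated_linear_predictor(self):
        spec = hm.ModelSpec.named("personal")
        params = _zero_params(spec)
        params["alpha_away"] = -0.5
        params["beta"].update(p_use=1.2, p_win=0.4, team_strength=2.0)
        params["manager_effects"].update(intercept=0.3, p_use=-0.2)
        params["division_effects"].update(intercept=0.1, p_use=0.5)
        rows = [
            {"p_use": 0.5, "p_win": -1.0, "p_use_x_p_win": -0.5,
             "p_use_x_o_win": 0.0, "team_strength": 0.1, "is_home": False},
            {"p_use": -0.25, "p_win": 0.0, "p_use_x_p_win": 0.0,
             "p_use_x_o_win": 0.2, "team_strength": 0.0, "is_home": False},
            {"p_use": 0.0, "p_win": 0.5, "p_use_x_p_win": 0.0,
             "p_use_x_o_win": 0.0, "team_strength": -0.2, "is_home": True},
        ]
        etas = [
            -0.5 + 0.3 + 0.1 + (1.2 - 0.2 + 0.5) * 0.5 + 0.4 * -1.0 + 2.0 * 0.1,
            -0.5 + 0.3 + 0.1 + (1.2 - 0.2 + 0.5) * -0.25,
            0.0 + 0.3 + 0.1 + 0.4 * 0.5 + 2.0 * -0.2,
        ]
        for row, eta in zip(rows, etas):
            assert hm.likelihood(params, row, spec) == pytest.approx(expit(eta))

    def test_missing_parameter_raises(self):
        spec = hm.ModelSpec.named("null")
        params = _zero_params(spec)
        del params["beta"]["team_strength"]
        with pytest.raises(hm.SpecificationError):
            hm.likelihood(params, {"team_strength": 0.0, "is_home": True}, spec)


class TestModelSpec:
    def test_nesting_and_slope_structure(self):
        null = hm.ModelSpec.named("null")
        personal = hm.ModelSpec.named("personal")
        population = hm.ModelSpec.named("population")
        full = hm.ModelSpec.named("full")
        assert set(null.fixed_terms) == {"team_strength"}
        assert set(full.fixed_terms) >= set(personal.fixed_terms) \
            | set(population.fixed_terms)
        for spec in (null, personal, population, full):
            assert set(spec.manager_slopes) <= set(spec.fixed_terms)
            assert set(spec.division_slopes) <= set(spec.fixed_terms)
        assert set(personal.manager_slopes) == {"p_use", "p_win"}
        assert set(personal.division_slopes) == {"p_use"}
        assert set(full.manager_slopes) == {"p_use", "p_win", "g_use", "g_win"}
        assert set(full.division_slopes) == {"p_use", "g_use"}
        with_win = hm.ModelSpec.named("full", division_winrate_slopes=True)
        assert set(with_win.division_slopes) == {"p_use", "p_win",
                                                 "g_use", "g_win"}

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            hm.ModelSpec.named("bogus")


class TestWaic:
    def test_zero_variance_draws(self):
        ll = np.tile(np.array([-1.0, -2.0, -0.5]), (4, 1))
        out = hm.waic(ll)
        assert out["p_waic"] == pytest.approx(0.0)
        assert out["waic"] == pytest.approx(-2 * ll[0].sum())

    def test_two_by_two_hand_computation(self):
        ll = np.array([[-1.0, -2.0], [-1.5, -1.0]])
        lppd = (np.log(np.mean(np.exp(ll[:, 0])))
                + np.log(np.mean(np.exp(ll[:, 1]))))
        p = ll[:, 0].var(ddof=1) + ll[:, 1].var(ddof=1)
        out = hm.waic(ll)
        assert out["waic"] == pytest.approx(-2 * (lppd - p))
        assert out["p_waic"] == pytest.approx(p)

    def test_duplicating_observations_doubles_waic(self):
        rng = np.random.default_rng(0)
        ll = -rng.exponential(size=(8, 5))
        once, twice = hm.waic(ll), hm.waic(np.hstack([ll, ll]))
        assert twice["waic"] == pytest.approx(2 * once["waic"])
        assert twice["p_waic"] == pytest.approx(2 * once["p_waic"])

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            ll = -rng.exponential(size=(rng.integers(2, 30),
                                        rng.integers(1, 40)))
            got = hm.waic(ll)
            w, p, se = naive_waic(ll)
            assert got["waic"] == pytest.approx(w, abs=1e-8)
            assert got["p_waic"] == pytest.approx(p, abs=1e-8)
            if ll.shape[1] > 1:
                assert got["se"] == pytest.approx(se, abs=1e-8)

    def test_matches_arviz_up_to_variance_convention(self):
        # arviz computes the pointwise penalty with the population variance;
        # this package follows the R convention (sample variance, ddof=1),
        # so the two agree exactly after rescaling the penalty by S/(S-1).
        import arviz as az

        rng = np.random.default_rng(3)
        S = 100
        ll = -rng.exponential(size=(S, 12))
        idata = az.from_dict(
            log_likelihood={"y": ll.reshape(2, S // 2, 12)})
        ref = az.waic(idata, scale="deviance")
        got = hm.waic(ll)
        p_ref = float(ref.p_waic) * S / (S - 1)
        assert got["p_waic"] == pytest.approx(p_ref, rel=1e-6)
        assert got["waic"] == pytest.approx(
            float(ref.elpd_waic) + 2 * (got["p_waic"] - float(ref.p_waic)),
            rel=1e-6)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            hm.waic(np.array([[np.inf, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValueError):
            hm.waic(np.zeros((1, 4)))


def _fake_fit(name, loglik, obs_ids=None):
    spec = hm.ModelSpec.named(name)
    S = loglik.shape[0]
    return hm.PosteriorDraws(
        spec=spec, draws={"alpha_home": np.zeros((1, S))}, loglik=loglik,
        diagnostics={}, manager_levels=[], division_levels=[],
        obs_ids=np.array(obs_ids if obs_ids is not None
                         else [f"o{i}" for i in range(loglik.shape[1])]),
        seed=0)


class TestCompare:
    def test_single_model(self):
        tbl = hm.compare([_fake_fit("null", -np.ones((4, 6)))])
        assert tbl["weight"].iloc[0] == 1.0
        assert tbl["d_waic"].iloc[0] == 0.0
        assert tbl["d_se"].iloc[0] == 0.0

    def test_equal_waic_splits_weight(self):
        rng = np.random.default_rng(1)
        ll = -rng.exponential(size=(6, 8))
        tbl = hm.compare([_fake_fit("null", ll), _fake_fit("full", ll)])
        np.testing.assert_allclose(tbl["weight"], [0.5, 0.5])
        assert tbl["weight"].sum() == pytest.approx(1.0)

    def test_different_observation_sets_rejected(self):
        a = _fake_fit("null", -np.ones((4, 6)))
        b = _fake_fit("full", -np.ones((4, 6)),
                      obs_ids=[f"x{i}" for i in range(6)])
        with pytest.raises(ValueError, match="not comparable"):
            hm.compare([a, b])


class TestCoefficientTable:
    def test_constant_draws(self):
        fitted = _fake_fit("null", -np.ones((4, 3)))
        fitted.draws = {"beta_team_strength": np.full((2, 5), 1.7)}
        tbl = hm.coefficient_table(fitted).set_index("parameter")
        row = tbl.loc["beta_team_strength"]
        assert row["mean"] == row["lower"] == row["upper"] == 1.7
        assert row["excludes_zero"]

    def test_quantiles_match_sort_oracle(self):
        rng = np.random.default_rng(9)
        draws = rng.normal(size=(2, 500))
        fitted = _fake_fit("null", -np.ones((4, 3)))
        fitted.draws = {"alpha_home": draws}
        tbl = hm.coefficient_table(fitted).set_index("parameter")
        flat = np.sort(draws.ravel())
        lo = np.quantile(flat, 0.055)
        hi = np.quantile(flat, 0.945)
        assert tbl.loc["alpha_home", "lower"] == pytest.approx(lo)
        assert tbl.loc["alpha_home", "upper"] == pytest.approx(hi)


class TestFit:
    def test_same_seed_reproduces_draws(self, desk_design):
        spec = hm.ModelSpec.named("null")
        st = hm.McmcSettings(chains=1, warmup=80, samples=60)
        a = hm.fit(desk_design, spec, st, seed=5)
        b = hm.fit(desk_design, spec, st, seed=5)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])
        np.testing.assert_array_equal(a.loglik, b.loglik)

    def test_posterior_structure_and_invariants(self, small_fit):
        f = small_fit
        assert f.loglik.shape == (f.n_draws, f.n_obs)
        assert np.isfinite(f.loglik).all()
        for k, v in f.draws.items():
            if k.startswith("sigma"):
                assert (v > 0).all()
        assert f.draws["b_manager_p_use"].shape[-1] == len(f.manager_levels)
        assert f.draws["b_division_g_use"].shape[-1] == len(f.division_levels)

    def test_balanced_coin_flip_intercepts_cover_zero(self):
        rng = np.random.default_rng(11)
        n = 400
        design = pd.DataFrame({
            "obs_id": [f"o{i}" for i in range(n)],
            "is_focal": rng.uniform(size=n) < 0.5,
            "is_home": np.tile([True, False], n // 2),
            "team_strength": 0.0,
            "manager": rng.choice([f"m{j}" for j in range(10)], size=n),
            "division": "D1",
        })
        f = hm.fit(design, hm.ModelSpec.named("null"),
                   hm.McmcSettings(chains=2, warmup=250, samples=250), seed=3)
        for a in ("alpha_home", "alpha_away"):
            lo, hi = hm.percentile_interval(f.stacked(a))
            assert lo < 0 < hi

    def test_fixed_effects_match_glm_oracle(self):
        """Weak priors + homogeneous groups: posterior means track the MLE."""
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        n = 600
        x1 = rng.normal(scale=0.5, size=n)
        x2 = rng.normal(scale=0.5, size=n)
        eta = 0.4 + 1.0 * x1 - 0.8 * x2
        design = pd.DataFrame({
            "obs_id": [f"o{i}" for i in range(n)],
            "is_focal": rng.uniform(size=n) < expit(eta),
            "is_home": True,
            "p_use": x1, "p_win": x2,
            "p_use_x_p_win": 0.0, "p_use_x_o_win": 0.0,
            "team_strength": 0.0,
            "manager": rng.choice([f"m{j}" for j in range(12)], size=n),
            "division": "D1",
        })
        f = hm.fit(design, hm.ModelSpec.named("personal"),
                   hm.McmcSettings(chains=2, warmup=400, samples=400), seed=8)
        X = sm.add_constant(design[["p_use", "p_win"]])
        glm = sm.GLM(design["is_focal"].astype(float), X,
                     family=sm.families.Binomial()).fit()
        for term in ("p_use", "p_win"):
            post = f.stacked(f"beta_{term}")
            tol = 2 * (post.std() + glm.bse[term])
            assert abs(post.mean() - glm.params[term]) < tol

    def test_varying_slopes_change_waic_penalty(self, desk_design, small_fit):
        fixed_only = hm.ModelSpec(
            name="full", fixed_terms=small_fit.spec.fixed_terms,
            manager_slopes=(), division_slopes=())
        f2 = hm.fit(desk_design, fixed_only,
                    hm.McmcSettings(chains=2, warmup=300, samples=300),
                    seed=99)
        p_full = hm.waic(small_fit.loglik)["p_waic"]
        p_fixed = hm.waic(f2.loglik)["p_waic"]
        assert p_full != pytest.approx(p_fixed, abs=1e-6)
        assert p_full > p_fixed          # slopes add effective parameters

    def test_save_load_round_trip(self, small_fit, tmp_path):
        path = tmp_path / "full.draws.npz"
        hm.save_draws(small_fit, path)
        back = hm.load_draws(path)
        assert back.spec == small_fit.spec
        for k in small_fit.draws:
            np.testing.assert_array_equal(back.draws[k], small_fit.draws[k])
        np.testing.assert_array_equal(back.loglik, small_fit.loglik)
        assert back.manager_levels == small_fit.manager_levels
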