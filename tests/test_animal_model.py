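import numpy as np
import pytest
from scipy.linalg import cho_factor, cho_solve

import qgconstraints as qg
from qgconstraints.animal_model import (
    MCMCSettings,
    PriorSpec,
    PosteriorChain,
    _sample_invwishart,
    default_informative_prior,
    parameter_expanded_prior,
    fit_animal_model,
)
from qgconstraints.pedigree import additive_relationship
from qgconstraints.simulate import SimConfig
from qgconstraints.summarize import summarize_posterior


# ---------- priors ----------

def test_default_prior_formula():
    p = default_informative_prior(4, np.ones(4), 3)
    np.testing.assert_allclose(p.V, np.eye(4) / 3)
    assert p.nu == 4


def test_default_prior_univariate():
    p = default_informative_prior(1, 2.0, 1)
    assert p.V[0, 0] == pytest.approx(2.0)
    assert p.nu == 1


def test_default_prior_rejects_nonpositive_vp():
    with pytest.raises(ValueError):
        default_informative_prior(4, [1.0, -1.0, 1.0, 1.0], 3)


def test_invwishart_sampler_matches_analytic_mean():
    # E[IW(Psi, nu)] = Psi / (nu - t - 1); independent oracle for the sampler
    rng = np.random.default_rng(0)
    V = np.array([[1.0, 0.3], [0.3, 2.0]])
    nu = 8.0
    prior = PriorSpec(family="informative", V=V, nu=nu)
    draws = np.stack([_sample_invwishart(rng, prior.scale, nu) for _ in range(20_000)])
    expected = prior.scale / (nu - 2 - 1)
    np.testing.assert_allclose(draws.mean(axis=0), expected, rtol=0.05)


def test_prior_scale_is_nu_V():
    # at nu = t the IW mean is undefined; the documented contract is the
    # scale matrix nu*V with df nu (prior mode V*nu/(nu+t+1))
    p = default_informative_prior(4, 2.0 * np.ones(4), 2)
    np.testing.assert_allclose(p.scale, 4.0 * np.diag(2.0 * np.ones(4)) / 2)


def test_px_prior_defaults():
    p = parameter_expanded_prior(4)
    np.testing.assert_allclose(p.V, np.eye(4))
    assert p.nu == 4 and p.alpha_variance == 625.0


# ---------- settings ----------

def test_settings_minimum_samples():
    with pytest.raises(ValueError, match="100"):
        MCMCSettings(iterations=1_000, burn_in=500, thinning=15, seed=0)


def test_settings_burnin_bound():
    with pytest.raises(ValueError):
        MCMCSettings(iterations=100, burn_in=100, thinning=1, seed=0)


def test_settings_sample_count():
    s = MCMCSettings(iterations=20_000, burn_in=5_000, thinning=15, seed=0)
    assert s.n_samples == 1_000


# ---------- fit: identifiability errors ----------

def _no_repeat_data(seed=0):
    cfg = SimConfig(n_founders=40, generations=3, max_repeats=1, repeat_rate=0.0,
                    unknown_age_fraction=0.0, seed=seed)
    ped = qg.simulate_pedigree(cfg)
    obs, _ = qg.simulate_phenotypes(ped, cfg)
    return ped, obs


def test_pe_requires_repeats():
    ped, obs = _no_repeat_data()
    obs_std, _ = qg.mean_standardize(obs)
    design = qg.build_fixed_design(obs_std)
    prior = qg.default_informative_prior(4, np.ones(4), 3)
    settings = MCMCSettings(iterations=300, burn_in=100, thinning=2, seed=0)
    with pytest.raises(ValueError, match="repeated measures"):
        fit_animal_model(obs_std, design, ped, prior, settings)


def test_year_requires_two_years():
    ped, obs = _no_repeat_data()
    df = obs.data.copy()
    df["year"] = 2000
    obs1 = obs.copy_with(df)
    obs_std, _ = qg.mean_standardize(obs1)
    design = qg.build_fixed_design(obs_std)
    prior = qg.default_informative_prior(4, np.ones(4), 3)
    settings = MCMCSettings(iterations=300, burn_in=100, thinning=2, seed=0)
    with pytest.raises(ValueError, match="year"):
        fit_animal_model(obs_std, design, ped, prior, settings,
                         include_pe=False)


def test_unknown_individual_errors():
    ped, obs = _no_repeat_data()
    df = obs.data.copy()
    df.loc[df.index[0], "id"] = "NOT_IN_PEDIGREE"
    obs1 = obs.copy_with(df)
    obs_std, _ = qg.mean_standardize(obs1)
    design = qg.build_fixed_design(obs_std)
    prior = qg.default_informative_prior(4, np.ones(4), 3)
    settings = MCMCSettings(iterations=300, burn_in=100, thinning=2, seed=0)
    with pytest.raises(ValueError, match="pedigree"):
        fit_animal_model(obs_std, design, ped, prior, settings,
                         include_pe=False, include_year=True)


# ---------- prior-only run samples the prior ----------

def test_prior_only_recovers_prior_moments():
    cfg = SimConfig(n_founders=40, generations=3, seed=2)
    ped = qg.simulate_pedigree(cfg)
    obs, _ = qg.simulate_phenotypes(ped, cfg)
    obs_std, _ = qg.mean_standardize(obs)
    design = qg.build_fixed_design(obs_std)
    # nu = t + 4 so the prior mean exists: E[G] = nu*V/(nu - t - 1)
    t = 4
    nu = t + 4.0
    V = np.diag([0.002, 0.003, 0.004, 0.005])
    prior = PriorSpec(family="informative", V=V, nu=nu)
    settings = MCMCSettings(iterations=6_000, burn_in=1_000, thinning=10, seed=3)
    chain = fit_animal_model(obs_std, design, ped, prior, settings, prior_only=True)
    expected = prior.scale / (nu - t - 1)
    got = chain.G.mean(axis=0)
    np.testing.assert_allclose(np.diag(got), np.diag(expected), rtol=0.35)


# ---------- univariate REML oracle ----------

def reml_va_oracle(y, X, A):
    """Profile REML for y = Xb + a + e, var(a) = s2a * A, var(e) = s2e * I.

    Optimizes the ratio lam = s2e/s2a; the scale s2a is profiled out.
    Independent of the Gibbs sampler.
    """
    from scipy.optimize import minimize_scalar

    n, p = X.shape

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        K = A + lam * np.eye(n)
        c = cho_factor(K, lower=True)
        Kinv_y = cho_solve(c, y)
        Kinv_X = cho_solve(c, X)
        XtKX = X.T @ Kinv_X
        beta = np.linalg.solve(XtKX, X.T @ Kinv_y)
        resid_quad = float(y @ Kinv_y - (X.T @ Kinv_y) @ beta)
        s2a = resid_quad / (n - p)
        logdetK = 2.0 * np.sum(np.log(np.diag(c[0])))
        _, logdetX = np.linalg.slogdet(XtKX)
        return 0.5 * ((n - p) * np.log(s2a) + logdetK + logdetX + (n - p))

    res = minimize_scalar(neg_reml, bounds=(-5, 5), method="bounded")
    lam = np.exp(res.x)
    K = A + lam * np.eye(n)
    c = cho_factor(K, lower=True)
    Kinv_y = cho_solve(c, y)
    Kinv_X = cho_solve(c, X)
    beta = np.linalg.solve(X.T @ Kinv_X, X.T @ Kinv_y)
    s2a = float(y @ Kinv_y - (X.T @ Kinv_y) @ beta) / (len(y) - X.shape[1])
    return s2a


def test_univariate_va_matches_reml_oracle():
    # single-trait, single-record animal model vs profile REML
    rng = np.random.default_rng(7)
    cfg = SimConfig(n_founders=300, generations=4, mean_offspring=2.2,
                    max_repeats=1, repeat_rate=0.0, missing_rate=(0, 0, 0, 0),
                    unknown_age_fraction=0.0, seed=8)
    ped = qg.simulate_pedigree(cfg)
    A = additive_relationship(ped).values
    n = len(ped)
    s2a_true, s2e_true = 0.4, 0.6
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    a = np.sqrt(s2a_true) * (L @ rng.standard_normal(n))
    y = 10.0 + a + np.sqrt(s2e_true) * rng.standard_normal(n)

    import pandas as pd

    from qgconstraints.phenotypes import FixedDesign, ObservationTable

    df = pd.DataFrame({"id": ped.ids, "year": 2000, "sex": "F", "age": 1.0,
                       "date": np.nan, "w1": y, "fledged": np.nan})
    obs = ObservationTable(data=df, traits=("w1",))
    design = FixedDesign(matrix=np.ones((n, 1)), columns=["intercept"])
    prior = default_informative_prior(1, float(np.var(y)), 1)
    settings = MCMCSettings(iterations=6_000, burn_in=1_000, thinning=10, seed=9)
    chain = fit_animal_model(obs, design, ped, prior, settings,
                             include_pe=False, include_year=False)
    va_gibbs = float(chain.G[:, 0, 0].mean())
    va_reml = reml_va_oracle(y, np.ones((n, 1)), A)
    assert va_gibbs == pytest.approx(va_reml, rel=0.15)


# ---------- chain properties ----------

def test_chain_samples_positive_definite(small_chain):
    _, _, _, chain = small_chain
    for M in (chain.G, chain.P_pe, chain.P_year, chain.R):
        eig = np.linalg.eigvalsh(M)
        assert eig.min() > 0


def test_chain_reproducible(small_sim):
    cfg, ped, obs, _ = small_sim
    obs_std, _ = qg.mean_standardize(obs)
    design = qg.build_fixed_design(obs_std)
    Vp = np.nanvar(obs_std.data[list(obs.traits)].to_numpy(dtype=float), axis=0)
    prior = qg.default_informative_prior(4, Vp, 3)
    settings = MCMCSettings(iterations=1_200, burn_in=200, thinning=10, seed=21)
    c1 = fit_animal_model(obs_std, design, ped, prior, settings)
    c2 = fit_animal_model(obs_std, design, ped, prior, settings)
    assert np.array_equal(c1.G, c2.G)
    assert np.array_equal(c1.B, c2.B)


def test_chain_length_and_metadata(small_chain):
    _, _, _, chain = small_chain
    assert len(chain) == (2500 - 700) // 15
    assert chain.metadata["seed"] == 5
    assert chain.metadata["prior_family"] == "informative"


def test_chain_roundtrip_save_load(tmp_path, small_chain):
    _, _, _, chain = small_chain
    chain.save(tmp_path / "chain")
    back = PosteriorChain.load(tmp_path / "chain")
    np.testing.assert_allclose(back.G, chain.G)
    np.testing.assert_allclose(back.B, chain.B)
    assert back.trait_names == chain.trait_names


# ---------- summaries ----------

def test_summary_constant_chain_zero_width():
    t = 2
    G = np.tile(np.array([[0.5, 0.1], [0.1, 0.4]]), (120, 1, 1))
    chain = PosteriorChain(G=G, P_pe=G.copy(), P_year=G.copy(), R=G.copy(),
                           B=np.zeros((120, 1, t)), trait_names=("a", "b"),
                           fixed_columns=["intercept"])
    s = summarize_posterior(chain).set_index("element")
    row = s[s["quantity"] == "IA_evolvability"].loc["a"]
    assert row["lo95"] == row["hi95"]


def test_summary_reporting_scale():
    # mean-standardized V_A of 0.00032 is reported as 0.032 (x100)
    t = 1
    G = np.full((150, 1, 1), 0.00032)
    chain = PosteriorChain(G=G, P_pe=G.copy(), P_year=G.copy(), R=G.copy(),
                           B=np.zeros((150, 1, 1)), trait_names=("wing",),
                           fixed_columns=["intercept"])
    s = summarize_posterior(chain)
    ia = s[(s["quantity"] == "IA_evolvability")].iloc[0]
    assert ia["mode"] == pytest.approx(0.032)


def test_summary_heritability():
    G = np.full((150, 1, 1), 0.3)
    other = np.full((150, 1, 1), 0.7 / 3)
    chain = PosteriorChain(G=G, P_pe=other, P_year=other, R=other,
                           B=np.zeros((150, 1, 1)), trait_names=("wing",),
                           fixed_columns=["intercept"])
    s = summarize_posterior(chain)
    h2 = s[s["quantity"] == "heritability"].iloc[0]
    assert h2["mode"] == pytest.approx(0.3, abs=1e-9)


def test_summary_modes_near_truth(small_sim, small_chain):
    cfg, *_ = small_sim
    _, _, _, chain = small_chain
    s = summarize_posterior(chain)
    ia = s[s["quantity"] == "IA_evolvability"].reset_index(drop=True)
    for k in range(4):
        truth = cfg.G_true[k, k] * 100
        sd = np.std(chain.G[:, k, k]) * 100
        assert abs(ia.loc[k, "mode"] - truth) < 4 * sd + 1e-6
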