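import numpy as np
import pytest

from qgconstraints.metrics import (
    angle_gmax_beta,
    average_evolvability,
    evolvability_beta,
    fold_angle,
    gmax,
    meta_geometric_mean,
    predicted_response,
    propagate,
    rate_of_adaptation,
    relative_rate_of_adaptation,
)
from qgconstraints.reference import POINT_BETA, point_G


def random_pd(t, rng, scale=1.0):
    M = rng.standard_normal((t, t))
    return scale * (M @ M.T + t * np.eye(t) * 0.1)


# ---------- independent oracles ----------

def power_iteration_oracle(G, iters=10_000):
    v = np.ones(G.shape[0]) / np.sqrt(G.shape[0])
    for _ in range(iters):
        w = G @ v
        v = w / np.linalg.norm(w)
    lam = float(v @ G @ v)
    return lam, v


def mc_average_evolvability_oracle(G, n=100_000, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n, G.shape[0]))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return float(np.mean(np.einsum("ij,jk,ik->i", u, G, u)))


def fitness_surface_oracle(G, beta, gamma):
    # independent evaluation of the quadratic fitness surface at z = G beta
    def w(z):
        val = 0.0
        for i in range(len(z)):
            val += beta[i] * z[i]
            for j in range(len(z)):
                val += 0.5 * z[i] * gamma[i, j] * z[j]
        return val

    z_star = np.einsum("ij,j->i", G, beta)
    return w(z_star)


# ---------- predicted_response ----------

def test_identity_G_returns_beta():
    beta = np.array([0.2, -0.1, 0.5, 0.0])
    np.testing.assert_allclose(predicted_response(np.eye(4), beta), beta)


def test_diagonal_G_multi_equals_uni():
    G = np.diag([1.0, 2.0, 3.0, 4.0])
    beta = np.array([1.0, -1.0, 0.5, 0.25])
    np.testing.assert_allclose(predicted_response(G, beta), predicted_response(G, beta, univariate=True))


def test_gull_response_matches_product_oracle():
    G = point_G("red_billed_gull")
    beta = POINT_BETA["red_billed_gull"]
    oracle = np.einsum("ij,j->i", G, beta)
    np.testing.assert_allclose(predicted_response(G, beta), oracle, atol=1e-12)


def test_dimension_mismatch_errors():
    with pytest.raises(ValueError):
        predicted_response(np.eye(3), np.zeros(4))


# ---------- rate_of_adaptation ----------

def test_zero_gamma_is_beta_G_beta():
    rng = np.random.default_rng(1)
    G = random_pd(4, rng)
    beta = rng.standard_normal(4)
    assert rate_of_adaptation(G, beta, np.zeros((4, 4))) == pytest.approx(float(beta @ G @ beta))


def test_unit_case():
    assert rate_of_adaptation(np.eye(4), np.array([1.0, 0, 0, 0]), np.zeros((4, 4))) == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_rate_matches_fitness_surface_oracle(seed):
    rng = np.random.default_rng(seed)
    G = random_pd(4, rng)
    beta = rng.standard_normal(4)
    M = rng.standard_normal((4, 4))
    gamma = M + M.T
    assert rate_of_adaptation(G, beta, gamma) == pytest.approx(
        fitness_surface_oracle(G, beta, gamma), abs=1e-10)


# ---------- relative_rate_of_adaptation ----------

def test_diagonal_G_gives_one():
    rng = np.random.default_rng(2)
    G = np.diag(rng.uniform(0.5, 2.0, 4))
    beta = rng.standard_normal(4)
    M = rng.standard_normal((4, 4))
    assert relative_rate_of_adaptation(G, beta, M + M.T) == pytest.approx(1.0)


def test_worked_two_trait_case():
    G = np.array([[1.0, 0.9], [0.9, 1.0]])
    beta = np.array([1.0, -1.0])
    assert relative_rate_of_adaptation(G, beta, np.zeros((2, 2))) == pytest.approx(0.1)


def test_gull_point_RA_inside_published_interval():
    ra = relative_rate_of_adaptation(point_G("red_billed_gull"), POINT_BETA["red_billed_gull"])
    assert 0.446 < ra < 1.305


def test_zero_denominator_errors():
    G = np.array([[0.0, 0.0], [0.0, 1.0]])
    with pytest.raises(ZeroDivisionError):
        relative_rate_of_adaptation(G, np.array([1.0, 0.0]))


# ---------- evolvability ----------

def test_ebeta_identity():
    rng = np.random.default_rng(3)
    beta = rng.standard_normal(4)
    assert evolvability_beta(np.eye(4), beta) == pytest.approx(1.0)


def test_ebeta_along_eigenvector():
    rng = np.random.default_rng(4)
    G = random_pd(4, rng)
    w, V = np.linalg.eigh(G)
    assert evolvability_beta(G, V[:, -1]) == pytest.approx(w[-1])


def test_gull_ebeta_inside_published_interval():
    e = evolvability_beta(point_G("red_billed_gull"), POINT_BETA["red_billed_gull"])
    assert 0.0208 < e < 0.0533


def test_ebeta_zero_beta_errors():
    with pytest.raises(ValueError):
        evolvability_beta(np.eye(2), np.zeros(2))


def test_average_evolvability_identity():
    assert average_evolvability(np.eye(4)) == pytest.approx(1.0)


def test_gull_average_evolvability():
    assert average_evolvability(point_G("red_billed_gull")) == pytest.approx(0.0554, rel=0.01)


def test_average_evolvability_matches_mc_oracle():
    rng = np.random.default_rng(5)
    G = random_pd(4, rng)
    assert average_evolvability(G) == pytest.approx(mc_average_evolvability_oracle(G), rel=0.01)


# ---------- gmax ----------

def test_gmax_diagonal():
    d = gmax(np.diag([4.0, 3.0, 2.0, 1.0]))
    assert d.percent_variance == pytest.approx(40.0)
    np.testing.assert_allclose(d.g_max, [1, 0, 0, 0], atol=1e-12)


def test_gull_gmax_published():
    d = gmax(point_G("red_billed_gull"))
    assert d.percent_variance == pytest.approx(63.4, rel=0.01)
    assert d.g_max[2] == pytest.approx(0.839, abs=0.01)


@pytest.mark.parametrize("seed", range(5))
def test_gmax_matches_power_iteration(seed):
    rng = np.random.default_rng(seed)
    G = random_pd(5, rng)
    d = gmax(G)
    lam, v = power_iteration_oracle(G)
    assert d.eigenvalues[0] == pytest.approx(lam, abs=1e-8)
    assert abs(float(v @ d.g_max)) > 1 - 1e-8


def test_gmax_unit_norm_and_orientation():
    rng = np.random.default_rng(7)
    for _ in range(10):
        d = gmax(random_pd(4, rng))
        assert np.linalg.norm(d.g_max) == pytest.approx(1.0)
        assert d.g_max.sum() > 0
        assert np.all(np.diff(d.eigenvalues) <= 1e-12)
        assert 0 < d.percent_variance <= 100


def test_gmax_tie_warning():
    with pytest.warns(UserWarning, match="degenerate"):
        gmax(np.eye(3))


# ---------- angle ----------

def test_angle_aligned_and_orthogonal():
    G = np.diag([4.0, 1.0])
    assert angle_gmax_beta(G, np.array([2.0, 0.0])) == pytest.approx(0.0)
    assert angle_gmax_beta(G, np.array([0.0, -3.0])) == pytest.approx(90.0)


def test_fold_rule():
    assert fold_angle(120.0) == pytest.approx(60.0)
    assert fold_angle(45.0) == pytest.approx(45.0)


def test_angle_zero_implies_ebeta_lambda1():
    rng = np.random.default_rng(8)
    G = random_pd(4, rng)
    d = gmax(G)
    beta = 2.5 * d.g_max
    assert angle_gmax_beta(G, beta) == pytest.approx(0.0, abs=1e-6)
    assert evolvability_beta(G, beta) == pytest.approx(d.eigenvalues[0], abs=1e-10)


# ---------- invariants over random matrices ----------

@pytest.mark.parametrize("seed", range(10))
def test_rayleigh_bounds_and_reordering_invariance(seed):
    rng = np.random.default_rng(seed)
    t = 4
    G = random_pd(t, rng)
    beta = rng.standard_normal(t)
    M = rng.standard_normal((t, t))
    gamma = M + M.T
    w = np.linalg.eigvalsh(G)
    e = evolvability_beta(G, beta)
    assert w[0] - 1e-10 <= e <= w[-1] + 1e-10
    assert w[0] - 1e-10 <= average_evolvability(G) <= w[-1] + 1e-10
    theta = angle_gmax_beta(G, beta)
    assert 0.0 <= theta <= 90.0
    # simultaneous reordering leaves all metrics unchanged
    perm = rng.permutation(t)
    Gp, bp, gp = G[np.ix_(perm, perm)], beta[perm], gamma[np.ix_(perm, perm)]
    assert relative_rate_of_adaptation(Gp, bp, gp) == pytest.approx(
        relative_rate_of_adaptation(G, beta, gamma), rel=1e-10)
    assert evolvability_beta(Gp, bp) == pytest.approx(e, rel=1e-10)
    assert average_evolvability(Gp) == pytest.approx(average_evolvability(G), rel=1e-12)
    assert angle_gmax_beta(Gp, bp) == pytest.approx(theta, abs=1e-8)


def test_RA_one_iff_diagonal():
    rng = np.random.default_rng(11)
    G = random_pd(4, rng)
    beta = rng.standard_normal(4)
    Gd = np.diag(np.diag(G))
    assert relative_rate_of_adaptation(Gd, beta) == pytest.approx(1.0)


# ---------- propagate ----------

def make_chains(S=150, t=4, seed=0):
    rng = np.random.default_rng(seed)
    G = np.stack([random_pd(t, rng, scale=0.001) for _ in range(S)])
    beta = rng.standard_normal((S, t))
    M = rng.standard_normal((S, t, t))
    gamma = M + np.transpose(M, (0, 2, 1))
    return G, beta, gamma


def test_propagate_identical_samples_degenerate_ci():
    G, beta, gamma = make_chains(S=120, seed=1)
    Gc = np.repeat(G[:1], 120, axis=0)
    bc = np.repeat(beta[:1], 120, axis=0)
    gc = np.repeat(gamma[:1], 120, axis=0)
    post = propagate(Gc, bc, gc, population="const")
    s = post.summary().set_index("metric")
    assert s.loc["R_A", "lo95"] == pytest.approx(s.loc["R_A", "hi95"])


def test_propagate_ps_all_below_one():
    G, beta, gamma = make_chains(seed=2)
    post = propagate(G, beta, None)
    forced = propagate(G, beta, None)
    forced.R_A = np.clip(post.R_A, None, 0.99)
    assert forced.ps_constraint == 100.0


def test_propagate_theta_bounds():
    G, beta, gamma = make_chains(seed=3)
    post = propagate(G, beta, gamma)
    assert np.all(post.theta_gmax >= 0) and np.all(post.theta_gmax <= 90)


def test_propagate_length_mismatch_errors():
    G, beta, gamma = make_chains(seed=4)
    with pytest.raises(ValueError):
        propagate(G[:-5], beta, gamma)


# ---------- meta_geometric_mean ----------

class FakePost:
    def __init__(self, x):
        self.R_A = np.asarray(x, dtype=float)


def test_meta_constant_pair():
    res = meta_geometric_mean([FakePost(np.full(200, 0.5)), FakePost(np.full(200, 2.0))])
    assert res["mode"] == pytest.approx(1.0)


def test_meta_all_ones():
    res = meta_geometric_mean([FakePost(np.ones(200))] * 3)
    assert res["mode"] == pytest.approx(1.0)


def test_meta_excludes_nonpositive():
    a = np.full(200, 0.8)
    b = np.full(200, 0.8)
    b[:5] = -1.0
    with pytest.warns(UserWarning, match="excluded"):
        res = meta_geometric_mean([FakePost(a), FakePost(b)])
    assert res["n_excluded"] == 5


def test_meta_requires_two():
    with pytest.raises(ValueError):
        meta_geometric_mean([FakePost(np.ones(100))])
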