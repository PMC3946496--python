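"""Constraint and evolvability metrics computed from G, beta and gamma.

All operations act on a single (G, beta, gamma) triple; ``propagate``
maps them over paired posterior samples so that every summary carries
full posterior uncertainty.

Conventions: the quadratic selection matrix gamma is taken in the
*doubled* convention (diagonal = 2x raw quadratic regression
coefficients). Variances and evolvabilities are reported x100, angles in
degrees, proportions of support in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from qgconstraints.summarize import hdi, posterior_mode, summarize_samples


def _check_square(G, name="G"):
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    return G


def predicted_response(G, beta, univariate: bool = False) -> np.ndarray:
    """One-generation response to selection from the breeder's equation.

    Multivariate: dz = G @ beta. Univariate: covariances ignored,
    dz_i = G_ii * beta_i.
    """
    G = _check_square(G)
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != G.shape[0]:
        raise ValueError("beta dimension does not match G")
    if univariate:
        return np.diag(G) * beta
    return G @ beta


def rate_of_adaptation(G, beta, gamma=None) -> float:
    """Second-order predicted fitness change from one generation of response.

    With dz = G beta: beta' dz + 0.5 * dz' gamma dz. ``gamma`` must be in
    the doubled convention (or None/zero for purely directional selection).
    """
    G = _check_square(G)
    beta = np.asarray(beta, dtype=float).ravel()
    dz = G @ beta
    out = float(beta @ dz)
    if gamma is not None:
        gamma = _check_square(np.asarray(gamma, dtype=float), "gamma")
        out += 0.5 * float(dz @ gamma @ dz)
    return out


def relative_rate_of_adaptation(G, beta, gamma=None) -> float:
    """Ratio of the rate of adaptation with vs. without genetic covariances.

    Denominator uses diag(G). A value below 1 means the covariances slow
    adaptation down.
    """
    G = _check_square(G)
    num = rate_of_adaptation(G, beta, gamma)
    den = rate_of_adaptation(np.diag(np.diag(G)), beta, gamma)
    if den == 0.0:
        raise ZeroDivisionError("rate of adaptation without covariances is zero")
    return num / den


def evolvability_beta(G, beta) -> float:
    """Genetic variance available in the exact direction of selection.

    e_beta = beta' G beta / (beta' beta); equals the Rayleigh quotient of
    G along beta, so it is bounded by the extreme eigenvalues.
    """
    G = _check_square(G)
    beta = np.asarray(beta, dtype=float).ravel()
    bb = float(beta @ beta)
    if bb == 0.0:
        raise ValueError("beta is zero")
    return float(beta @ G @ beta) / bb


def average_evolvability(G) -> float:
    """Expected evolvability over uniformly random directions: trace(G)/t."""
    G = _check_square(G)
    return float(np.trace(G)) / G.shape[0]


@dataclass
class GmaxDecomposition:
    """Eigendecomposition of G with the leading axis sign-oriented."""

    eigenvalues: np.ndarray  # non-increasing
    g_max: np.ndarray  # unit leading eigenvector, loading sum > 0
    percent_variance: float  # 100 * lambda_1 / sum(lambda)

    @property
    def loadings(self) -> np.ndarray:
        return self.g_max


def gmax(G, tie_tol: float = 1e-10) -> GmaxDecomposition:
    """Leading-axis decomposition of a symmetric PSD matrix.

    The leading eigenvector is normalized and sign-flipped so the sum of
    its loadings is positive. A (near-)tied leading eigenvalue is broken
    deterministically by lexicographic loading order, with a warning.
    """
    import warnings

    G = _check_square(G)
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    v = V[:, 0]
    if G.shape[0] > 1 and abs(w[0] - w[1]) <= tie_tol * max(1.0, abs(w[0])):
        warnings.warn("leading eigenvalue is (near-)degenerate; tie broken lexicographically", stacklevel=2)
        tied = np.flatnonzero(np.abs(w - w[0]) <= tie_tol * max(1.0, abs(w[0])))
        cands = sorted((tuple(np.round(V[:, k], 12)), k) for k in tied)
        v = V[:, cands[0][1]]
    if v.sum() < 0:
        v = -v
    total = float(w.sum())
    return GmaxDecomposition(eigenvalues=w, g_max=v, percent_variance=100.0 * float(w[0]) / total)


def angle_gmax_beta(G, beta) -> float:
    """Angle in degrees between the leading axis of G and beta, folded to [0, 90]."""
    beta = np.asarray(beta, dtype=float).ravel()
    nb = np.linalg.norm(beta)
    if nb == 0.0:
        raise ValueError("beta is zero")
    v = gmax(G).g_max
    c = float(v @ beta) / nb
    c = np.clip(c, -1.0, 1.0)
    theta = np.degrees(np.arccos(c))
    if theta > 90.0:
        theta = 180.0 - theta
    return float(theta)


def fold_angle(theta_degrees: float) -> float:
    """Fold an angle into [0, 90] (axes have no sign)."""
    theta = float(theta_degrees) % 180.0
    return 180.0 - theta if theta > 90.0 else theta


METRIC_SCALE = 100.0  # variances/evolvabilities reported x100


@dataclass
class ConstraintPosterior:
    """Per-sample constraint metrics for one population.

    Arrays are indexed by posterior sample. Evolvabilities are on the
    same scale as the input G samples; ``summary`` applies the x100
    reporting scale for variance-like quantities.
    """

    population: str
    R_A: np.ndarray
    e_beta: np.ndarray
    e_mean: np.ndarray
    theta_gmax: np.ndarray
    percent_gmax: np.ndarray
    lambda1: np.ndarray
    loadings: np.ndarray  # (S, t)
    response_multi: np.ndarray  # (S, t)
    response_uni: np.ndarray  # (S, t)
    trait_names: tuple

    def __len__(self) -> int:
        return len(self.R_A)

    @property
    def ps_constraint(self) -> float:
        """Percentage of samples with R_A < 1."""
        return 100.0 * float(np.mean(self.R_A < 1.0))

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        rows = []

        def add(metric, x, scale=1.0):
            s = summarize_samples(np.asarray(x) * scale, prob)
            rows.append({"population": self.population, "metric": metric,
                         "mode": s["mode"], "lo95": s["lo95"], "hi95": s["hi95"]})

        add("R_A", self.R_A)
        add("e_beta", self.e_beta, METRIC_SCALE)
        add("e_mean", self.e_mean, METRIC_SCALE)
        add("theta_gmax", self.theta_gmax)
        add("percent_gmax", self.percent_gmax)
        add("lambda1", self.lambda1, METRIC_SCALE)
        for k, name in enumerate(self.trait_names):
            add(f"loading_{name}", self.loadings[:, k])
            add(f"response_multi_{name}", self.response_multi[:, k], METRIC_SCALE)
            add(f"response_uni_{name}", self.response_uni[:, k], METRIC_SCALE)
        df = pd.DataFrame(rows)
        ps = pd.DataFrame([{"population": self.population, "metric": "PS_RA_lt_1",
                            "mode": self.ps_constraint, "lo95": np.nan, "hi95": np.nan}])
        return pd.concat([df, ps], ignore_index=True)


def propagate(G_samples, beta_samples, gamma_samples=None, population: str = "",
              trait_names=None) -> ConstraintPosterior:
    """Compute every constraint metric per paired posterior sample.

    ``G_samples`` is (S, t, t); ``beta_samples`` is (S, t);
    ``gamma_samples`` is (S, t, t) in the doubled convention or None.
    Pairing is index-wise, so chains must have equal length.
    """
    G_samples = np.asarray(G_samples, dtype=float)
    beta_samples = np.asarray(beta_samples, dtype=float)
    S, t = beta_samples.shape
    if G_samples.shape != (S, t, t):
        raise ValueError(f"chain length mismatch: G {G_samples.shape}, beta {beta_samples.shape}")
    if gamma_samples is not None:
        gamma_samples = np.asarray(gamma_samples, dtype=float)
        if gamma_samples.shape != (S, t, t):
            raise ValueError("gamma chain does not match")
    if trait_names is None:
        trait_names = tuple(f"trait{k+1}" for k in range(t))
    out = {k: np.empty(S) for k in ("R_A", "e_beta", "e_mean", "theta_gmax", "percent_gmax", "lambda1")}
    loadings = np.empty((S, t))
    resp_m = np.empty((S, t))
    resp_u = np.empty((S, t))
    for s in range(S):
        G, b = G_samples[s], beta_samples[s]
        g = gamma_samples[s] if gamma_samples is not None else None
        out["R_A"][s] = relative_rate_of_adaptation(G, b, g)
        out["e_beta"][s] = evolvability_beta(G, b)
        out["e_mean"][s] = average_evolvability(G)
        dec = gmax(G)
        out["theta_gmax"][s] = fold_angle(np.degrees(np.arccos(np.clip(dec.g_max @ b / np.linalg.norm(b), -1, 1))))
        out["percent_gmax"][s] = dec.percent_variance
        out["lambda1"][s] = dec.eigenvalues[0]
        loadings[s] = dec.g_max
        resp_m[s] = predicted_response(G, b)
        resp_u[s] = predicted_response(G, b, univariate=True)
    return ConstraintPosterior(population=population, trait_names=tuple(trait_names),
                               loadings=loadings, response_multi=resp_m, response_uni=resp_u,
                               **out)


def meta_geometric_mean(posteriors, metric: str = "R_A", prob: float = 0.95) -> dict:
    """Across-population geometric mean of a positive metric, per iteration.

    For each posterior-sample index the geometric mean is taken across
    populations; the resulting chain is summarized by mode and HDI.
    Samples where any population is non-positive are excluded (counted).
    """
    if len(posteriors) < 2:
        raise ValueError("need at least two populations")
    mats = np.stack([np.asarray(getattr(p, metric), dtype=float) for p in posteriors])
    lengths = {m.shape[0] for m in mats}
    if len(lengths) != 1:
        raise ValueError("posterior chains have different lengths")
    ok = np.all(mats > 0, axis=0)
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        import warnings

        warnings.warn(f"excluded {n_excluded} iteration(s) with non-positive {metric}", stacklevel=2)
    if not np.any(ok):
        raise ValueError("no iteration with all-positive metric values")
    gm = np.exp(np.mean(np.log(mats[:, ok]), axis=0))
    lo, hi = hdi(gm, prob)
    return {"metric": metric, "mode": posterior_mode(gm), "mean": float(gm.mean()),
            "lo95": lo, "hi95": hi, "n_excluded": n_excluded, "samples": gm}
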