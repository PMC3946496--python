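"""Lande-Arnold selection gradients with posterior uncertainty.

Directional gradients beta come from the linear-terms-only regression of
relative fitness on the processed traits; the quadratic/correlational
matrix gamma comes from the full quadratic model (linear + squared +
pairwise products). Both are Bayesian normal linear regressions with
flat coefficient priors and a weakly informative inverse-gamma residual
prior, so the posterior is sampled exactly (no MCMC). Quadratic
regression coefficients are doubled in the stored gamma so its diagonal
is on the selection-gradient scale; an un-doubled view is kept for
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from qgconstraints.animal_model import MCMCSettings
from qgconstraints.phenotypes import SelectionTable
from qgconstraints.summarize import hdi, posterior_mode

RESIDUAL_PRIOR_SHAPE = 0.001  # inverse-gamma a0
RESIDUAL_PRIOR_SCALE = 0.001  # inverse-gamma b0


@dataclass
class SelectionPosterior:
    """Per-sample directional (beta) and quadratic (gamma) gradients.

    ``gamma`` is stored in the doubled convention (diagonal = 2x the raw
    quadratic regression coefficient); ``gamma_raw`` keeps the un-doubled
    coefficients for table-style reporting.
    """

    beta: np.ndarray        # (S, t)
    gamma: np.ndarray       # (S, t, t), doubled diagonal
    gamma_raw: np.ndarray   # (S, t, t), un-doubled diagonal
    trait_names: tuple
    doubled: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.beta) < 100:
            raise ValueError("selection posterior needs >= 100 samples")
        if not self.doubled:
            raise ValueError("gamma must be stored in the doubled convention")

    def __len__(self) -> int:
        return len(self.beta)

    def to_frame(self) -> pd.DataFrame:
        names = list(self.trait_names)
        t = len(names)
        cols = {f"beta.{n}": self.beta[:, k] for k, n in enumerate(names)}
        for i in range(t):
            for j in range(i, t):
                cols[f"gamma.{names[i]}.{names[j]}"] = self.gamma[:, i, j]
        return pd.DataFrame(cols)

    def save(self, prefix) -> None:
        import json

        prefix = str(prefix)
        self.to_frame().to_csv(prefix + ".csv", index=False)
        meta = dict(self.metadata)
        meta.update({"trait_names": list(self.trait_names), "doubled": self.doubled,
                     "n_samples": len(self)})
        with open(prefix + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


def _bayes_lm(rng: np.random.Generator, X: np.ndarray, y: np.ndarray, n_samples: int,
              names: list[str]) -> np.ndarray:
    """Exact posterior draws for normal regression with flat coefficient prior.

    sigma^2 ~ IG(a0 + (n-k)/2, b0 + SSR/2); coef | sigma^2 ~ N(betahat, sigma^2 (X'X)^-1).
    """
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more than {k} complete rows, got {n}")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    if np.any(diag < 1e-10 * diag.max()):
        bad = [names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"rank-deficient selection design; aliased columns: {bad}")
    bhat = linalg.solve_triangular(r, q.T @ y, lower=False)
    ssr = float(np.sum((y - X @ bhat) ** 2))
    a_post = RESIDUAL_PRIOR_SHAPE + 0.5 * (n - k)
    b_post = RESIDUAL_PRIOR_SCALE + 0.5 * ssr
    sigma2 = b_post / rng.gamma(a_post, 1.0, size=n_samples)
    z = rng.standard_normal((n_samples, k))
    # coef = bhat + sigma * R^-1 z
    coefs = bhat[None, :] + np.sqrt(sigma2)[:, None] * linalg.solve_triangular(r, z.T, lower=False).T
    return coefs


def fit_selection_gradients(table: SelectionTable, settings: MCMCSettings) -> SelectionPosterior:
    """Posterior samples of beta and gamma from a prepared selection table.

    The number of samples equals ``settings.n_samples`` so the posterior
    pairs index-wise with an animal-model chain run under the same
    settings.
    """
    rng = np.random.default_rng(settings.seed)
    t = len(table.traits)
    S = settings.n_samples

    X_lin, w, names_lin = table.design(quadratic=False)
    beta_draws = _bayes_lm(rng, X_lin, w, S, names_lin)[:, 1 : t + 1]

    X_quad, _, names_quad = table.design(quadratic=True)
    quad_draws = _bayes_lm(rng, X_quad, w, S, names_quad)
    gamma_raw = np.zeros((S, t, t))
    pos = 1 + t
    for i in range(t):
        gamma_raw[:, i, i] = quad_draws[:, pos]
        pos += 1
    for i in range(t):
        for j in range(i + 1, t):
            gamma_raw[:, i, j] = quad_draws[:, pos]
            gamma_raw[:, j, i] = quad_draws[:, pos]
            pos += 1
    gamma = gamma_raw.copy()
    diag = np.arange(t)
    gamma[:, diag, diag] *= 2.0

    return SelectionPosterior(
        beta=beta_draws, gamma=gamma, gamma_raw=gamma_raw,
        trait_names=tuple(table.traits), doubled=True,
        metadata={"n_rows": len(table), "seed": settings.seed, "n_samples": S},
    )


def beta_norm(post: SelectionPosterior) -> np.ndarray:
    """Euclidean norm of beta per posterior sample."""
    return np.linalg.norm(post.beta, axis=1)


def significance_summary(post: SelectionPosterior, prob: float = 0.95) -> pd.DataFrame:
    """Mode, HDI and a CI-excludes-zero flag per coefficient.

    Quadratic coefficients are reported un-doubled, matching the usual
    table convention.
    """
    names = list(post.trait_names)
    t = len(names)
    rows = []

    def add(label, x):
        lo, hi = hdi(x, prob)
        rows.append({"coefficient": label, "mode": posterior_mode(x), "lo95": lo,
                     "hi95": hi, "significant": bool(lo > 0 or hi < 0)})

    add("||beta||", beta_norm(post))
    rows[-1]["significant"] = False  # a norm is non-negative by construction
    for k, n in enumerate(names):
        add(n, post.beta[:, k])
    for i in range(t):
        add(f"{names[i]}^2", post.gamma_raw[:, i, i])
    for i in range(t):
        for j in range(i + 1, t):
            add(f"{names[i]}:{names[j]}", post.gamma_raw[:, i, j])
    return pd.DataFrame(rows)
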