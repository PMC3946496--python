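"""Posterior summaries: KDE mode, highest-density intervals, chain tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def posterior_mode(samples) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a 512-point grid.

    Constant samples return that constant.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no samples")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return lo
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def hdi(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("no samples")
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def summarize_samples(x, prob: float = 0.95) -> dict:
    """mode / mean / HDI / effective sample size for one scalar chain."""
    x = np.asarray(x, dtype=float).ravel()
    lo, hi = hdi(x, prob)
    return {
        "mode": posterior_mode(x),
        "mean": float(x.mean()),
        "lo95": lo,
        "hi95": hi,
        "ess": effective_sample_size(x),
    }


def effective_sample_size(x) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    v = float(np.var(x))
    if n < 3 or v <= 1e-300:
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * v)
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


REPORT_SCALE = 100.0


def summarize_posterior(chain, std=None, prob: float = 0.95) -> pd.DataFrame:
    """Tidy summary of a fitted multivariate animal-model chain.

    Per distinct G element: posterior mode, HDI and ESS on the x100
    reporting scale. Per trait: the mean-standardized additive variance
    x100 and the heritability V_A / (V_A + V_PE + V_year + V_R) computed
    per sample and then summarized.
    """
    t = chain.n_traits
    names = list(chain.trait_names)
    rows = []
    G = chain.G  # (S, t, t)
    for i in range(t):
        for j in range(i, t):
            x = G[:, i, j] * REPORT_SCALE
            label = names[i] if i == j else f"{names[i]}:{names[j]}"
            kind = "IA_evolvability" if i == j else "genetic_covariance"
            rows.append({"element": label, "quantity": kind, **summarize_samples(x, prob)})
    total = chain.G + chain.P_pe + chain.P_year + chain.R
    for i in range(t):
        h2 = G[:, i, i] / total[:, i, i]
        rows.append({"element": names[i], "quantity": "heritability", **summarize_samples(h2, prob)})
    return pd.DataFrame(rows)
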