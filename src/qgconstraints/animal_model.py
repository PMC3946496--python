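"""Bayesian multivariate animal model fitted by Gibbs sampling.

The model for record j of individual i measured in year y is

    y_j = B' x_j + a_i + pe_i + yr_y + e_j

with t-variate effects a ~ N(0, G (x) A), pe ~ N(0, P_pe (x) I),
yr ~ N(0, P_year (x) I), e ~ N(0, R (x) I) and an effectively flat
normal prior on the fixed effects B. Covariance matrices get conjugate
inverse-Wishart updates; missing trait values are data-augmented from
their conditional normal (missing at random). Location effects are
updated per level with all traits drawn jointly; breeding values use the
sparse pedigree precision A^-1 built by Henderson's rules.

Two prior families are supported: a slightly informative inverse-Wishart
prior (scale nu*V, df nu) and a parameter-expanded prior in which each
random term's effects are scaled by a working parameter vector alpha with
a normal prior, yielding a heavier-tailed marginal prior on variances.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from qgconstraints import _kernels
from qgconstraints.pedigree import Pedigree, RelatednessMatrix, a_inverse
from qgconstraints.phenotypes import FixedDesign, ObservationTable

FIXED_EFFECT_PRIOR_VARIANCE = 1e10
DEFAULT_ALPHA_VARIANCE = 625.0

INFORMATIVE = "informative"
PARAMETER_EXPANDED = "parameter_expanded"


@dataclass
class PriorSpec:
    """Covariance prior applied to every random term and the residual.

    ``family`` is 'informative' or 'parameter_expanded'. The
    inverse-Wishart prior has scale nu*V and degrees of freedom nu
    (proper for nu > t - 1 with V positive definite). For the
    parameter-expanded family V is the working-covariance scale and
    ``alpha_variance`` the prior variance of the working parameters.
    """

    family: str
    V: np.ndarray
    nu: float
    alpha_variance: float = DEFAULT_ALPHA_VARIANCE
    residual_V: np.ndarray | None = None  # residual term prior scale; defaults to V

    def __post_init__(self) -> None:
        if self.family not in (INFORMATIVE, PARAMETER_EXPANDED):
            raise ValueError(f"unknown prior family {self.family!r}")
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        t = self.V.shape[0]
        if not np.allclose(self.V, self.V.T):
            raise ValueError("prior scale V must be symmetric")
        if np.any(np.linalg.eigvalsh(self.V) <= 0):
            raise ValueError("prior scale V must be positive definite")
        if self.nu <= t - 1:
            raise ValueError("nu must exceed t - 1 for a proper prior")
        if self.residual_V is not None:
            self.residual_V = np.atleast_2d(np.asarray(self.residual_V, dtype=float))
            if self.residual_V.shape != self.V.shape:
                raise ValueError("residual_V must match V in shape")

    @property
    def n_traits(self) -> int:
        return self.V.shape[0]

    @property
    def scale(self) -> np.ndarray:
        """Inverse-Wishart scale matrix nu * V for the random terms."""
        return self.nu * self.V

    @property
    def residual_scale(self) -> np.ndarray:
        """Inverse-Wishart scale for the residual term (never expanded)."""
        V = self.V if self.residual_V is None else self.residual_V
        return self.nu * V


def default_informative_prior(t: int, Vp, r: int) -> PriorSpec:
    """Slightly informative prior: V = diag(Vp)/r, nu = t.

    ``Vp`` is the phenotypic variance (scalar or length-t diagonal) and
    ``r`` the number of random terms the variance is split across.
    """
    if t < 1 or r < 1:
        raise ValueError("t and r must be >= 1")
    Vp = np.asarray(Vp, dtype=float).ravel()
    if Vp.size == 1:
        Vp = np.repeat(Vp, t)
    if Vp.size != t:
        raise ValueError("Vp must be scalar or length t")
    if np.any(Vp <= 0):
        raise ValueError("phenotypic variances must be positive")
    return PriorSpec(family=INFORMATIVE, V=np.diag(Vp) / r, nu=float(t))


def parameter_expanded_prior(t: int, Vp=None, r: int = 1,
                             alpha_variance: float = DEFAULT_ALPHA_VARIANCE) -> PriorSpec:
    """Parameter-expanded prior: working scale V = I, nu = t, alpha ~ N(0, alpha_variance).

    The residual term is never expanded; if the phenotypic variance ``Vp``
    is given it receives the slightly informative scale diag(Vp)/r so the
    residual prior sits on the data scale.
    """
    residual_V = None if Vp is None else np.diag(np.broadcast_to(np.asarray(Vp, dtype=float).ravel(), (t,)) / r)
    return PriorSpec(family=PARAMETER_EXPANDED, V=np.eye(t), nu=float(t),
                     alpha_variance=float(alpha_variance), residual_V=residual_V)


@dataclass
class MCMCSettings:
    """Chain length controls. (iterations - burn_in) / thinning >= 100."""

    iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_samples < 100:
            raise ValueError("(iterations - burn_in)/thinning must be >= 100")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


def paper_scale_settings(seed: int = 0) -> MCMCSettings:
    """Long-run settings: 1.2M iterations, 200k burn-in, thin 1000."""
    return MCMCSettings(iterations=1_200_000, burn_in=200_000, thinning=1_000, seed=seed)


@dataclass
class PosteriorSample:
    G: np.ndarray
    P_pe: np.ndarray
    P_year: np.ndarray
    R: np.ndarray
    B: np.ndarray


@dataclass
class PosteriorChain:
    """Thinned posterior samples of all covariance matrices and fixed effects."""

    G: np.ndarray       # (S, t, t)
    P_pe: np.ndarray
    P_year: np.ndarray
    R: np.ndarray
    B: np.ndarray       # (S, p, t)
    trait_names: tuple
    fixed_columns: list
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.G.shape[0]

    def __getitem__(self, s: int) -> PosteriorSample:
        return PosteriorSample(self.G[s], self.P_pe[s], self.P_year[s], self.R[s], self.B[s])

    @property
    def n_traits(self) -> int:
        return self.G.shape[1]

    @property
    def fixed_effect_means(self) -> np.ndarray:
        """Posterior-mean fixed-effect coefficients, (p, t)."""
        return self.B.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        t = self.n_traits
        names = list(self.trait_names)
        cols = {}
        for label, arr in (("G", self.G), ("PE", self.P_pe), ("YR", self.P_year), ("R", self.R)):
            for i in range(t):
                for j in range(i, t):
                    cols[f"{label}.{names[i]}.{names[j]}"] = arr[:, i, j]
        for p, cname in enumerate(self.fixed_columns):
            for k in range(t):
                cols[f"B.{cname}.{names[k]}"] = self.B[:, p, k]
        return pd.DataFrame(cols)

    def save(self, prefix) -> None:
        prefix = str(prefix)
        self.to_frame().to_csv(prefix + ".csv", index=False)
        meta = dict(self.metadata)
        meta["trait_names"] = list(self.trait_names)
        meta["fixed_columns"] = list(self.fixed_columns)
        meta["n_samples"] = len(self)
        with open(prefix + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)

    @classmethod
    def load(cls, prefix) -> "PosteriorChain":
        prefix = str(prefix)
        df = pd.read_csv(prefix + ".csv")
        with open(prefix + ".json") as fh:
            meta = json.load(fh)
        names = meta["trait_names"]
        fixed = meta["fixed_columns"]
        t, S = len(names), len(df)
        out = {}
        for label in ("G", "PE", "YR", "R"):
            arr = np.empty((S, t, t))
            for i in range(t):
                for j in range(i, t):
                    v = df[f"{label}.{names[i]}.{names[j]}"].to_numpy()
                    arr[:, i, j] = v
                    arr[:, j, i] = v
            out[label] = arr
        B = np.empty((S, len(fixed), t))
        for p, cname in enumerate(fixed):
            for k in range(t):
                B[:, p, k] = df[f"B.{cname}.{names[k]}"].to_numpy()
        return cls(G=out["G"], P_pe=out["PE"], P_year=out["YR"], R=out["R"], B=B,
                   trait_names=tuple(names), fixed_columns=fixed, metadata=meta)


def _sample_invwishart(rng: np.random.Generator, Psi: np.ndarray, df: float) -> np.ndarray:
    """Draw from IW(Psi, df) via the Bartlett decomposition."""
    p = Psi.shape[0]
    L = cholesky(Psi, lower=True)
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
    idx = np.tril_indices(p, k=-1)
    A[idx] = rng.standard_normal(len(idx[0]))
    M = solve_triangular(A, L.T, lower=True)
    S = M.T @ M
    return 0.5 * (S + S.T)


def _csr_groups(codes: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style (ptr, record-index) grouping of records by integer code."""
    order = np.argsort(codes, kind="stable").astype(np.int64)
    counts = np.bincount(codes, minlength=n_groups)
    ptr = np.zeros(n_groups + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return ptr, order


def _missing_patterns(miss: np.ndarray):
    """Group records by missingness pattern for the imputation kernel."""
    n, t = miss.shape
    codes = miss @ (1 << np.arange(t))
    has_missing = codes > 0
    uniq = np.unique(codes[has_missing])
    n_pat = len(uniq)
    miss_idx = np.full((max(n_pat, 1), t), -1, dtype=np.int64)
    obs_idx = np.full((max(n_pat, 1), t), -1, dtype=np.int64)
    miss_n = np.zeros(max(n_pat, 1), dtype=np.int64)
    obs_n = np.zeros(max(n_pat, 1), dtype=np.int64)
    ptr = np.zeros(max(n_pat, 1) + 1, dtype=np.int64)
    recs = []
    for p, code in enumerate(uniq):
        pat = (code >> np.arange(t)) & 1
        mi = np.flatnonzero(pat == 1)
        oi = np.flatnonzero(pat == 0)
        miss_n[p] = len(mi)
        obs_n[p] = len(oi)
        miss_idx[p, : len(mi)] = mi
        obs_idx[p, : len(oi)] = oi
        members = np.flatnonzero(codes == code)
        recs.append(members)
        ptr[p + 1] = ptr[p] + len(members)
    rec = np.concatenate(recs).astype(np.int64) if recs else np.zeros(0, dtype=np.int64)
    return n_pat, miss_idx, miss_n, obs_idx, obs_n, ptr, rec


def _digest(*arrays) -> str:
    h = hashlib.sha256()
    for arr in arrays:
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def fit_animal_model(obs_std: ObservationTable, design: FixedDesign, relatedness,
                     prior: PriorSpec, settings: MCMCSettings,
                     include_pe: bool = True, include_year: bool = True,
                     prior_only: bool = False, progress: bool = False) -> PosteriorChain:
    """Fit the multivariate animal model by Gibbs sampling.

    ``relatedness`` is the Pedigree the A matrix derives from (preferred;
    A^-1 is then built sparsely by Henderson's rules). Every observed
    individual must be in the pedigree. ``prior_only`` masks all
    responses so the chain samples the prior (for calibration checks).
    """
    if not isinstance(relatedness, Pedigree):
        raise TypeError("relatedness must be a Pedigree (A^-1 is built from its structure)")
    ped = relatedness
    df = obs_std.data
    traits = obs_std.traits
    t = len(traits)
    n_rec = len(df)

    ids = df["id"].astype(str).to_numpy()
    try:
        anim_idx = np.array([ped.index_of(i) for i in ids], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"observed individual {exc.args[0]!r} is not in the pedigree") from exc

    years = df["year"].to_numpy()
    year_levels = np.unique(years)
    if include_year and len(year_levels) < 2:
        raise ValueError("year term requires records from at least 2 years; "
                         "refit with include_year=False")
    yr_idx = np.searchsorted(year_levels, years).astype(np.int64)
    n_year = len(year_levels)

    pe_levels, pe_idx = np.unique(anim_idx, return_inverse=True)
    pe_idx = pe_idx.astype(np.int64)
    n_pe = len(pe_levels)
    if include_pe and np.bincount(pe_idx).max() < 2:
        raise ValueError("permanent-environment term is unidentifiable without repeated "
                         "measures; refit with include_pe=False")

    X = np.asarray(design.matrix, dtype=float)
    if X.shape[0] != n_rec:
        raise ValueError("design matrix rows do not match observation rows")
    p = X.shape[1]
    if prior.n_traits != t:
        raise ValueError("prior dimension does not match trait count")

    Y = df[list(traits)].to_numpy(dtype=float).copy()
    miss = np.isnan(Y)
    if prior_only:
        miss = np.ones_like(miss)
    observed_digest = _digest(np.nan_to_num(Y), anim_idx, yr_idx, X)

    # fill starting values for augmented entries
    col_means = np.ones(t)
    for k in range(t):
        vals = Y[~miss[:, k], k]
        col_means[k] = vals.mean() if vals.size else 1.0
        Y[miss[:, k], k] = col_means[k]

    n_pat, pmi, pmn, poi, pon, pptr, prec_ = _missing_patterns(miss)

    Ainv = a_inverse(ped).tocsr()
    n_anim = len(ped)

    yr_ptr, yr_rec = _csr_groups(yr_idx, n_year)
    pe_ptr, pe_rec = _csr_groups(pe_idx, n_pe)
    an_ptr, an_rec = _csr_groups(anim_idx, n_anim)

    rng = np.random.default_rng(settings.seed)
    _kernels.seed_kernel(int(np.random.default_rng(settings.seed + 1).integers(2**31 - 1)))

    # initial values
    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    a = np.zeros((n_anim, t))
    pe = np.zeros((n_pe, t))
    yr = np.zeros((n_year, t))
    alpha_a = np.ones(t)
    alpha_pe = np.ones(t)
    alpha_yr = np.ones(t)
    px = prior.family == PARAMETER_EXPANDED
    G_w = prior.V.copy()
    P_w = prior.V.copy()
    Yc_w = prior.V.copy()
    R = (prior.V if prior.residual_V is None else prior.residual_V).copy()

    Psi = prior.scale
    Psi_R = prior.residual_scale
    nu = prior.nu
    S_a = np.zeros((t, t))
    S_pe = np.zeros((t, t))
    S_yr = np.zeros((t, t))

    S = settings.n_samples
    out_G = np.empty((S, t, t))
    out_P = np.zeros((S, t, t))
    out_Y = np.zeros((S, t, t))
    out_R = np.empty((S, t, t))
    out_B = np.empty((S, p, t))

    v0 = FIXED_EFFECT_PRIOR_VARIANCE
    XtX = X.T @ X
    stored = 0
    dummy = np.zeros((1, t))

    pe_arr = pe if include_pe else dummy
    yr_arr = yr if include_year else dummy

    def effective(term_cov, alpha):
        D = np.diag(alpha)
        return D @ term_cov @ D

    def draw_alpha(eta_rec, resid, avar):
        """Working-parameter draw: resid_j ~ N(diag(eta_j) alpha, R)."""
        Rinv = np.linalg.inv(R)
        P_mat = Rinv * (eta_rec.T @ eta_rec) + np.eye(t) / avar
        rhs = ((resid @ Rinv) * eta_rec).sum(axis=0)
        c, low = cho_factor(P_mat)
        mean = cho_solve((c, low), rhs)
        noise = solve_triangular(c, rng.standard_normal(t), lower=False)
        return mean + noise

    for it in range(1, settings.iterations + 1):
        mu_fix = X @ B
        Rinv = np.linalg.inv(R)
        Ginv = np.linalg.inv(G_w)
        Pinv = np.linalg.inv(P_w)
        Ycinv = np.linalg.inv(Yc_w)

        if n_pat:
            _kernels.impute_missing(Y, mu_fix, a, pe_arr, yr_arr, alpha_a, alpha_pe, alpha_yr,
                                    anim_idx, pe_idx, yr_idx, include_pe, include_year,
                                    n_pat, pmi, pmn, poi, pon, pptr, prec_, R)
        status = _kernels.sweep_locations(
            Y, mu_fix, a, pe_arr, yr_arr, alpha_a, alpha_pe, alpha_yr,
            anim_idx, pe_idx, yr_idx, include_pe, include_year,
            yr_ptr, yr_rec, pe_ptr, pe_rec, an_ptr, an_rec,
            Ainv.indptr.astype(np.int64), Ainv.indices.astype(np.int64), Ainv.data,
            Rinv, Ginv, Pinv, Ycinv, S_a, S_pe, S_yr)
        if status != 0:
            raise RuntimeError(f"non-positive-definite conditional precision at iteration {it}")

        # effective (alpha-scaled) contributions per record
        contrib = (alpha_a * a)[anim_idx]
        if include_pe:
            contrib = contrib + (alpha_pe * pe)[pe_idx]
        if include_year:
            contrib = contrib + (alpha_yr * yr)[yr_idx]

        # fixed effects: vec(B) row-major, precision kron(X'X, Rinv) + I/v0
        Ystar = Y - contrib
        Q = np.kron(XtX, Rinv) + np.eye(p * t) / v0
        rhs = (X.T @ Ystar @ Rinv).ravel()
        c, low = cho_factor(Q)
        bvec = cho_solve((c, low), rhs) + solve_triangular(c, rng.standard_normal(p * t), lower=False)
        B = bvec.reshape(p, t)
        mu_fix = X @ B

        if px:
            base = Y - mu_fix
            eta_a = a[anim_idx]
            eta_pe = pe[pe_idx] if include_pe else None
            eta_yr = yr[yr_idx] if include_year else None
            r_a = base - ((alpha_pe * pe)[pe_idx] if include_pe else 0) \
                       - ((alpha_yr * yr)[yr_idx] if include_year else 0)
            alpha_a = draw_alpha(eta_a, r_a, prior.alpha_variance)
            if include_pe:
                r_pe = base - (alpha_a * a)[anim_idx] \
                            - ((alpha_yr * yr)[yr_idx] if include_year else 0)
                alpha_pe = draw_alpha(eta_pe, r_pe, prior.alpha_variance)
            if include_year:
                r_yr = base - (alpha_a * a)[anim_idx] \
                            - ((alpha_pe * pe)[pe_idx] if include_pe else 0)
                alpha_yr = draw_alpha(eta_yr, r_yr, prior.alpha_variance)
            contrib = (alpha_a * a)[anim_idx]
            if include_pe:
                contrib = contrib + (alpha_pe * pe)[pe_idx]
            if include_year:
                contrib = contrib + (alpha_yr * yr)[yr_idx]

        # covariance draws
        G_w = _sample_invwishart(rng, Psi + S_a, nu + n_anim)
        if include_pe:
            P_w = _sample_invwishart(rng, Psi + S_pe, nu + n_pe)
        if include_year:
            Yc_w = _sample_invwishart(rng, Psi + S_yr, nu + n_year)
        resid = Y - mu_fix - contrib
        R = _sample_invwishart(rng, Psi_R + resid.T @ resid, nu + n_rec)

        if it > settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            G_eff = effective(G_w, alpha_a) if px else G_w
            P_eff = (effective(P_w, alpha_pe) if px else P_w) if include_pe else np.zeros((t, t))
            Y_eff = (effective(Yc_w, alpha_yr) if px else Yc_w) if include_year else np.zeros((t, t))
            for M, name in ((G_eff, "G"), (R, "R")):
                if np.any(np.linalg.eigvalsh(M) <= 0):
                    raise RuntimeError(f"stored {name} sample not positive definite")
            out_G[stored] = G_eff
            out_P[stored] = P_eff
            out_Y[stored] = Y_eff
            out_R[stored] = R
            out_B[stored] = B
            stored += 1
        if progress and it % max(1, settings.iterations // 20) == 0:
            print(f"  iteration {it}/{settings.iterations}", flush=True)

    metadata = {
        "prior_family": prior.family,
        "prior_nu": prior.nu,
        "prior_V": prior.V.tolist(),
        "alpha_variance": prior.alpha_variance,
        "iterations": settings.iterations,
        "burn_in": settings.burn_in,
        "thinning": settings.thinning,
        "seed": settings.seed,
        "n_records": int(n_rec),
        "n_individuals": int(n_pe),
        "n_pedigree": int(n_anim),
        "n_years": int(n_year),
        "include_pe": include_pe,
        "include_year": include_year,
        "prior_only": prior_only,
        "data_digest": observed_digest,
        "year_levels": [int(v) for v in year_levels],
    }
    return PosteriorChain(G=out_G[:stored], P_pe=out_P[:stored], P_year=out_Y[:stored],
                          R=out_R[:stored], B=out_B[:stored],
                          trait_names=tuple(traits), fixed_columns=list(design.columns),
                          metadata=metadata)
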