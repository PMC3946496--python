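"""Numba kernels for the Gibbs sweep of the multivariate animal model.

Everything here operates on flat float64/int64 arrays. Trait dimension t
is small (typically 4), so Cholesky factorizations and triangular solves
are hand-coded with explicit loops to avoid per-call LAPACK overhead in
the per-individual update loops.

Random numbers use numba's internal np.random state; ``seed_kernel``
must be called once per chain for reproducibility (single-threaded).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _chol_inplace(A, L, t):
    """Lower Cholesky of A (t x t) into L. Returns 0 on success, 1 if not PD."""
    for i in range(t):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return 1
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, t):
            L[i, j] = 0.0
    return 0


@njit(cache=True, inline="always")
def _forward(L, b, x, t):
    """Solve L x = b (L lower triangular)."""
    for i in range(t):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]


@njit(cache=True, inline="always")
def _backward_t(L, b, x, t):
    """Solve L' x = b (L lower triangular)."""
    for i in range(t - 1, -1, -1):
        s = b[i]
        for k in range(i + 1, t):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]


@njit(cache=True, inline="always")
def _draw_mvn_prec(P, rhs, out, L, w1, w2, t):
    """Draw out ~ N(P^-1 rhs, P^-1). Returns 0 on success, 1 if P not PD.

    Retries once with a small ridge before giving up.
    """
    ok = _chol_inplace(P, L, t)
    if ok != 0:
        for i in range(t):
            P[i, i] += 1e-8 * (1.0 + abs(P[i, i]))
        ok = _chol_inplace(P, L, t)
        if ok != 0:
            return 1
    _forward(L, rhs, w1, t)
    _backward_t(L, w1, w2, t)  # mean
    for i in range(t):
        w1[i] = np.random.standard_normal()
    _backward_t(L, w1, out, t)  # noise with cov P^-1
    for i in range(t):
        out[i] += w2[i]
    return 0


@njit(cache=True)
def impute_missing(Y, mu_fix, a, pe, yr, alpha_a, alpha_pe, alpha_yr,
                   anim_idx, pe_idx, yr_idx, use_pe, use_year,
                   n_pat, pat_miss_idx, pat_miss_n, pat_obs_idx, pat_obs_n,
                   pat_ptr, pat_rec, R):
    """Sample missing trait values from their conditional normal given R."""
    t = Y.shape[1]
    mu = np.empty(t)
    eobs = np.empty(t)
    z = np.empty(t)
    Roo = np.empty((t, t))
    Loo = np.empty((t, t))
    M = np.empty((t, t))      # R_mo @ Roo^-1
    Ccov = np.empty((t, t))
    Lc = np.empty((t, t))
    col = np.empty(t)
    sol = np.empty(t)
    for p in range(n_pat):
        km = pat_miss_n[p]
        ko = pat_obs_n[p]
        if km == 0:
            continue
        # conditional matrices for this pattern
        if ko > 0:
            for i in range(ko):
                for j in range(ko):
                    Roo[i, j] = R[pat_obs_idx[p, i], pat_obs_idx[p, j]]
            if _chol_inplace(Roo[:ko, :ko], Loo[:ko, :ko], ko) != 0:
                continue  # caller guarantees PD R; skip defensively
            for m in range(km):
                for j in range(ko):
                    col[j] = R[pat_miss_idx[p, m], pat_obs_idx[p, j]]
                _forward(Loo[:ko, :ko], col[:ko], sol[:ko], ko)
                _backward_t(Loo[:ko, :ko], sol[:ko], col[:ko], ko)
                for j in range(ko):
                    M[m, j] = col[j]
            for m in range(km):
                for mm in range(km):
                    s = R[pat_miss_idx[p, m], pat_miss_idx[p, mm]]
                    for j in range(ko):
                        s -= M[m, j] * R[pat_miss_idx[p, mm], pat_obs_idx[p, j]]
                    Ccov[m, mm] = s
        else:
            for m in range(km):
                for mm in range(km):
                    Ccov[m, mm] = R[pat_miss_idx[p, m], pat_miss_idx[p, mm]]
        if _chol_inplace(Ccov[:km, :km], Lc[:km, :km], km) != 0:
            continue
        for rix in range(pat_ptr[p], pat_ptr[p + 1]):
            j = pat_rec[rix]
            ai = anim_idx[j]
            for k in range(t):
                mu[k] = mu_fix[j, k] + alpha_a[k] * a[ai, k]
            if use_pe:
                pi = pe_idx[j]
                for k in range(t):
                    mu[k] += alpha_pe[k] * pe[pi, k]
            if use_year:
                yi = yr_idx[j]
                for k in range(t):
                    mu[k] += alpha_yr[k] * yr[yi, k]
            for o in range(ko):
                k = pat_obs_idx[p, o]
                eobs[o] = Y[j, k] - mu[k]
            for m in range(km):
                z[m] = np.random.standard_normal()
            for m in range(km):
                k = pat_miss_idx[p, m]
                v = mu[k]
                for o in range(ko):
                    v += M[m, o] * eobs[o]
                for mm in range(m + 1):
                    v += Lc[m, mm] * z[mm]
                Y[j, k] = v


@njit(cache=True)
def sweep_locations(Y, mu_fix, a, pe, yr, alpha_a, alpha_pe, alpha_yr,
                    anim_idx, pe_idx, yr_idx, use_pe, use_year,
                    yr_ptr, yr_rec, pe_ptr, pe_rec, an_ptr, an_rec,
                    Ainv_indptr, Ainv_indices, Ainv_data,
                    Rinv, Ginv, Pinv, Yinv,
                    S_a, S_pe, S_yr):
    """One Gibbs pass over year, permanent-environment and breeding values.

    Updates yr, pe, a in place and fills the scatter matrices
    S_a = a' Ainv a, S_pe = pe' pe, S_yr = yr' yr used by the
    inverse-Wishart covariance draws. Returns 0, or 1 on a
    non-recoverable non-PD conditional precision.
    """
    t = Y.shape[1]
    s = np.empty(t)
    rhs = np.empty(t)
    nsum = np.empty(t)
    tmp = np.empty(t)
    P = np.empty((t, t))
    L = np.empty((t, t))
    w1 = np.empty(t)
    w2 = np.empty(t)
    out = np.empty(t)

    # --- year effects ---
    if use_year:
        n_year = yr.shape[0]
        for g in range(n_year):
            for k in range(t):
                s[k] = 0.0
            ng = 0
            for rix in range(yr_ptr[g], yr_ptr[g + 1]):
                j = yr_rec[rix]
                ai = anim_idx[j]
                ng += 1
                for k in range(t):
                    v = Y[j, k] - mu_fix[j, k] - alpha_a[k] * a[ai, k]
                    if use_pe:
                        v -= alpha_pe[k] * pe[pe_idx[j], k]
                    s[k] += v
            for u in range(t):
                acc = 0.0
                for v in range(t):
                    P[u, v] = ng * alpha_yr[u] * Rinv[u, v] * alpha_yr[v] + Yinv[u, v]
                    acc += Rinv[u, v] * s[v]
                rhs[u] = alpha_yr[u] * acc
            if _draw_mvn_prec(P, rhs, out, L, w1, w2, t) != 0:
                return 1
            for k in range(t):
                yr[g, k] = out[k]

    # --- permanent environment effects ---
    if use_pe:
        n_pe = pe.shape[0]
        for g in range(n_pe):
            for k in range(t):
                s[k] = 0.0
            ng = 0
            for rix in range(pe_ptr[g], pe_ptr[g + 1]):
                j = pe_rec[rix]
                ai = anim_idx[j]
                ng += 1
                for k in range(t):
                    v = Y[j, k] - mu_fix[j, k] - alpha_a[k] * a[ai, k]
                    if use_year:
                        v -= alpha_yr[k] * yr[yr_idx[j], k]
                    s[k] += v
            for u in range(t):
                acc = 0.0
                for v in range(t):
                    P[u, v] = ng * alpha_pe[u] * Rinv[u, v] * alpha_pe[v] + Pinv[u, v]
                    acc += Rinv[u, v] * s[v]
                rhs[u] = alpha_pe[u] * acc
            if _draw_mvn_prec(P, rhs, out, L, w1, w2, t) != 0:
                return 1
            for k in range(t):
                pe[g, k] = out[k]

    # --- breeding values (single-site over individuals, joint over traits) ---
    n_anim = a.shape[0]
    for i in range(n_anim):
        qii = 0.0
        for k in range(t):
            nsum[k] = 0.0
        for ptr in range(Ainv_indptr[i], Ainv_indptr[i + 1]):
            jj = Ainv_indices[ptr]
            q = Ainv_data[ptr]
            if jj == i:
                qii += q
            else:
                for k in range(t):
                    nsum[k] += q * a[jj, k]
        ni = an_ptr[i + 1] - an_ptr[i]
        for k in range(t):
            s[k] = 0.0
        for rix in range(an_ptr[i], an_ptr[i + 1]):
            j = an_rec[rix]
            for k in range(t):
                v = Y[j, k] - mu_fix[j, k]
                if use_pe:
                    v -= alpha_pe[k] * pe[pe_idx[j], k]
                if use_year:
                    v -= alpha_yr[k] * yr[yr_idx[j], k]
                s[k] += v
        for u in range(t):
            acc = 0.0
            accn = 0.0
            for v in range(t):
                P[u, v] = ni * alpha_a[u] * Rinv[u, v] * alpha_a[v] + qii * Ginv[u, v]
                acc += Rinv[u, v] * s[v]
                accn += Ginv[u, v] * nsum[v]
            rhs[u] = alpha_a[u] * acc - accn
        if _draw_mvn_prec(P, rhs, out, L, w1, w2, t) != 0:
            return 1
        for k in range(t):
            a[i, k] = out[k]

    # --- scatter matrices ---
    for u in range(t):
        for v in range(t):
            S_a[u, v] = 0.0
            S_pe[u, v] = 0.0
            S_yr[u, v] = 0.0
    for i in range(n_anim):
        for ptr in range(Ainv_indptr[i], Ainv_indptr[i + 1]):
            jj = Ainv_indices[ptr]
            q = Ainv_data[ptr]
            for u in range(t):
                for v in range(t):
                    S_a[u, v] += q * a[i, u] * a[jj, v]
    if use_pe:
        for g in range(pe.shape[0]):
            for u in range(t):
                for v in range(t):
                    S_pe[u, v] += pe[g, u] * pe[g, v]
    if use_year:
        for g in range(yr.shape[0]):
            for u in range(t):
                for v in range(t):
                    S_yr[u, v] += yr[g, u] * yr[g, v]
    return 0
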