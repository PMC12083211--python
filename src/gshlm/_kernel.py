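"""Compiled single-chain Gibbs kernel (numba).

Implements exactly the eight-step cycle of :mod:`gshlm.sampler` in one
njit-compiled loop so that replicated simulation studies run at desk scale.
The pure-Python step functions in ``sampler.py`` are the reference
implementation; the test suite checks that both engines target the same
posterior.  The inverse-Wishart draw uses the standard Bartlett
decomposition (scipy cannot be called from compiled code); it is
cross-checked against scipy.stats.invwishart in the tests.

Randomness: numba maintains its own Mersenne-Twister state per thread,
seeded explicitly at kernel entry, so chains are reproducible for a given
seed (though not draw-for-draw identical to the numpy-Generator reference
engine).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _fill_c_columns(D, rows, C, ci, Xrow, p, q, xc, cc_s, cc_t):
    """Refresh the C-dependent design columns for the given rows."""
    n_xc = xc.shape[0]
    for ii in range(rows.shape[0]):
        idx = rows[ii]
        j = ci[idx]
        for k in range(p):
            D[idx, 1 + k] = C[j, k]
        off = 1 + p + q
        for a in range(n_xc):
            s = xc[a]
            for b in range(q):
                D[idx, off] = Xrow[idx, b] * C[j, s]
                off += 1
        for a in range(cc_s.shape[0]):
            D[idx, off] = C[j, cc_s[a]] * C[j, cc_t[a]]
            off += 1


@njit(cache=True)
def _chol_upper_solve(L, z):
    """Solve L' x = z for lower-triangular L (back substitution)."""
    d = z.shape[0]
    x = np.empty(d)
    for i in range(d - 1, -1, -1):
        s = z[i]
        for j in range(i + 1, d):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _inv_wishart_bartlett(df, scale):
    """Draw T ~ IW(df, scale): T = W^-1 with W ~ Wishart(df, scale^-1)."""
    p = scale.shape[0]
    Ls = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(np.random.chisquare(df - i))
        for j in range(i):
            A[i, j] = np.random.standard_normal()
    M = Ls @ A
    W = M @ M.T
    T = np.linalg.inv(W)
    # symmetrize against round-off
    for i in range(p):
        for j in range(i):
            m = 0.5 * (T[i, j] + T[j, i])
            T[i, j] = m
            T[j, i] = m
    return T


@njit(cache=True)
def gibbs_kernel(
    y_init,
    ymiss_idx,
    C_init,
    cmiss_j,
    cmiss_off,
    ci,
    nj,
    rows_sorted,
    row_off,
    Xrow,
    Wm,
    p,
    q,
    xc,
    cc_s,
    cc_t,
    beta_init,
    tau_init,
    sigma2_init,
    alpha_init,
    T_init,
    a0,
    rate0,
    V0,
    S0,
    n_burn,
    n_post,
    seed,
):
    np.random.seed(seed)
    N = y_init.shape[0]
    J = nj.shape[0]
    d = beta_init.shape[0]
    n_alpha = alpha_init.shape[0]
    r_w = Wm.shape[1]  # 1 + q2
    K = d + 2 + n_alpha + p * (p + 1) // 2

    yimp = y_init.copy()
    C = C_init.copy()
    beta = beta_init.copy()
    tau = tau_init
    sigma2 = sigma2_init
    alpha = alpha_init.copy()
    T = T_init.copy()
    u = np.zeros(J)

    # design matrix, kept consistent with the current completed C
    D = np.zeros((N, d))
    all_rows = np.arange(N)
    for idx in range(N):
        D[idx, 0] = 1.0
        for b in range(q):
            D[idx, 1 + p + b] = Xrow[idx, b]
    _fill_c_columns(D, all_rows, C, ci, Xrow, p, q, xc, cc_s, cc_t)

    G = Wm.T.copy() @ Wm  # constant Gram matrix of (1, x2)
    draws = np.empty((n_post, K))
    lp = np.empty(N)
    Mmean = np.empty((J, p))

    for t in range(n_burn + n_post):
        # ---- Step 1: random intercepts u_j
        lp[:] = D @ beta
        rsum = np.zeros(J)
        for idx in range(N):
            rsum[ci[idx]] += yimp[idx] - lp[idx]
        for j in range(J):
            delta = nj[j] / sigma2 + 1.0 / tau
            mean = rsum[j] / sigma2 / delta
            u[j] = mean + np.random.standard_normal() / np.sqrt(delta)

        # ---- Step 2: tau ~ IG(J/2 + a0, sum u^2 / 2 + rate0)
        ssq = 0.0
        for j in range(J):
            ssq += u[j] * u[j]
        tau = 1.0 / np.random.gamma(J / 2.0 + a0, 1.0 / (ssq / 2.0 + rate0))

        # ---- Step 3: beta ~ N((X'X)^-1 X'(y-u), sigma2 (X'X)^-1)
        Dt = D.T.copy()
        XtX = Dt @ D
        yt = np.empty(N)
        for idx in range(N):
            yt[idx] = yimp[idx] - u[ci[idx]]
        Xty = Dt @ yt
        mean_b = np.linalg.solve(XtX, Xty)
        Lb = np.linalg.cholesky(XtX)
        z = np.empty(d)
        for a in range(d):
            z[a] = np.random.standard_normal()
        beta = mean_b + np.sqrt(sigma2) * _chol_upper_solve(Lb, z)

        # ---- Step 4: sigma2 ~ IG(N/2 + a0, sum e^2 / 2 + rate0)
        lp[:] = D @ beta
        sse = 0.0
        for idx in range(N):
            e = yimp[idx] - lp[idx] - u[ci[idx]]
            sse += e * e
        sigma2 = 1.0 / np.random.gamma(N / 2.0 + a0, 1.0 / (sse / 2.0 + rate0))

        # ---- Step 5: impute missing Y from the posterior predictive
        for ii in range(ymiss_idx.shape[0]):
            idx = ymiss_idx[ii]
            yimp[idx] = lp[idx] + u[ci[idx]] + np.sqrt(sigma2) * np.random.standard_normal()

        # ---- Step 6: alpha ~ N(., (sum W'T^-1 W)^-1), precision kron(T^-1, G)
        Tinv = np.linalg.inv(T)
        prec = np.empty((n_alpha, n_alpha))
        for k1 in range(p):
            for k2 in range(p):
                for r1 in range(r_w):
                    for r2 in range(r_w):
                        prec[k1 * r_w + r1, k2 * r_w + r2] = Tinv[k1, k2] * G[r1, r2]
        rhs = np.zeros(n_alpha)
        CTinv = C @ Tinv  # (J, p)
        for j in range(J):
            for k in range(p):
                for r in range(r_w):
                    rhs[k * r_w + r] += Wm[j, r] * CTinv[j, k]
        mean_a = np.linalg.solve(prec, rhs)
        La = np.linalg.cholesky(prec)
        za = np.empty(n_alpha)
        for a in range(n_alpha):
            za[a] = np.random.standard_normal()
        alpha = mean_a + _chol_upper_solve(La, za)

        # ---- Step 7: T ~ IW(V0 + J, S0 + sum resid resid')
        for j in range(J):
            for k in range(p):
                m = 0.0
                for r in range(r_w):
                    m += Wm[j, r] * alpha[k * r_w + r]
                Mmean[j, k] = m
        scale = S0.copy()
        for j in range(J):
            for k1 in range(p):
                for k2 in range(p):
                    scale[k1, k2] += (C[j, k1] - Mmean[j, k1]) * (C[j, k2] - Mmean[j, k2])
        T = _inv_wishart_bartlett(V0 + J, scale)

        # ---- Step 8: impute missing C_kj, systematic scan k = 1..p
        for k in range(p):
            m0 = cmiss_off[k]
            m1 = cmiss_off[k + 1]
            if m1 == m0:
                continue
            # conditional moments of C_k | C_(-k)
            if p > 1:
                Trr = np.empty((p - 1, p - 1))
                Tri = np.empty(p - 1)
                a = 0
                for r1 in range(p):
                    if r1 == k:
                        continue
                    Tri[a] = T[r1, k]
                    b = 0
                    for r2 in range(p):
                        if r2 == k:
                            continue
                        Trr[a, b] = T[r1, r2]
                        b += 1
                    a += 1
                sol = np.linalg.solve(Trr, Tri)
                T_cond = T[k, k]
                for a in range(p - 1):
                    T_cond -= Tri[a] * sol[a]
            else:
                sol = np.zeros(0)
                T_cond = T[k, k]
            for mi in range(m0, m1):
                j = cmiss_j[mi]
                M_cond = Mmean[j, k]
                a = 0
                for r1 in range(p):
                    if r1 == k:
                        continue
                    M_cond += sol[a] * (C[j, r1] - Mmean[j, r1])
                    a += 1
                smu2sq = 0.0
                smu2r = 0.0
                ck_old = C[j, k]
                for ri in range(row_off[j], row_off[j + 1]):
                    idx = rows_sorted[ri]
                    # mu2 = d(lp)/d(C_k) for this row
                    mu2 = beta[1 + k]
                    off = 1 + p + q
                    for aa in range(xc.shape[0]):
                        if xc[aa] == k:
                            for b in range(q):
                                mu2 += beta[off + b] * Xrow[idx, b]
                        off += q
                    for aa in range(cc_s.shape[0]):
                        if cc_s[aa] == k:
                            mu2 += beta[off] * C[j, cc_t[aa]]
                        elif cc_t[aa] == k:
                            mu2 += beta[off] * C[j, cc_s[aa]]
                        off += 1
                    lp_row = 0.0
                    for b in range(d):
                        lp_row += D[idx, b] * beta[b]
                    mu1 = lp_row + u[j] - mu2 * ck_old
                    smu2sq += mu2 * mu2
                    smu2r += mu2 * (yimp[idx] - mu1)
                Delta = 1.0 / T_cond + smu2sq / sigma2
                M_tilde = (M_cond / T_cond + smu2r / sigma2) / Delta
                C[j, k] = M_tilde + np.random.standard_normal() / np.sqrt(Delta)
                _fill_c_columns(
                    D, rows_sorted[row_off[j]:row_off[j + 1]], C, ci, Xrow,
                    p, q, xc, cc_s, cc_t,
                )

        # ---- record
        if t >= n_burn:
            s = t - n_burn
            for b in range(d):
                draws[s, b] = beta[b]
            draws[s, d] = tau
            draws[s, d + 1] = sigma2
            for a in range(n_alpha):
                draws[s, d + 2 + a] = alpha[a]
            off = d + 2 + n_alpha
            for r1 in range(p):
                for r2 in range(r1, p):
                    draws[s, off] = T[r1, r2]
                    off += 1
    return draws
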