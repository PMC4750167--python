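"""Numba single-site Gibbs kernel shared by BayesB/BayesC/BayesC0/GBLUP.

One compiled routine runs all four models; they differ only in the prior
inclusion fraction pi, the variance degrees of freedom, and whether each
locus has its own effect variance (BayesB) or a common one (BayesC family).
The residual vector and the per-window genomic-value columns are maintained
incrementally; both are exactly recomputable from the final state, which
the test suite audits.

All randomness comes from numba's internal RNG seeded once per chain, so a
chain is bit-reproducible for a given seed.
"""

import numpy as np
from numba import njit

__all__ = ["gibbs_chain"]


@njit(cache=True, fastmath=True)
def _dot(a, b):
    s = 0.0
    for i in range(a.size):
        s += a[i] * b[i]
    return s


@njit(cache=True, fastmath=True)
def _scaled_inv_chi2(df, scale):
    # draw from scaled-inv-chi2(df, scale) = df*scale / chi2(df)
    return df * scale / np.random.chisquare(df)


@njit(cache=True, fastmath=True)
def gibbs_chain(
    XT,            # (p, n) centered dosages, C-contiguous
    Xf,            # (n, nf) fixed-effect design
    y,             # (n,)
    beta_init,     # (nf,)
    pi,            # prior fraction of zero-effect SNPs
    nu_a, S2_a,    # genetic-scale prior df and scale
    nu_e, S2_e,    # residual prior df and scale
    bayesB,        # per-locus variances if True, common variance otherwise
    fix_variances, # freeze variance components at their initial values
    sigma2_a0, sigma2_e0,
    n_iter, burn_in, thin,
    window_of,     # (p,) int64 window index per SNP, -1 = unassigned
    n_windows,
    store_windows,
    seed,
):
    np.random.seed(seed)
    p, n = XT.shape
    nf = Xf.shape[1]

    xtx = np.empty(p)
    for j in range(p):
        xtx[j] = _dot(XT[j], XT[j])
    xfxf = np.empty(nf)
    for k in range(nf):
        s = 0.0
        for i in range(n):
            s += Xf[i, k] * Xf[i, k]
        xfxf[k] = s

    beta = beta_init.copy()
    alpha = np.zeros(p)
    delta = np.zeros(p, dtype=np.int8)
    if pi == 0.0:
        for j in range(p):
            delta[j] = 1
    s2j = np.full(p, sigma2_a0)       # per-locus variances (BayesB)
    sigma2_a = sigma2_a0
    sigma2_e = sigma2_e0

    e = y.copy()
    for k in range(nf):
        bk = beta[k]
        if bk != 0.0:
            for i in range(n):
                e[i] -= Xf[i, k] * bk

    n_stored = (n_iter - burn_in + thin - 1) // thin
    if store_windows:
        U = np.zeros((n_windows, n))
        V = np.zeros((n_stored, n_windows), dtype=np.float32)
    else:
        U = np.zeros((1, 1))
        V = np.zeros((1, 1), dtype=np.float32)
    inc_w = np.zeros(n_windows, dtype=np.int64)

    # Rao-Blackwellized accumulators: per locus the conditional posterior
    # inclusion probability and conditional mean effect given the rest of
    # the state, recorded at update time — same expectation as averaging
    # the draws, much lower Monte-Carlo variance
    cond_p1 = np.zeros(p)
    cond_mean = np.zeros(p)
    alpha_sum = np.zeros(p)
    delta_sum = np.zeros(p)
    beta_sum = np.zeros(nf)
    tr_sigma2_e = np.empty(n_stored)
    tr_sigma2_a = np.empty(n_stored)
    tr_genvar = np.empty(n_stored)
    log_pi = np.log(pi) if pi > 0.0 else 0.0
    log_1mpi = np.log(1.0 - pi)

    error_iter = -1
    s_idx = 0
    for it in range(n_iter):
        # --- fixed effects, flat prior ---
        for k in range(nf):
            ck = xfxf[k]
            if ck <= 0.0:
                continue
            r = 0.0
            for i in range(n):
                r += Xf[i, k] * e[i]
            r += ck * beta[k]
            newb = np.random.normal(r / ck, np.sqrt(sigma2_e / ck))
            db = newb - beta[k]
            if db != 0.0:
                for i in range(n):
                    e[i] -= Xf[i, k] * db
            beta[k] = newb

        # --- loci in index order ---
        sum_a2 = 0.0
        m_inc = 0
        for j in range(p):
            c = xtx[j]
            old = alpha[j]
            if c <= 0.0:
                # monomorphic after centering: forced out of the model
                if old != 0.0:
                    for i in range(n):
                        e[i] += XT[j, i] * old
                alpha[j] = 0.0
                delta[j] = 0
                cond_p1[j] = 0.0
                cond_mean[j] = 0.0
                continue
            s2 = s2j[j] if bayesB else sigma2_a
            r = _dot(XT[j], e) + c * old
            chat = c + sigma2_e / s2
            if pi > 0.0:
                v1 = c * c * s2 + c * sigma2_e
                v0 = c * sigma2_e
                logL1 = -0.5 * (np.log(v1) + r * r / v1)
                logL0 = -0.5 * (np.log(v0) + r * r / v0)
                logodds = log_1mpi - log_pi + logL1 - logL0
                if logodds > 35.0:
                    p1 = 1.0
                elif logodds < -35.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + np.exp(-logodds))
                inc = np.random.random() < p1
            else:
                p1 = 1.0
                inc = True
            cond_p1[j] = p1
            cond_mean[j] = p1 * r / chat
            if inc:
                newa = np.random.normal(r / chat, np.sqrt(sigma2_e / chat))
                sum_a2 += newa * newa
                m_inc += 1
                delta[j] = 1
            else:
                newa = 0.0
                delta[j] = 0
            da = newa - old
            if da != 0.0:
                w = window_of[j]
                if store_windows and w >= 0:
                    Uw = U[w]
                    for i in range(n):
                        xv = XT[j, i]
                        e[i] -= xv * da
                        Uw[i] += xv * da
                else:
                    for i in range(n):
                        e[i] -= XT[j, i] * da
            alpha[j] = newa
            if bayesB and not fix_variances:
                if inc:
                    df = nu_a + 1.0
                    s2j[j] = _scaled_inv_chi2(df, (nu_a * S2_a + newa * newa) / df)
                else:
                    s2j[j] = _scaled_inv_chi2(nu_a, S2_a)

        # --- variance components ---
        if not fix_variances:
            if not bayesB:
                df = nu_a + m_inc
                sigma2_a = _scaled_inv_chi2(df, (nu_a * S2_a + sum_a2) / df)
            ee = _dot(e, e)
            df_e = nu_e + n
            sigma2_e = _scaled_inv_chi2(df_e, (nu_e * S2_e + ee) / df_e)
        if not np.isfinite(sigma2_e) or sigma2_e <= 0.0:
            error_iter = it
            break

        # --- store ---
        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(p):
                alpha_sum[j] += cond_mean[j]
                delta_sum[j] += cond_p1[j]
            for k in range(nf):
                beta_sum[k] += beta[k]
            # total genomic value u_i = y_i - Xf beta - e_i
            mu = 0.0
            for i in range(n):
                fi = 0.0
                for k in range(nf):
                    fi += Xf[i, k] * beta[k]
                mu += y[i] - fi - e[i]
            mu /= n
            vv = 0.0
            for i in range(n):
                fi = 0.0
                for k in range(nf):
                    fi += Xf[i, k] * beta[k]
                u = y[i] - fi - e[i]
                vv += (u - mu) * (u - mu)
            tr_genvar[s_idx] = vv / n
            tr_sigma2_e[s_idx] = sigma2_e
            if bayesB:
                sa = 0.0
                for j in range(p):
                    sa += s2j[j]
                tr_sigma2_a[s_idx] = sa / p
            else:
                tr_sigma2_a[s_idx] = sigma2_a
            if store_windows:
                for w in range(n_windows):
                    inc_w[w] = 0
                for j in range(p):
                    if delta[j] == 1:
                        w = window_of[j]
                        if w >= 0:
                            inc_w[w] += 1
                for w in range(n_windows):
                    if inc_w[w] > 0:
                        Uw = U[w]
                        m = 0.0
                        for i in range(n):
                            m += Uw[i]
                        m /= n
                        v = 0.0
                        for i in range(n):
                            v += (Uw[i] - m) * (Uw[i] - m)
                        V[s_idx, w] = v / n
                    else:
                        V[s_idx, w] = 0.0
            s_idx += 1

    n_eff = s_idx if s_idx > 0 else 1
    return (
        alpha_sum / n_eff,
        delta_sum / n_eff,
        beta_sum / n_eff,
        tr_sigma2_e[:s_idx],
        tr_sigma2_a[:s_idx],
        tr_genvar[:s_idx],
        V[:s_idx] if store_windows else V[:0],
        alpha,
        beta,
        e,
        error_iter,
    )
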