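"""Compiled Metropolis-within-Gibbs sweep for the nested logit models.

Exploits that every design column is 0/1 (intercept or dummy): a scalar
random-walk move on one coefficient shifts the linear predictor by a constant
on that column's active rows only, so each block update touches just its
active set.  The per-row log-normaliser l_i = log(1 + exp(eta_i)) is
maintained incrementally alongside eta.

The accept rule is the standard symmetric random-walk Metropolis ratio on
the unnormalised log posterior; precisions are updated by conjugate Gibbs
draws (pre-drawn Gamma(shape', 1) variates scaled by the current rate).
Region effects u are recentred to sum to zero after every sweep, with the
mean absorbed into the intercept so the linear predictor is untouched.
"""

import numpy as np
from numba import njit

__all__ = ["run_chain_core"]


@njit(inline="always")
def _log1pexp(e):
    # log(1 + exp(e)) without overflow
    if e > 0.0:
        return e + np.log1p(np.exp(-e))
    return np.log1p(np.exp(e))


@njit(cache=True)
def run_chain_core(
    y,                    # float64 (n,)
    eta,                  # float64 (n,) in/out — init X @ beta + effects
    col_idx, col_ptr,     # CSR active-row indices per design column
    col_ysum,             # float64 (k,) sum of y over each column's rows
    reg_idx, reg_ptr,     # CSR row indices per region
    reg_ysum,             # float64 (J,)
    nb_idx, nb_ptr,       # CSR neighbour indices per region (ICAR graph)
    edge_a, edge_b,       # int64 edge lists (j < r)
    has_u, has_v,         # booleans
    beta, u, v,           # initial state (modified in place copies)
    prec_v, prec_u,       # initial precisions
    beta_prec,            # prior precision on coefficients
    gamma_rate,           # hyperprior rate constant
    gamma_v_draws,        # Gamma(shape + J/2, 1) variates, one per iteration
    gamma_u_draws,        # Gamma(shape + (J-1)/2, 1) variates
    n_iter, burn_in, thin,
    adapt,
    scale_beta, scale_v, scale_u,   # RW scales, adapted during burn-in
    rng,
    # outputs
    beta_out, u_out, v_out, sig2_out, tau2_out, dev_out,
    acc_beta, att_beta, acc_v, att_v, acc_u, att_u,
):
    n = y.shape[0]
    k = beta.shape[0]
    J = u.shape[0]
    l = np.empty(n)
    for i in range(n):
        l[i] = _log1pexp(eta[i])
    buf = np.empty(n)  # proposal log-normalisers for the active set

    win = 50  # adaptation window (sweeps)
    wacc_beta = np.zeros(k)
    wacc_v = np.zeros(J)
    wacc_u = np.zeros(J)

    kept = 0
    for it in range(n_iter):
        post = it >= burn_in

        # ---- coefficient blocks ----
        for h in range(k):
            delta = scale_beta[h] * rng.standard_normal()
            a0, a1 = col_ptr[h], col_ptr[h + 1]
            s_old = 0.0
            s_new = 0.0
            for t in range(a0, a1):
                i = col_idx[t]
                ln = _log1pexp(eta[i] + delta)
                buf[t - a0] = ln
                s_new += ln
                s_old += l[i]
            b = beta[h]
            dlp = delta * col_ysum[h] - (s_new - s_old)
            dlp += -0.5 * beta_prec * ((b + delta) ** 2 - b * b)
            if np.log(rng.random()) < dlp:
                beta[h] = b + delta
                for t in range(a0, a1):
                    i = col_idx[t]
                    eta[i] += delta
                    l[i] = buf[t - a0]
                wacc_beta[h] += 1.0
                if post:
                    acc_beta[h] += 1
            if post:
                att_beta[h] += 1

        # ---- exchangeable effects v ----
        if has_v:
            for j in range(J):
                delta = scale_v[j] * rng.standard_normal()
                a0, a1 = reg_ptr[j], reg_ptr[j + 1]
                s_old = 0.0
                s_new = 0.0
                for t in range(a0, a1):
                    i = reg_idx[t]
                    ln = _log1pexp(eta[i] + delta)
                    buf[t - a0] = ln
                    s_new += ln
                    s_old += l[i]
                x = v[j]
                dlp = delta * reg_ysum[j] - (s_new - s_old)
                dlp += -0.5 * prec_v * ((x + delta) ** 2 - x * x)
                if np.log(rng.random()) < dlp:
                    v[j] = x + delta
                    for t in range(a0, a1):
                        i = reg_idx[t]
                        eta[i] += delta
                        l[i] = buf[t - a0]
                    wacc_v[j] += 1.0
                    if post:
                        acc_v[j] += 1
                if post:
                    att_v[j] += 1

        # ---- ICAR effects u ----
        if has_u:
            for j in range(J):
                delta = scale_u[j] * rng.standard_normal()
                a0, a1 = reg_ptr[j], reg_ptr[j + 1]
                s_old = 0.0
                s_new = 0.0
                for t in range(a0, a1):
                    i = reg_idx[t]
                    ln = _log1pexp(eta[i] + delta)
                    buf[t - a0] = ln
                    s_new += ln
                    s_old += l[i]
                # full-conditional ICAR prior: N(neighbour mean, 1/(m_j prec_u))
                b0, b1 = nb_ptr[j], nb_ptr[j + 1]
                m_j = b1 - b0
                nb_mean = 0.0
                for t in range(b0, b1):
                    nb_mean += u[nb_idx[t]]
                nb_mean /= m_j
                x = u[j]
                dlp = delta * reg_ysum[j] - (s_new - s_old)
                dlp += -0.5 * m_j * prec_u * (
                    (x + delta - nb_mean) ** 2 - (x - nb_mean) ** 2
                )
                if np.log(rng.random()) < dlp:
                    u[j] = x + delta
                    for t in range(a0, a1):
                        i = reg_idx[t]
                        eta[i] += delta
                        l[i] = buf[t - a0]
                    wacc_u[j] += 1.0
                    if post:
                        acc_u[j] += 1
                if post:
                    att_u[j] += 1
            # recentre for identifiability; absorb mean into intercept so the
            # linear predictor (hence eta, l) is unchanged
            mu = 0.0
            for j in range(J):
                mu += u[j]
            mu /= J
            for j in range(J):
                u[j] -= mu
            beta[0] += mu

        # ---- conjugate precision updates ----
        if has_v:
            ss = 0.0
            for j in range(J):
                ss += v[j] * v[j]
            prec_v = gamma_v_draws[it] / (gamma_rate + 0.5 * ss)
        if has_u:
            ss = 0.0
            for e in range(edge_a.shape[0]):
                d = u[edge_a[e]] - u[edge_b[e]]
                ss += d * d
            prec_u = gamma_u_draws[it] / (gamma_rate + 0.5 * ss)

        # ---- burn-in step-size adaptation ----
        if adapt and not post and (it + 1) % win == 0:
            for h in range(k):
                r = wacc_beta[h] / win
                scale_beta[h] *= np.exp(min(max(r - 0.44, -0.5), 0.5))
                wacc_beta[h] = 0.0
            if has_v:
                for j in range(J):
                    r = wacc_v[j] / win
                    scale_v[j] *= np.exp(min(max(r - 0.44, -0.5), 0.5))
                    wacc_v[j] = 0.0
            if has_u:
                for j in range(J):
                    r = wacc_u[j] / win
                    scale_u[j] *= np.exp(min(max(r - 0.44, -0.5), 0.5))
                    wacc_u[j] = 0.0

        # ---- record ----
        if post and (it - burn_in) % thin == 0:
            for h in range(k):
                beta_out[kept, h] = beta[h]
            if has_u:
                for j in range(J):
                    u_out[kept, j] = u[j]
                tau2_out[kept] = 1.0 / prec_u
            if has_v:
                for j in range(J):
                    v_out[kept, j] = v[j]
                sig2_out[kept] = 1.0 / prec_v
            ll = 0.0
            for i in range(n):
                ll += y[i] * eta[i] - l[i]
            dev_out[kept] = -2.0 * ll
            kept += 1
    return kept
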