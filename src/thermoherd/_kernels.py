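"""Numba-compiled Gibbs location-sampling sweep.

One sweep updates, in place and in fixed order: every fixed-effect level
(scalar full conditionals), every pedigree animal's genetic 6-vector
(blocked, using the A^-1 row structure for the prior conditional), and every
cow's permanent-environment 6-vector.  The residual vector ``e = y - W theta``
is maintained incrementally.  Standard-normal innovations are drawn outside
and passed in, so the sweep itself is deterministic.
"""

import numpy as np
from numba import njit

NC = 6  # coefficients per random block


@njit(cache=True)
def scale_move_block(
    e,
    rinv_rec,
    coeffs,  # (n_groups, 6): u for the genetic block, p for the pe block
    rec_group,  # record -> animal/cow index
    rec_gcol0,
    rec_f,
    cov,  # (6, 6) Phi or psi, updated in place on acceptance
    prior_df,
    prior_scale,  # (6, 6) inverse-Wishart scale matrix S0
    zeta,  # (6,) N(0,1) log-step innovations
    unif,  # (6,) U(0,1) acceptance draws
    tau,
):
    """Joint Metropolis rescaling of one coefficient column and its
    covariance row/column: u[:,c] -> d*u[:,c], cov -> D cov D, d = exp(tau*z).

    The Gaussian quadratic form is invariant under the joint rescaling, so
    the log acceptance ratio reduces to the likelihood change plus
    -prior_scale/2 * delta tr(cov^-1) - prior_df * log d.  This interweaving
    move frees the slow log-variance direction that the centered Gibbs scan
    mixes poorly when a component is weakly identified.
    """
    n_rec = e.shape[0]
    accepted = 0
    for c in range(NC):
        d = np.exp(tau * zeta[c])
        intercept = c % 2 == 0
        c0 = c if intercept else c - 1
        # likelihood change
        dll = 0.0
        for r in range(n_rec):
            if rec_gcol0[r] == c0:
                w = coeffs[rec_group[r], c] if intercept else rec_f[r] * coeffs[rec_group[r], c]
                e_new = e[r] - (d - 1.0) * w
                dll += rinv_rec[r] * (e_new * e_new - e[r] * e[r])
        cov_inv = np.linalg.inv(cov)
        dtr = cov_inv[c, c] * prior_scale[c, c] * (1.0 / (d * d) - 1.0)
        for k in range(NC):
            if k != c:
                dtr += 2.0 * cov_inv[c, k] * prior_scale[k, c] * (1.0 / d - 1.0)
        log_accept = -0.5 * (dll + dtr) - prior_df * np.log(d)
        if np.log(unif[c]) < log_accept:
            accepted += 1
            for r in range(n_rec):
                if rec_gcol0[r] == c0:
                    w = coeffs[rec_group[r], c] if intercept else rec_f[r] * coeffs[rec_group[r], c]
                    e[r] -= (d - 1.0) * w
            for g in range(coeffs.shape[0]):
                coeffs[g, c] *= d
            for k in range(NC):
                cov[c, k] *= d
                cov[k, c] *= d
    return accepted


@njit(cache=True, inline="always")
def _sample_mvn_canonical(P, b, z):
    """Draw from N(P^-1 b, P^-1) given precision P, shift b, N(0,1) vector z.

    Hand-rolled 6x6 Cholesky and triangular solves: with P = L L', the draw
    is P^-1 b + L^-T z, whose covariance is (L L')^-1 = P^-1.
    """
    n = P.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        s = P[i, i]
        for k in range(i):
            s -= L[i, k] * L[i, k]
        L[i, i] = np.sqrt(s)
        for j in range(i + 1, n):
            t = P[j, i]
            for k in range(i):
                t -= L[j, k] * L[i, k]
            L[j, i] = t / L[i, i]
    y = np.empty(n)
    for i in range(n):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    out = np.empty(n)
    for i in range(n - 1, -1, -1):
        s = y[i] + z[i]  # L^T (mean + w) = y + z
        for k in range(i + 1, n):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]
    return out


@njit(cache=True)
def gibbs_sweep(
    e,
    rinv_rec,
    fix_ptr,
    fix_rec,
    fixed_vals,
    an_ptr,
    an_rec,
    u,
    cw_ptr,
    cw_rec,
    p,
    rec_gcol0,
    rec_f,
    ai_ptr,
    ai_idx,
    ai_val,
    phi_inv,
    psi_inv,
    z_fixed,
    z_u,
    z_p,
):
    # ---- fixed-effect levels: scalar conditionals -------------------------
    nf = fixed_vals.shape[0]
    for j in range(nf):
        prec = 0.0
        s = 0.0
        old = fixed_vals[j]
        for k in range(fix_ptr[j], fix_ptr[j + 1]):
            r = fix_rec[k]
            ri = rinv_rec[r]
            prec += ri
            s += ri * (e[r] + old)
        new = s / prec + z_fixed[j] / np.sqrt(prec)
        delta = new - old
        fixed_vals[j] = new
        for k in range(fix_ptr[j], fix_ptr[j + 1]):
            e[fix_rec[k]] -= delta

    # ---- genetic 6-blocks per animal --------------------------------------
    n_anim = u.shape[0]
    for n in range(n_anim):
        acc = np.zeros(NC)
        ann = 0.0
        for k in range(ai_ptr[n], ai_ptr[n + 1]):
            m = ai_idx[k]
            v = ai_val[k]
            if m == n:
                ann += v
            else:
                for c in range(NC):
                    acc[c] += v * u[m, c]
        P = ann * phi_inv
        b = -(phi_inv @ acc)
        for k in range(an_ptr[n], an_ptr[n + 1]):
            r = an_rec[k]
            ri = rinv_rec[r]
            c0 = rec_gcol0[r]
            f = rec_f[r]
            et = e[r] + u[n, c0] + f * u[n, c0 + 1]
            P[c0, c0] += ri
            P[c0, c0 + 1] += f * ri
            P[c0 + 1, c0] += f * ri
            P[c0 + 1, c0 + 1] += f * f * ri
            b[c0] += ri * et
            b[c0 + 1] += f * ri * et
        new_u = _sample_mvn_canonical(P, b, z_u[n])
        for k in range(an_ptr[n], an_ptr[n + 1]):
            r = an_rec[k]
            c0 = rec_gcol0[r]
            f = rec_f[r]
            e[r] -= (new_u[c0] - u[n, c0]) + f * (new_u[c0 + 1] - u[n, c0 + 1])
        for c in range(NC):
            u[n, c] = new_u[c]

    # ---- permanent-environment 6-blocks per cow ---------------------------
    n_cow = p.shape[0]
    for cidx in range(n_cow):
        P = psi_inv.copy()
        b = np.zeros(NC)
        for k in range(cw_ptr[cidx], cw_ptr[cidx + 1]):
            r = cw_rec[k]
            ri = rinv_rec[r]
            c0 = rec_gcol0[r]
            f = rec_f[r]
            et = e[r] + p[cidx, c0] + f * p[cidx, c0 + 1]
            P[c0, c0] += ri
            P[c0, c0 + 1] += f * ri
            P[c0 + 1, c0] += f * ri
            P[c0 + 1, c0 + 1] += f * f * ri
            b[c0] += ri * et
            b[c0 + 1] += f * ri * et
        new_p = _sample_mvn_canonical(P, b, z_p[cidx])
        for k in range(cw_ptr[cidx], cw_ptr[cidx + 1]):
            r = cw_rec[k]
            c0 = rec_gcol0[r]
            f = rec_f[r]
            e[r] -= (new_p[c0] - p[cidx, c0]) + f * (new_p[c0 + 1] - p[cidx, c0 + 1])
        for c in range(NC):
            p[cidx, c] = new_p[c]
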