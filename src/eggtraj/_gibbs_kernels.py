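"""Numba kernels for the Gibbs location sweep.

One sweep samples, in fixed order, every fixed effect (scalar full
conditionals), every animal's block of additive regression coefficients
(k-variate Gaussian full conditional, coupled across animals through the
sparse relationship inverse), and every hen's block of permanent
environmental coefficients.  The record residual vector ``e`` is kept
current throughout, so full-conditional right-hand sides are O(records per
effect).  Standard normal deviates are consumed sequentially from a
pre-generated array, which makes a sweep bit-reproducible for a given seed.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _chol_small(M, L, k):
    """Cholesky of a small PD matrix into L; returns 0 on success, 1 on failure."""
    for i in range(k):
        for j in range(i + 1):
            s = M[i, j]
            for m in range(j):
                s -= L[i, m] * L[j, m]
            if i == j:
                if s <= 0.0:
                    return 1
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return 0


@njit(cache=True)
def _sample_block(LHS, RHS, z, out, k):
    """Draw from N(LHS^-1 RHS, LHS^-1); returns number of jitter retries."""
    L = np.zeros((k, k))
    jitter = 0.0
    tries = 0
    while _chol_small(LHS, L, k) != 0:
        jitter = 1e-8 if jitter == 0.0 else jitter * 10.0
        for i in range(k):
            LHS[i, i] += jitter
        tries += 1
        if tries > 30:
            break
    # mean: solve L L' mu = RHS
    tmp = np.zeros(k)
    for i in range(k):
        s = RHS[i]
        for m in range(i):
            s -= L[i, m] * tmp[m]
        tmp[i] = s / L[i, i]
    mu = np.zeros(k)
    for i in range(k - 1, -1, -1):
        s = tmp[i]
        for m in range(i + 1, k):
            s -= L[m, i] * mu[m]
        mu[i] = s / L[i, i]
    # deviate: solve L' x = z so that Var(x) = LHS^-1
    for i in range(k - 1, -1, -1):
        s = z[i]
        for m in range(i + 1, k):
            s -= L[m, i] * out[m]
        out[i] = s / L[i, i]
    for i in range(k):
        out[i] += mu[i]
    return tries


@njit(cache=True)
def location_sweep(
    theta_fix,
    alpha,
    pe,
    e,
    # record structure
    rec_period,
    wrow,
    # fixed-effect columns (CSC over records)
    xcol_indptr,
    xcol_rec,
    xcol_val,
    # per-animal / per-hen record ranges
    astart,
    aend,
    hen_index,
    # bases and priors
    Phi,
    kindptr,
    kindices,
    kdata,
    Cinv,
    Pinv,
    rvar,
    z,
):
    """One systematic-scan sweep over all location effects (in place)."""
    k = Phi.shape[1]
    nf = theta_fix.shape[0]
    n_animals = alpha.shape[0]
    n_hens = pe.shape[0]
    iz = 0
    n_jitter = 0

    # --- fixed effects, scalar conditionals with flat priors ---
    for c in range(nf):
        lhs = 0.0
        rhs = 0.0
        for idx in range(xcol_indptr[c], xcol_indptr[c + 1]):
            r = xcol_rec[idx]
            v = xcol_val[idx]
            w = 1.0 / rvar[rec_period[r]]
            lhs += v * v * w
            rhs += v * (e[r] + v * theta_fix[c]) * w
        if lhs > 0.0:
            new = rhs / lhs + z[iz] / np.sqrt(lhs)
            delta = new - theta_fix[c]
            theta_fix[c] = new
            for idx in range(xcol_indptr[c], xcol_indptr[c + 1]):
                e[xcol_rec[idx]] -= xcol_val[idx] * delta
        iz += 1

    # --- additive coefficient blocks, coupled through the relationship inverse ---
    LHS = np.zeros((k, k))
    RHS = np.zeros(k)
    newb = np.zeros(k)
    for i in range(n_animals):
        aii = 0.0
        s = np.zeros(k)
        for idx in range(kindptr[i], kindptr[i + 1]):
            j = kindices[idx]
            v = kdata[idx]
            if j == i:
                aii += v
            else:
                for m in range(k):
                    s[m] += v * alpha[j, m]
        for a in range(k):
            RHS[a] = 0.0
            for b in range(k):
                LHS[a, b] = aii * Cinv[a, b]
                RHS[a] -= Cinv[a, b] * s[b]
        for r in range(astart[i], aend[i]):
            w = 1.0 / rvar[rec_period[r]]
            row = wrow[r]
            dot = 0.0
            for m in range(k):
                dot += Phi[row, m] * alpha[i, m]
            adj = e[r] + dot
            for a in range(k):
                RHS[a] += w * Phi[row, a] * adj
                for b in range(k):
                    LHS[a, b] += w * Phi[row, a] * Phi[row, b]
        n_jitter += _sample_block(LHS, RHS, z[iz:iz + k], newb, k)
        iz += k
        for r in range(astart[i], aend[i]):
            row = wrow[r]
            d = 0.0
            for m in range(k):
                d += Phi[row, m] * (newb[m] - alpha[i, m])
            e[r] -= d
        for m in range(k):
            alpha[i, m] = newb[m]

    # --- permanent environmental blocks, iid prior ---
    for h in range(n_hens):
        i = hen_index[h]
        for a in range(k):
            RHS[a] = 0.0
            for b in range(k):
                LHS[a, b] = Pinv[a, b]
        for r in range(astart[i], aend[i]):
            w = 1.0 / rvar[rec_period[r]]
            row = wrow[r]
            dot = 0.0
            for m in range(k):
                dot += Phi[row, m] * pe[h, m]
            adj = e[r] + dot
            for a in range(k):
                RHS[a] += w * Phi[row, a] * adj
                for b in range(k):
                    LHS[a, b] += w * Phi[row, a] * Phi[row, b]
        n_jitter += _sample_block(LHS, RHS, z[iz:iz + k], newb, k)
        iz += k
        for r in range(astart[i], aend[i]):
            row = wrow[r]
            d = 0.0
            for m in range(k):
                d += Phi[row, m] * (newb[m] - pe[h, m])
            e[r] -= d
        for m in range(k):
            pe[h, m] = newb[m]

    return n_jitter
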