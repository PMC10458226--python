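"""Cyclic coordinate-descent kernel for the elastic-net multinomial model.

The solver minimizes the penalized multinomial negative log-likelihood

    -1/n sum_i sum_k 1(y_i = k) log softmax_k(b + x_i' B)
    + lambda * sum_k [ alpha ||B_k||_1 + (1/2)(1 - alpha) ||B_k||_2^2 ]

by cycling over class blocks.  For class k (others fixed) a quadratic
approximation of the conditional loss is built at the current point with
IRLS weights w_i = p_ik (1 - p_ik) (floored away from zero) and working
response z_i = eta_ik + r_i / w_i, r_i = 1(y_i = k) - p_ik; coordinate
descent with soft-thresholding solves the penalized weighted least
squares, visiting zero coefficients only on periodic full sweeps
(active-set strategy).  Because the quadratic uses exact curvature rather
than a global bound, each block step is safeguarded: if the penalized
objective increased, the block iterate is halved back toward its previous
value until the objective is non-increasing, so the objective decreases
monotonically across outer iterations by construction.

Softmax state (per-row exponentials, their sums, and reference maxima) is
maintained incrementally as blocks change, so probabilities and objective
values cost O(n) per block instead of O(nK); the state is rebuilt
periodically to keep floating-point drift in check.

Columns of X must be standardized (zero mean, unit population variance;
constant columns all-zero) before entry.
"""

import numpy as np
from numba import njit

W_FLOOR = 1e-6


@njit(cache=True)
def _soft_threshold(g, t):
    if g > t:
        return g - t
    if g < -t:
        return g + t
    return 0.0


@njit(cache=True)
def _rebuild_softmax(eta, M, E, S):
    n, K = eta.shape
    for i in range(n):
        m = eta[i, 0]
        for k in range(1, K):
            if eta[i, k] > m:
                m = eta[i, k]
        M[i] = m
        s = 0.0
        for k in range(K):
            e = np.exp(eta[i, k] - m)
            E[i, k] = e
            s += e
        S[i] = s


@njit(cache=True)
def _nll(eta, y_idx, M, S):
    n = eta.shape[0]
    v = 0.0
    for i in range(n):
        v -= eta[i, y_idx[i]] - (M[i] + np.log(S[i]))
    return v / n


@njit(cache=True)
def _penalty_k(beta, k, alpha, lam):
    p = beta.shape[0]
    s = 0.0
    for j in range(p):
        bjk = beta[j, k]
        s += alpha * abs(bjk) + 0.5 * (1.0 - alpha) * bjk * bjk
    return lam * s


@njit(cache=True)
def _update_block_softmax(eta, k, M, E, S):
    """Refresh column k of the exponential cache after eta[:, k] changed."""
    n = eta.shape[0]
    for i in range(n):
        S[i] -= E[i, k]
        v = eta[i, k] - M[i]
        if v > 30.0:
            # new dominant score: rescale the row around the new reference
            scale = np.exp(M[i] - eta[i, k])
            S[i] *= scale
            for l in range(E.shape[1]):
                E[i, l] *= scale
            M[i] = eta[i, k]
            v = 0.0
        e = np.exp(v)
        E[i, k] = e
        S[i] += e
        if S[i] < 1e-12:
            # stale reference max left the whole row underflowed: rebuild
            Kk = E.shape[1]
            m = eta[i, 0]
            for l in range(1, Kk):
                if eta[i, l] > m:
                    m = eta[i, l]
            M[i] = m
            s = 0.0
            for l in range(Kk):
                el = np.exp(eta[i, l] - m)
                E[i, l] = el
                s += el
            S[i] = s


@njit(cache=True)
def cd_multinomial(Xt, y_idx, K, alpha, lam, beta, b, max_outer, tol, obj_tol):
    """In-place coordinate descent.

    Parameters
    ----------
    Xt : (p, n) C-contiguous standardized design, transposed.
    y_idx : (n,) integer class index per sample (0..K-1).
    beta : (p, K) coefficients, modified in place (warm start allowed).
    b : (K,) intercepts, modified in place.

    Returns
    -------
    (n_outer, converged_flag)
    """
    p, n = Xt.shape
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)

    # column mean squares of the standardized design (0 marks constants)
    colvar = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        colvar[j] = s / n

    eta = np.empty((n, K))
    for i in range(n):
        for k in range(K):
            e = b[k]
            for j in range(p):
                e += Xt[j, i] * beta[j, k]
            eta[i, k] = e

    M = np.empty(n)
    E = np.empty((n, K))
    S = np.empty(n)
    _rebuild_softmax(eta, M, E, S)

    pen = np.empty(K)
    for k in range(K):
        pen[k] = _penalty_k(beta, k, alpha, lam)

    w = np.empty(n)
    z = np.empty(n)
    res = np.empty(n)
    xw2 = np.empty(p)
    beta_old = np.empty(p)
    eta_old = np.empty(n)

    obj = _nll(eta, y_idx, M, S) + pen.sum()
    converged = False
    outer = 0
    for outer in range(1, max_outer + 1):
        if outer % 50 == 0:
            _rebuild_softmax(eta, M, E, S)  # limit floating-point drift
        obj_start = obj
        block_change = 0.0
        for k in range(K):
            # IRLS weights and working response at the current point
            for i in range(n):
                pik = E[i, k] / S[i]
                wi = pik * (1.0 - pik)
                if wi < W_FLOOR:
                    wi = W_FLOOR
                w[i] = wi
                r = (1.0 if y_idx[i] == k else 0.0) - pik
                z[i] = eta[i, k] + r / wi
                res[i] = r / wi
            wsum = 0.0
            for i in range(n):
                wsum += w[i]
            for j in range(p):
                if colvar[j] == 0.0:
                    xw2[j] = 0.0
                    continue
                s = 0.0
                for i in range(n):
                    s += w[i] * Xt[j, i] * Xt[j, i]
                xw2[j] = s / n
            for j in range(p):
                beta_old[j] = beta[j, k]
            b_old = b[k]
            for i in range(n):
                eta_old[i] = eta[i, k]

            # penalized weighted least squares by coordinate descent; the
            # quadratic is rebuilt every outer pass, so a few sweeps per
            # block suffice; zero coords are revisited on full sweeps
            for sweep in range(8):
                full = sweep % 5 == 0
                inner_change = 0.0
                d = 0.0
                for i in range(n):
                    d += w[i] * res[i]
                d /= wsum
                if d != 0.0:
                    b[k] += d
                    for i in range(n):
                        res[i] -= d
                    if abs(d) > inner_change:
                        inner_change = abs(d)
                for j in range(p):
                    if xw2[j] == 0.0:
                        continue
                    bj = beta[j, k]
                    if not full and bj == 0.0:
                        continue
                    g = 0.0
                    for i in range(n):
                        g += w[i] * Xt[j, i] * res[i]
                    g = g / n + xw2[j] * bj
                    bnew = _soft_threshold(g, l1) / (xw2[j] + l2)
                    d = bnew - bj
                    if d != 0.0:
                        beta[j, k] = bnew
                        for i in range(n):
                            res[i] -= d * Xt[j, i]
                        if abs(d) > inner_change:
                            inner_change = abs(d)
                if inner_change > block_change:
                    block_change = inner_change
                if inner_change < 0.1 * tol:
                    break
            for i in range(n):
                eta[i, k] = z[i] - res[i]
            _update_block_softmax(eta, k, M, E, S)
            pen_k_new = _penalty_k(beta, k, alpha, lam)

            # safeguard: halve back toward the previous iterate until the
            # penalized objective is non-increasing (exact-curvature steps
            # are not globally majorizing)
            obj_new = _nll(eta, y_idx, M, S) + pen.sum() - pen[k] + pen_k_new
            halvings = 0
            while obj_new > obj + 1e-12 and halvings < 30:
                for j in range(p):
                    beta[j, k] = 0.5 * (beta[j, k] + beta_old[j])
                b[k] = 0.5 * (b[k] + b_old)
                for i in range(n):
                    eta[i, k] = 0.5 * (eta[i, k] + eta_old[i])
                _update_block_softmax(eta, k, M, E, S)
                pen_k_new = _penalty_k(beta, k, alpha, lam)
                obj_new = _nll(eta, y_idx, M, S) + pen.sum() - pen[k] + pen_k_new
                halvings += 1
            if halvings == 30 and obj_new > obj + 1e-12:
                # no acceptable step: restore the previous iterate
                for j in range(p):
                    beta[j, k] = beta_old[j]
                b[k] = b_old
                for i in range(n):
                    eta[i, k] = eta_old[i]
                _update_block_softmax(eta, k, M, E, S)
                pen_k_new = _penalty_k(beta, k, alpha, lam)
                obj_new = obj
            pen[k] = pen_k_new
            obj = obj_new

            change = abs(b[k] - b_old)
            for j in range(p):
                d = abs(beta[j, k] - beta_old[j])
                if d > change:
                    change = d
            if change > block_change:
                block_change = change
        if block_change < tol:
            converged = True
            break
        # flat-direction exit: near-unpenalized fits on separable data keep
        # drifting in parameters while the objective has converged
        if outer > 1 and obj_start - obj < obj_tol * (abs(obj) + 1e-3):
            converged = True
            break
    return outer, converged


def standardize(X):
    """Zero-mean / unit-population-variance columns; constants -> all-zero.

    Returns (Xs, mean, scale); scale is 1 for constant columns so the
    transform is always invertible on the non-constant ones.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / scale
    Xs[:, sd == 0] = 0.0
    return Xs, mean, scale
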