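"""Batched one-dimensional Gaussian-mixture fitting.

The significance model fits a one- and a two-component Gaussian mixture to
every protein's abundance-window of background scores.  With thousands of
proteins each carrying its own ~200-point window, the fits are run as one
vectorized EM over a (windows × restarts, window_size) batch instead of a
per-window loop.  Windows of unequal length (pool edges, self-exclusion)
are padded and masked.

Conventions follow the common EM implementation choices: full-batch EM,
variance regularization ``reg_covar`` added to every M-step variance,
convergence on the change of the mean per-point log-likelihood, best
log-likelihood kept across restarts.  BIC uses 3K-1 free parameters for a
K-component 1-D mixture.
"""

from __future__ import annotations

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))


def _masked_em_2comp(
    X: np.ndarray,
    mask: np.ndarray,
    mu0: np.ndarray,
    sd0: np.ndarray,
    w0: np.ndarray,
    *,
    tol: float,
    max_iter: int,
    reg_covar: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run EM on a batch of rows; returns (weights, means, vars, mean_loglik).

    X, mask: (B, m); mu0/sd0: (B, 2); w0: (B, 2).  Rows converge
    independently; converged rows are dropped from the working set.
    """
    B = X.shape[0]
    w = w0.copy()
    mu = mu0.copy()
    var = sd0.copy() ** 2 + reg_covar
    n_valid = mask.sum(axis=1).astype(float)
    mean_ll = np.full(B, -np.inf)

    # compacted working set: rows still iterating; re-compacted only when a
    # sizable share has converged, so the hot loop avoids per-iteration
    # fancy-indexing copies of the whole batch
    active = np.arange(B)
    Xa, Ma = X, mask
    wa, mua, vara = w[active], mu[active], var[active]
    nva = n_valid
    lla = mean_ll[active]

    for _ in range(max_iter):
        # E-step: log N(x | mu_k, var_k) + log w_k, shape (b, 2, m)
        log_prob = Xa[:, None, :] - mua[:, :, None]
        np.square(log_prob, out=log_prob)
        log_prob /= vara[:, :, None]
        log_prob += (np.log(vara) + _LOG2PI)[:, :, None]
        log_prob *= -0.5
        log_prob += np.log(wa)[:, :, None]
        top = log_prob.max(axis=1, keepdims=True)
        resp = log_prob
        resp -= top
        np.exp(resp, out=resp)
        denom = resp.sum(axis=1)
        lse = top[:, 0, :] + np.log(denom)
        resp /= denom[:, None, :]
        resp *= Ma[:, None, :]

        ll = (lse * Ma).sum(axis=1) / nva

        # M-step
        nk = resp.sum(axis=2) + 10.0 * np.finfo(float).tiny
        wa = nk / nva[:, None]
        mua = (resp * Xa[:, None, :]).sum(axis=2) / nk
        dev = Xa[:, None, :] - mua[:, :, None]
        vara = (resp * dev**2).sum(axis=2) / nk + reg_covar

        done = np.abs(ll - lla) < tol
        lla = ll
        n_done = int(done.sum())
        if n_done == active.size:
            w[active], mu[active], var[active] = wa, mua, vara
            mean_ll[active] = lla
            break
        if n_done > active.size // 4:
            # flush converged rows back and shrink the working set
            w[active], mu[active], var[active] = wa, mua, vara
            mean_ll[active] = lla
            keep = ~done
            active = active[keep]
            Xa, Ma = X[active], mask[active]
            wa, mua, vara = wa[keep], mua[keep], vara[keep]
            nva, lla = n_valid[active], lla[keep]
    else:
        w[active], mu[active], var[active] = wa, mua, vara
        mean_ll[active] = lla

    return w, mu, var, mean_ll


def _final_loglik(X, mask, w, mu, var, n_valid):
    diff = X[:, None, :] - mu[:, :, None]
    log_prob = (
        -0.5 * (diff**2 / var[:, :, None] + np.log(var)[:, :, None] + _LOG2PI)
        + np.log(w)[:, :, None]
    )
    top = log_prob.max(axis=1, keepdims=True)
    lse = top[:, 0, :] + np.log(np.exp(log_prob - top).sum(axis=1))
    return (lse * mask).sum(axis=1)


def fit_1comp(X: np.ndarray, mask: np.ndarray, *, reg_covar: float = 1e-6):
    """Closed-form single-Gaussian fit per masked row.

    Returns (means, variances, total_loglik, bic), each of shape (B,).
    """
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = mask.sum(axis=1).astype(float)
    mu = (X * mask).sum(axis=1) / n
    sq = ((X - mu[:, None]) ** 2 * mask).sum(axis=1)
    var = sq / n + reg_covar
    ll = -0.5 * (n * (np.log(var) + _LOG2PI) + sq / var)
    bic = -2.0 * ll + 2.0 * np.log(n)
    return mu, var, ll, bic


def fit_2comp(
    X: np.ndarray,
    mask: np.ndarray,
    *,
    n_restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg_covar: float = 1e-6,
):
    """Two-component mixture fit per masked row, best of ``n_restarts``.

    Restart 0 initializes component means at the 25th/75th percentile of
    each window; the rest draw random window members.  Components are
    returned sorted by mean.  Returns (weights, means, variances,
    total_loglik, bic) with component axes of size 2.
    """
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    B, m = X.shape
    R = max(1, int(n_restarts))
    rng = np.random.default_rng(seed)
    n_valid = mask.sum(axis=1).astype(float)

    # per-window summary stats for initialization
    Xq = np.where(mask, X, np.nan)
    q25 = np.nanpercentile(Xq, 25, axis=1)
    q75 = np.nanpercentile(Xq, 75, axis=1)
    sd_all = np.sqrt(np.nanvar(Xq, axis=1)) + np.sqrt(reg_covar)

    mu0 = np.empty((B, R, 2))
    mu0[:, 0, 0] = q25
    mu0[:, 0, 1] = q75
    if R > 1:
        # sample random valid members as means for the remaining restarts
        u = rng.random((B, R - 1, 2))
        order = np.argsort(~mask, axis=1, kind="stable")  # valid indices first
        idx = np.minimum((u * n_valid[:, None, None]).astype(int), (n_valid - 1).astype(int)[:, None, None])
        picked = np.take_along_axis(order, idx.reshape(B, -1), axis=1).reshape(B, R - 1, 2)
        mu0[:, 1:, :] = np.take_along_axis(
            X, picked.reshape(B, -1), axis=1
        ).reshape(B, R - 1, 2)
    sd0 = np.broadcast_to(sd_all[:, None, None], (B, R, 2)).copy()
    w0 = np.full((B, R, 2), 0.5)

    # short-run EM initialization: every restart gets a burn-in, then only
    # the best-likelihood restart per window is run to full convergence
    burn_in = min(50, max_iter)
    Xb = np.repeat(X, R, axis=0)
    Mb = np.repeat(mask, R, axis=0)
    w, mu, var, _ = _masked_em_2comp(
        Xb,
        Mb,
        mu0.reshape(B * R, 2),
        sd0.reshape(B * R, 2),
        w0.reshape(B * R, 2),
        tol=tol,
        max_iter=burn_in,
        reg_covar=reg_covar,
    )
    ll = _final_loglik(Xb, Mb, w, mu, var, np.repeat(n_valid, R))
    best = ll.reshape(B, R).argmax(axis=1)
    sel = np.arange(B) * R + best
    w, mu, var = w[sel], mu[sel], var[sel]
    if max_iter > burn_in:
        w, mu, var, _ = _masked_em_2comp(
            X, mask, mu, np.sqrt(np.maximum(var - reg_covar, 0.0)), w,
            tol=tol, max_iter=max_iter - burn_in, reg_covar=reg_covar,
        )
    ll = _final_loglik(X, mask, w, mu, var, n_valid)

    order = np.argsort(mu, axis=1)
    w = np.take_along_axis(w, order, axis=1)
    mu = np.take_along_axis(mu, order, axis=1)
    var = np.take_along_axis(var, order, axis=1)
    bic = -2.0 * ll + 5.0 * np.log(n_valid)
    return w, mu, var, ll, bic
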