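"""Forward/backward recursions over the combined permutation state space.

The hidden state of the pillar chain is one track->subgenome permutation per
genome, i.e. a point in ``{0..5}^G`` encoded as a base-6 integer with genome 0
as the most significant digit.  Between adjacent pillars each genome's
permutation persists with probability ``1 - theta_g`` and is redrawn
uniformly over all six permutations otherwise, so the transition kernel
factorizes over genome axes and one step costs ``O(G * 6^G)``.

Kernels are compiled with numba when available; a NumPy fallback keeps the
package importable without it.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return deco

#: Scaling floor: when a pillar's emission mass underflows, its contribution
#: is floored at log(_TINY) and the chain restarted from uniform, keeping the
#: log-likelihood finite (and ordered in the number of underflowed pillars)
#: so that bounded optimizers can recover from absurd parameter corners.
_TINY = 1e-290
_LOG_TINY = np.log(1e-290)


@njit(cache=True)
def _apply_kernel(alpha, theta_row, G):
    """In place: per-genome persistence/redraw kernel along each base-6 axis."""
    S = alpha.shape[0]
    for g in range(G):
        th = theta_row[g]
        if th <= 0.0:
            continue
        stride = 1
        for _ in range(G - 1 - g):
            stride *= 6
        block = stride * 6
        for base in range(0, S, block):
            for b in range(stride):
                s0 = base + b
                tot = 0.0
                for d in range(6):
                    tot += alpha[s0 + d * stride]
                add = th * tot / 6.0
                keep = 1.0 - th
                for d in range(6):
                    idx = s0 + d * stride
                    alpha[idx] = keep * alpha[idx] + add


@njit(cache=True)
def forward_lnl(E_pat, pat_idx, theta_eff, G):
    """Scaled forward recursion; returns the total log-likelihood."""
    n = pat_idx.shape[0]
    S = E_pat.shape[1]
    alpha = np.empty(S)
    for s in range(S):
        alpha[s] = E_pat[pat_idx[0], s] / S
    c = alpha.sum()
    if c <= _TINY:
        lnl = _LOG_TINY
        alpha[:] = 1.0 / S
    else:
        lnl = np.log(c)
        alpha /= c
    for i in range(1, n):
        _apply_kernel(alpha, theta_eff[i], G)
        row = pat_idx[i]
        for s in range(S):
            alpha[s] *= E_pat[row, s]
        c = alpha.sum()
        if c <= _TINY:
            lnl += _LOG_TINY
            alpha[:] = 1.0 / S
        else:
            lnl += np.log(c)
            alpha /= c
    return lnl


@njit(cache=True)
def forward_backward(E_pat, pat_idx, theta_eff, G):
    """Posterior distribution over combined states at every pillar.

    Returns ``(gamma, lnl)`` with ``gamma[i]`` summing to one.
    """
    n = pat_idx.shape[0]
    S = E_pat.shape[1]
    A = np.empty((n, S))
    alpha = np.empty(S)
    for s in range(S):
        alpha[s] = E_pat[pat_idx[0], s] / S
    c = alpha.sum()
    if c <= _TINY:
        lnl = _LOG_TINY
        alpha[:] = 1.0 / S
    else:
        lnl = np.log(c)
        alpha /= c
    A[0] = alpha
    for i in range(1, n):
        _apply_kernel(alpha, theta_eff[i], G)
        row = pat_idx[i]
        for s in range(S):
            alpha[s] *= E_pat[row, s]
        c = alpha.sum()
        if c <= _TINY:
            lnl += _LOG_TINY
            alpha[:] = 1.0 / S
        else:
            lnl += np.log(c)
            alpha /= c
        A[i] = alpha
    gamma = np.empty((n, S))
    beta = np.ones(S)
    gamma[n - 1] = A[n - 1]
    for i in range(n - 2, -1, -1):
        v = np.empty(S)
        row = pat_idx[i + 1]
        for s in range(S):
            v[s] = E_pat[row, s] * beta[s]
        _apply_kernel(v, theta_eff[i + 1], G)
        v /= v.sum()
        beta = v
        g = A[i] * beta
        gamma[i] = g / g.sum()
    return gamma, lnl


# -- NumPy reference implementations (also used when numba is missing) ------------

def _apply_kernel_np(alpha, theta_row, G):
    a = alpha.reshape((6,) * G)
    for g in range(G):
        th = theta_row[g]
        if th <= 0.0:
            continue
        s = a.sum(axis=g, keepdims=True)
        a *= (1.0 - th)
        a += (th / 6.0) * s
    return alpha


def forward_lnl_np(E_pat, pat_idx, theta_eff, G):
    n = pat_idx.shape[0]
    S = E_pat.shape[1]
    alpha = E_pat[pat_idx[0]] / S
    c = alpha.sum()
    if c <= _TINY:
        lnl = _LOG_TINY
        alpha = np.full(S, 1.0 / S)
    else:
        lnl = np.log(c)
        alpha = alpha / c
    for i in range(1, n):
        _apply_kernel_np(alpha, theta_eff[i], G)
        alpha *= E_pat[pat_idx[i]]
        c = alpha.sum()
        if c <= _TINY:
            lnl += _LOG_TINY
            alpha[:] = 1.0 / S
        else:
            lnl += np.log(c)
            alpha /= c
    return lnl


def forward_backward_np(E_pat, pat_idx, theta_eff, G):
    n = pat_idx.shape[0]
    S = E_pat.shape[1]
    A = np.empty((n, S))
    alpha = E_pat[pat_idx[0]] / S
    c = alpha.sum()
    if c <= _TINY:
        lnl = _LOG_TINY
        alpha = np.full(S, 1.0 / S)
    else:
        lnl = np.log(c)
        alpha = alpha / c
    A[0] = alpha
    for i in range(1, n):
        _apply_kernel_np(alpha, theta_eff[i], G)
        alpha *= E_pat[pat_idx[i]]
        c = alpha.sum()
        if c <= _TINY:
            lnl += _LOG_TINY
            alpha[:] = 1.0 / S
        else:
            lnl += np.log(c)
            alpha /= c
        A[i] = alpha
    gamma = np.empty((n, S))
    beta = np.ones(S)
    gamma[n - 1] = A[n - 1]
    for i in range(n - 2, -1, -1):
        v = E_pat[pat_idx[i + 1]] * beta
        _apply_kernel_np(v, theta_eff[i + 1], G)
        v /= v.sum()
        beta = v
        g = A[i] * beta
        gamma[i] = g / g.sum()
    return gamma, lnl


if not HAVE_NUMBA:  # pragma: no cover
    forward_lnl = forward_lnl_np  # noqa: F811
    forward_backward = forward_backward_np  # noqa: F811
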