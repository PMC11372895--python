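"""Numba Euler kernel for the frustrated Kuramoto-Sakaguchi dynamics.

The per-step cost is dominated by the edge sweep, so edges are split into the
zero-lag intra-module set and the lagged inter-module set (single lag value
alpha), each stored as CSR index arrays over directed edges.  The sine of a
phase difference is expanded with precomputed cos/sin of the current phases so
no trigonometric call appears inside the edge loops.

Per-module phasor sums are accumulated at every step; all order parameters at
every hierarchical layer derive exactly from them.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def euler_ks(
    theta0,
    omega,
    K,
    dt,
    steps,
    iptr_in,
    idx_in,
    iptr_lag,
    idx_lag,
    cos_a,
    sin_a,
    mod_id,
    n_mod,
    rec_stride,
    n_rec,
):
    """Integrate ``steps`` explicit-Euler updates.

    Returns (theta_rec, S_re, S_im, theta_final):
      theta_rec: (n_rec, N) phases at states 0, rec_stride, 2*rec_stride, ...
      S_re/S_im: (steps, n_mod) per-module phasor sums at states 1..steps
      theta_final: phases after the last update (unwrapped)
    """
    N = theta0.shape[0]
    theta = theta0.copy()
    ct = np.cos(theta)
    st = np.sin(theta)
    S_re = np.zeros((steps, n_mod))
    S_im = np.zeros((steps, n_mod))
    theta_rec = np.empty((n_rec, N))
    dth = np.empty(N)
    rec_i = 0
    if n_rec > 0:
        theta_rec[0] = theta
        rec_i = 1
    for m in range(steps):
        for i in range(N):
            ci = ct[i]
            si = st[i]
            acc = 0.0
            for p in range(iptr_in[i], iptr_in[i + 1]):
                j = idx_in[p]
                acc += st[j] * ci - ct[j] * si
            for p in range(iptr_lag[i], iptr_lag[i + 1]):
                j = idx_lag[p]
                s = st[j] * ci - ct[j] * si
                c = ct[j] * ci + st[j] * si
                acc += s * cos_a - c * sin_a
            dth[i] = dt * (omega[i] + K * acc)
        for i in range(N):
            theta[i] += dth[i]
            ci = np.cos(theta[i])
            si = np.sin(theta[i])
            ct[i] = ci
            st[i] = si
            b = mod_id[i]
            S_re[m, b] += ci
            S_im[m, b] += si
        nxt = m + 1
        if rec_i < n_rec and nxt % rec_stride == 0:
            theta_rec[rec_i] = theta
            rec_i += 1
    return theta_rec, S_re, S_im, theta
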