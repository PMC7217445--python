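"""Fused single-pass kernels for the simulated likelihood and its score.

The numpy implementation in :mod:`ovichoice.gmnl` materializes
(rows x draws) utility arrays; these numba kernels compute the same
quantities in registers, one respondent-draw at a time, which keeps the
per-evaluation cost linear in rows x draws with a small constant.  The
numpy path remains the reference implementation and the two are asserted
equal in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


if HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=False)
    def loglik_kernel(
        base, Xr, s, eta, eps0, tau, gamma,
        sit_ptr, chosen_idx, resp_sit_ptr,
    ):
        """logP[n, d] = log probability of respondent n's choice sequence
        under draw d."""
        N, D = eps0.shape
        K = Xr.shape[1]
        logP = np.empty((N, D))
        u = np.empty(64)
        for n in range(N):
            for d in range(D):
                sigma = np.exp(-0.5 * tau * tau + tau * eps0[n, d])
                b = gamma + (1.0 - gamma) * sigma
                acc = 0.0
                for t in range(resp_sit_ptr[n], resp_sit_ptr[n + 1]):
                    lo, hi = sit_ptr[t], sit_ptr[t + 1]
                    m = -1e300
                    for r in range(lo, hi):
                        dev = 0.0
                        for k in range(K):
                            dev += Xr[r, k] * s[k] * eta[n, d, k]
                        val = sigma * base[r] + b * dev
                        u[r - lo] = val
                        if val > m:
                            m = val
                    z = 0.0
                    for r in range(lo, hi):
                        z += np.exp(u[r - lo] - m)
                    acc += u[chosen_idx[t] - lo] - m - np.log(z)
                logP[n, d] = acc
        return logP

    @numba.njit(cache=False, fastmath=False)
    def score_kernel(
        base, X, Xr, s, eta, eps0, tau, gamma, w,
        sit_ptr, chosen_idx, resp_sit_ptr, want_tau,
    ):
        """Draw-weighted score: grad[j] = sum_n sum_d w[n,d] dlogP/dtheta_j."""
        N, D = eps0.shape
        K = Xr.shape[1]
        P = X.shape[1]
        grad = np.zeros(P + K + 1)
        u = np.empty(64)
        dv = np.empty(64)
        for n in range(N):
            for d in range(D):
                wn = w[n, d]
                if wn == 0.0:
                    continue
                sigma = np.exp(-0.5 * tau * tau + tau * eps0[n, d])
                b = gamma + (1.0 - gamma) * sigma
                etau = eps0[n, d] - tau
                for t in range(resp_sit_ptr[n], resp_sit_ptr[n + 1]):
                    lo, hi = sit_ptr[t], sit_ptr[t + 1]
                    m = -1e300
                    for r in range(lo, hi):
                        dev = 0.0
                        for k in range(K):
                            dev += Xr[r, k] * s[k] * eta[n, d, k]
                        val = sigma * base[r] + b * dev
                        u[r - lo] = val
                        dv[r - lo] = dev
                        if val > m:
                            m = val
                    z = 0.0
                    for r in range(lo, hi):
                        e = np.exp(u[r - lo] - m)
                        u[r - lo] = e  # reuse buffer for exp values
                        z += e
                    for r in range(lo, hi):
                        p = u[r - lo] / z
                        resid = (1.0 if r == chosen_idx[t] else 0.0) - p
                        c = wn * resid
                        cs = c * sigma
                        for j in range(P):
                            grad[j] += cs * X[r, j]
                        cb = c * b
                        for k in range(K):
                            grad[P + k] += cb * Xr[r, k] * eta[n, d, k]
                        if want_tau:
                            grad[P + K] += c * etau * (
                                sigma * base[r] + (1.0 - gamma) * sigma * dv[r - lo]
                            )
        return grad
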