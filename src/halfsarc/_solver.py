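"""Numba kernel for the per-step equilibrium relaxation.

Same algorithm as the reference implementation in :mod:`halfsarc.mechanics`
(Gauss-Seidel over filaments, exact tridiagonal Newton per chain, crossbridge
loads linearized at current offsets): tests assert the kernel's result against
the pure-python force assembly.  Kept separate so the mechanics module stays
readable.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=False)
def _xb_force_stiff(b, ls, k_r, k_th, r_eq, th_eq):
    r = np.sqrt(b * b + ls * ls)
    theta = np.arctan2(ls, b)
    dr = r - r_eq
    dth = theta - th_eq
    drdb = b / r
    dthdb = -ls / (r * r)
    e_prime = k_r * dr * drdb + k_th * dth * dthdb
    e_second = (k_r * (drdb * drdb + dr * ls * ls / r ** 3)
                + k_th * (dthdb * dthdb + dth * 2.0 * ls * b / r ** 4))
    return -e_prime, e_second


@njit(fastmath=False)
def _thomas(diag, rhs, k):
    """Solve tridiag(-k, diag, -k) x = rhs in place; returns x."""
    n = diag.size
    cp = np.empty(n)
    dp = np.empty(n)
    cp[0] = -k / diag[0]
    dp[0] = rhs[0] / diag[0]
    for i in range(1, n):
        m = diag[i] + k * cp[i - 1]
        cp[i] = -k / m
        dp[i] = (rhs[i] + k * dp[i - 1]) / m
    x = np.empty(n)
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


@njit(fastmath=False)
def balance_kernel(thick_x, thin_x, length, k_thick, k_thin, crown_sp,
                   site_sp, titin_f, xb_tfil, xb_tcrown, xb_afil, xb_asite,
                   xb_post, ls, k_r, k_th, rr_pre, rth_pre, rr_post, rth_post,
                   tol, max_iter, relax):
    """Relax node positions until max |node force| <= tol.

    Mutates thick_x (nT, nc) and thin_x (nA, ns).  Returns (residual, iters).
    """
    nT, nc = thick_x.shape
    nA, ns = thin_x.shape
    nxb = xb_tfil.size

    f_site = np.empty(nxb)
    k_lin = np.empty(nxb)
    thick_f = np.empty((nT, nc))
    thin_f = np.empty((nA, ns))

    for it in range(max_iter):
        # crossbridge loads at current offsets
        for m in range(nxb):
            b = thin_x[xb_afil[m], xb_asite[m]] - thick_x[xb_tfil[m], xb_tcrown[m]]
            if xb_post[m]:
                f, k2 = _xb_force_stiff(b, ls, k_r, k_th, rr_post, rth_post)
            else:
                f, k2 = _xb_force_stiff(b, ls, k_r, k_th, rr_pre, rth_pre)
            f_site[m] = f
            k_lin[m] = k2 if k2 > 0.0 else 0.0

        # assemble residuals
        resid = 0.0
        for fi in range(nT):
            for i in range(nc):
                lo = thick_x[fi, i] - (thick_x[fi, i - 1] if i > 0 else 0.0) - crown_sp
                force = -k_thick * lo
                if i < nc - 1:
                    hi = thick_x[fi, i + 1] - thick_x[fi, i] - crown_sp
                    force += k_thick * hi
                else:
                    force += titin_f
                thick_f[fi, i] = force
        for fi in range(nA):
            for j in range(ns):
                hi = (thin_x[fi, j + 1] if j < ns - 1 else length) - thin_x[fi, j] - site_sp
                force = k_thin * hi
                if j > 0:
                    lo = thin_x[fi, j] - thin_x[fi, j - 1] - site_sp
                    force -= k_thin * lo
                thin_f[fi, j] = force
        for m in range(nxb):
            thin_f[xb_afil[m], xb_asite[m]] += f_site[m]
            thick_f[xb_tfil[m], xb_tcrown[m]] -= f_site[m]
        for fi in range(nT):
            for i in range(nc):
                a = abs(thick_f[fi, i])
                if a > resid:
                    resid = a
        for fi in range(nA):
            for j in range(ns):
                a = abs(thin_f[fi, j])
                if a > resid:
                    resid = a
        if resid <= tol:
            return resid, it

        # per-node crossbridge stiffness
        kx_thick = np.zeros((nT, nc))
        kx_thin = np.zeros((nA, ns))
        for m in range(nxb):
            kx_thick[xb_tfil[m], xb_tcrown[m]] += k_lin[m]
            kx_thin[xb_afil[m], xb_asite[m]] += k_lin[m]

        # thick update (anchored at M-line below node 0)
        for fi in range(nT):
            diag = np.empty(nc)
            for i in range(nc):
                d = k_thick  # anchor or lower neighbor
                if i < nc - 1:
                    d += k_thick
                diag[i] = d + kx_thick[fi, i]
            dx = _thomas(diag, thick_f[fi], k_thick)
            for i in range(nc):
                thick_x[fi, i] += relax * dx[i]

        # refresh crossbridge + thin residuals with moved thick nodes
        for fi in range(nA):
            for j in range(ns):
                hi = (thin_x[fi, j + 1] if j < ns - 1 else length) - thin_x[fi, j] - site_sp
                force = k_thin * hi
                if j > 0:
                    lo = thin_x[fi, j] - thin_x[fi, j - 1] - site_sp
                    force -= k_thin * lo
                thin_f[fi, j] = force
        for m in range(nxb):
            b = thin_x[xb_afil[m], xb_asite[m]] - thick_x[xb_tfil[m], xb_tcrown[m]]
            if xb_post[m]:
                f, _k2 = _xb_force_stiff(b, ls, k_r, k_th, rr_post, rth_post)
            else:
                f, _k2 = _xb_force_stiff(b, ls, k_r, k_th, rr_pre, rth_pre)
            thin_f[xb_afil[m], xb_asite[m]] += f

        # thin update (anchored at Z-disk above the last node)
        for fi in range(nA):
            diag = np.empty(ns)
            for j in range(ns):
                d = k_thin  # anchor or upper neighbor
                if j > 0:
                    d += k_thin
                diag[j] = d + kx_thin[fi, j]
            dy = _thomas(diag, thin_f[fi], k_thin)
            for j in range(ns):
                thin_x[fi, j] += relax * dy[j]

    return resid, max_iter
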