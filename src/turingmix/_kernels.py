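"""Compiled inner loops for the explicit-Euler time stepper.

The kernels update the fields in place for ``nsteps`` steps and return the
index of the first step at which the open-simplex invariant was violated
(-1 on success).  They mirror, operation for operation, the numpy
implementation in :mod:`turingmix.simulator`; a cross-check test enforces
agreement.  If numba is unavailable the plain-Python versions still run
(slowly).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=True, fastmath=True)
def run_1d(phiA, phiI, phi0, chi, h, k, DA, DI, w2, dx, dt, nsteps):
    """Advance the conservative dynamics on a periodic 1D grid."""
    N = phiA.shape[0]
    lpA = np.empty(N)
    lpI = np.empty(N)
    muA = np.empty(N)
    muI = np.empty(N)
    fA = np.empty(N)  # face fluxes at i+1/2
    fI = np.empty(N)
    nA = np.empty(N)
    nI = np.empty(N)
    inv_dx = 1.0 / dx
    inv_dx2 = inv_dx * inv_dx
    for step in range(nsteps):
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            im = i - 1 if i > 0 else N - 1
            lpA[i] = np.log(phiA[i])
            lpI[i] = np.log(phiI[i])
            ls = np.log(1.0 - phiA[i] - phiI[i])
            lapA = (phiA[ip] + phiA[im] - 2.0 * phiA[i]) * inv_dx2
            lapI = (phiI[ip] + phiI[im] - 2.0 * phiI[i]) * inv_dx2
            muA[i] = lpA[i] - ls + chi * phiI[i] - w2 * lapA
            muI[i] = lpI[i] - ls + chi * phiA[i] - w2 * lapI
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            fA[i] = 0.5 * (DA * phiA[i] + DA * phiA[ip]) * (muA[ip] - muA[i]) * inv_dx
            fI[i] = 0.5 * (DI * phiI[i] + DI * phiI[ip]) * (muI[ip] - muI[i]) * inv_dx
        for i in range(N):
            im = i - 1 if i > 0 else N - 1
            divA = (fA[i] - fA[im]) * inv_dx
            divI = (fI[i] - fI[im]) * inv_dx
            x = h * (lpI[i] - lpA[i])
            if x > 0.0:
                e = np.exp(-x)
                prod = 2.0 * phi0 * e / (1.0 + e)
            else:
                e = np.exp(x)
                prod = 2.0 * phi0 / (1.0 + e)
            nA[i] = phiA[i] + dt * (divA + k * (prod - phiA[i]))
            nI[i] = phiI[i] + dt * (divI + k * (prod - phiI[i]))
        for i in range(N):
            if not (nA[i] > 0.0 and nI[i] > 0.0 and nA[i] + nI[i] < 1.0):
                return step
        for i in range(N):
            phiA[i] = nA[i]
            phiI[i] = nI[i]
    return -1


@njit(cache=True, fastmath=True)
def run_2d(phiA, phiI, phi0, chi, h, k, DA, DI, w2, dx, dt, nsteps):
    """Advance the conservative dynamics on a periodic 2D grid (5-point stencil).

    The transcendental-heavy per-cell work runs over flat views so it
    vectorizes; only the stencil loops use 2D neighbor indexing.
    """
    NX, NY = phiA.shape
    n = NX * NY
    fa = phiA.reshape(n)
    fi = phiI.reshape(n)
    lpA = np.empty(n)
    lpI = np.empty(n)
    ent = np.empty(n)  # ln(phi_i) - ln(phi_S) pieces share this solvent log
    prod = np.empty(n)
    muA = np.empty((NX, NY))
    muI = np.empty((NX, NY))
    fAx = np.empty((NX, NY))  # faces at (i+1/2, j)
    fIx = np.empty((NX, NY))
    fAy = np.empty((NX, NY))  # faces at (i, j+1/2)
    fIy = np.empty((NX, NY))
    nA = np.empty((NX, NY))
    nI = np.empty((NX, NY))
    ipx = np.empty(NX, dtype=np.int64)
    imx = np.empty(NX, dtype=np.int64)
    for i in range(NX):
        ipx[i] = i + 1 if i + 1 < NX else 0
        imx[i] = i - 1 if i > 0 else NX - 1
    jpy = np.empty(NY, dtype=np.int64)
    jmy = np.empty(NY, dtype=np.int64)
    for j in range(NY):
        jpy[j] = j + 1 if j + 1 < NY else 0
        jmy[j] = j - 1 if j > 0 else NY - 1
    inv_dx = 1.0 / dx
    inv_dx2 = inv_dx * inv_dx
    for step in range(nsteps):
        for c in range(n):
            lpA[c] = np.log(fa[c])
            lpI[c] = np.log(fi[c])
            ent[c] = np.log(1.0 - fa[c] - fi[c])
        for c in range(n):
            x = h * (lpI[c] - lpA[c])
            e = np.exp(-np.abs(x))
            if x > 0.0:
                prod[c] = 2.0 * phi0 * e / (1.0 + e)
            else:
                prod[c] = 2.0 * phi0 / (1.0 + e)
        lpA2 = lpA.reshape((NX, NY))
        lpI2 = lpI.reshape((NX, NY))
        ent2 = ent.reshape((NX, NY))
        for i in range(NX):
            ip = ipx[i]
            im = imx[i]
            for j in range(NY):
                jp = jpy[j]
                jm = jmy[j]
                lapA = (
                    phiA[ip, j] + phiA[im, j] + phiA[i, jp] + phiA[i, jm] - 4.0 * phiA[i, j]
                ) * inv_dx2
                lapI = (
                    phiI[ip, j] + phiI[im, j] + phiI[i, jp] + phiI[i, jm] - 4.0 * phiI[i, j]
                ) * inv_dx2
                muA[i, j] = lpA2[i, j] - ent2[i, j] + chi * phiI[i, j] - w2 * lapA
                muI[i, j] = lpI2[i, j] - ent2[i, j] + chi * phiA[i, j] - w2 * lapI
        for i in range(NX):
            ip = ipx[i]
            for j in range(NY):
                jp = jpy[j]
                fAx[i, j] = 0.5 * (DA * phiA[i, j] + DA * phiA[ip, j]) * (muA[ip, j] - muA[i, j]) * inv_dx
                fIx[i, j] = 0.5 * (DI * phiI[i, j] + DI * phiI[ip, j]) * (muI[ip, j] - muI[i, j]) * inv_dx
                fAy[i, j] = 0.5 * (DA * phiA[i, j] + DA * phiA[i, jp]) * (muA[i, jp] - muA[i, j]) * inv_dx
                fIy[i, j] = 0.5 * (DI * phiI[i, j] + DI * phiI[i, jp]) * (muI[i, jp] - muI[i, j]) * inv_dx
        prod2 = prod.reshape((NX, NY))
        for i in range(NX):
            im = imx[i]
            for j in range(NY):
                jm = jmy[j]
                divA = (fAx[i, j] - fAx[im, j]) * inv_dx + (fAy[i, j] - fAy[i, jm]) * inv_dx
                divI = (fIx[i, j] - fIx[im, j]) * inv_dx + (fIy[i, j] - fIy[i, jm]) * inv_dx
                nA[i, j] = phiA[i, j] + dt * (divA + k * (prod2[i, j] - phiA[i, j]))
                nI[i, j] = phiI[i, j] + dt * (divI + k * (prod2[i, j] - phiI[i, j]))
        ok = True
        for i in range(NX):
            for j in range(NY):
                if not (nA[i, j] > 0.0 and nI[i, j] > 0.0 and nA[i, j] + nI[i, j] < 1.0):
                    ok = False
        if not ok:
            return step
        for i in range(NX):
            for j in range(NY):
                phiA[i, j] = nA[i, j]
                phiI[i, j] = nI[i, j]
    return -1


@njit(cache=True, fastmath=True)
def run_ideal_1d(phiA, phiI, phi0, h, k, D00, D01, D10, D11, dx, dt, nsteps):
    """Ideal-diffusion dynamics with a constant 2x2 diffusivity matrix (1D)."""
    N = phiA.shape[0]
    nA = np.empty(N)
    nI = np.empty(N)
    inv_dx2 = 1.0 / (dx * dx)
    for step in range(nsteps):
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            im = i - 1 if i > 0 else N - 1
            lapA = (phiA[ip] + phiA[im] - 2.0 * phiA[i]) * inv_dx2
            lapI = (phiI[ip] + phiI[im] - 2.0 * phiI[i]) * inv_dx2
            x = h * (np.log(phiI[i]) - np.log(phiA[i]))
            if x > 0.0:
                e = np.exp(-x)
                prod = 2.0 * phi0 * e / (1.0 + e)
            else:
                e = np.exp(x)
                prod = 2.0 * phi0 / (1.0 + e)
            nA[i] = phiA[i] + dt * (D00 * lapA + D01 * lapI + k * (prod - phiA[i]))
            nI[i] = phiI[i] + dt * (D10 * lapA + D11 * lapI + k * (prod - phiI[i]))
        for i in range(N):
            if not (nA[i] > 0.0 and nI[i] > 0.0 and nA[i] + nI[i] < 1.0):
                return step
        for i in range(N):
            phiA[i] = nA[i]
            phiI[i] = nI[i]
    return -1
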