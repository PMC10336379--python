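"""Independent numerical oracles used by the tests.

These deliberately avoid the package's closed-form implementations: finite
differences for derivatives, a common-tangent solver for the binodal, and a
matrix logarithm to extract linear growth matrices from simulations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import fsolve


def finite_difference_jacobian(func, x0, eps=1e-6):
    """Central finite-difference Jacobian of a vector function of 2 variables."""
    x0 = np.asarray(x0, dtype=float)
    J = np.zeros((2, 2))
    for j in range(2):
        dx = np.zeros(2)
        dx[j] = eps
        fp = np.asarray(func(*(x0 + dx)))
        fm = np.asarray(func(*(x0 - dx)))
        J[:, j] = (fp - fm) / (2 * eps)
    return J


def symmetric_mixture_free_energy(phi, chi):
    """f(phi) = phi ln(phi/2) + (1-phi) ln(1-phi) + chi phi^2 / 4.

    Free energy of the symmetric composition path phiA = phiI = phi/2 of the
    three-component mixture; the associative binodal lives on this path.
    """
    return phi * np.log(phi / 2.0) + (1.0 - phi) * np.log(1.0 - phi) + chi * phi * phi / 4.0


def _mu(phi, chi):
    return np.log(phi / 2.0) - np.log(1.0 - phi) + chi * phi / 2.0


def _grand_potential(phi, chi):
    # f - phi f'; equal in coexisting phases (osmotic-pressure balance)
    return symmetric_mixture_free_energy(phi, chi) - phi * _mu(phi, chi)


def binodal_chi(phi0, guess_chi=-10.0):
    """Interaction strength putting the composition ``2 phi0`` on the binodal.

    Solves equal chemical potential and equal osmotic pressure between the
    phase at ``phi1 = 2 phi0`` and an unknown coexisting phase ``phi2``,
    treating ``(phi2, chi)`` as unknowns.  Brute-force common-tangent oracle,
    fully independent of any closed-form threshold.
    """
    phi1 = 2.0 * phi0

    def eqs(x):
        phi2, chi = x
        return [
            _mu(phi1, chi) - _mu(phi2, chi),
            _grand_potential(phi1, chi) - _grand_potential(phi2, chi),
        ]

    x0 = np.array([1.0 - phi1, guess_chi])
    sol, info, ier, msg = fsolve(eqs, x0, full_output=True, xtol=1e-13)
    if ier != 1:
        raise RuntimeError(f"binodal solver failed for phi0={phi0}: {msg}")
    phi2, chi = sol
    if abs(phi2 - phi1) < 1e-6:
        raise RuntimeError(f"binodal solver collapsed onto the trivial root at phi0={phi0}")
    return float(chi)


def growth_matrix_from_simulation(params, grid, mode, t_total, n_steps, amplitude=1e-6):
    """Extract the per-mode 2x2 linear growth matrix from two simulations.

    Perturbs first phiA, then phiI, with a single commensurate sine mode of
    tiny amplitude, reads off the complex Fourier coefficients after
    ``t_total``, and returns ``logm(E)/t_total`` where ``E`` maps initial to
    final coefficient vectors.  Works for complex eigenvalue pairs too.
    """
    from scipy.linalg import logm

    from turingmix.simulator import FieldState, _run_kernel

    N = grid.shape[0]
    x = np.arange(N) * grid.dx
    q = 2.0 * np.pi * mode / (N * grid.dx)
    dt = t_total / n_steps
    E = np.zeros((2, 2), dtype=complex)
    for col, (dA, dI) in enumerate([(1.0, 0.0), (0.0, 1.0)]):
        phiA = params.phi0 + amplitude * dA * np.sin(q * x)
        phiI = params.phi0 + amplitude * dI * np.sin(q * x)
        state = FieldState(grid, phiA, phiI, 0.0)
        _run_kernel(state, params, dt, n_steps)
        c0 = np.fft.rfft(np.sin(q * x))[mode] * amplitude
        E[0, col] = np.fft.rfft(state.phiA - params.phi0)[mode] / c0
        E[1, col] = np.fft.rfft(state.phiI - params.phi0)[mode] / c0
    return logm(E) / t_total
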