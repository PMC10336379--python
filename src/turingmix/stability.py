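"""Linear stability analysis of the homogeneous state.

Linearizing the conservative dynamics about ``phiA = phiI = phi0`` gives, for
a perturbation ``~ exp(i q x + sigma t)``, the 2x2 dynamical matrix

    J(q) = -q**2 * M @ (H + w**2 q**2 * Id) + R,

with mobility matrix ``M = diag(D_A phi0, D_I phi0)``, local Hessian ``H``
and reaction Jacobian ``R``.  The growth rate ``sigma_max(q)`` is the larger
real part of the two eigenvalues, computed from the closed-form
trace/determinant expression (exact and fast in parameter sweeps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .core_model import ModelParams, local_hessian, reaction_jacobian

__all__ = [
    "DispersionCurve",
    "StableStateError",
    "BracketError",
    "default_q_grid",
    "dynamical_matrix",
    "sigma_max_at",
    "dispersion_relation",
    "effective_diffusivity_matrix",
    "chi_star",
    "stability_boundary",
    "lsa_length_scale",
]

#: growth rates above this (in units D_A/w**2) count as unstable
INSTABILITY_TOL = 1e-10

#: reference box size defining the smallest resolvable wavenumber
L_REF = 2000.0


class StableStateError(RuntimeError):
    """Raised when an operation requires an unstable homogeneous state."""


class BracketError(RuntimeError):
    """Raised when a bisection bracket does not straddle a verdict change."""


@dataclass
class DispersionCurve:
    """Growth rates of the linearized dynamics over a wavenumber grid."""

    q: np.ndarray
    sigma_max: np.ndarray
    q_star: float
    sigma_star: float
    unstable: bool
    params: Optional[ModelParams] = field(default=None, repr=False)

    def to_csv(self, path: Union[str, Path]) -> None:
        arr = np.column_stack([self.q, self.sigma_max])
        np.savetxt(path, arr, delimiter=",", header="q,sigma_max", comments="")

    def report(self) -> dict:
        """JSON-serializable stability report."""
        out = {
            "unstable": self.unstable,
            "q_star": self.q_star,
            "sigma_star": self.sigma_star,
            "n_q": int(len(self.q)),
        }
        if self.params is not None:
            out["params"] = self.params.to_dict()
        return out

    def to_json(self, path: Union[str, Path]) -> None:
        import json

        Path(path).write_text(json.dumps(self.report(), indent=2))


def default_q_grid(w: float = 1.0, n: int = 1024) -> np.ndarray:
    """Log-spaced wavenumbers covering reaction-diffusion and interfacial scales.

    Spans ``[2 pi / L_ref, pi / w]`` with ``L_ref = 2000 w`` (the largest box
    used in replication runs).
    """
    return np.geomspace(2.0 * np.pi / (L_REF * w), np.pi / w, n)


def dynamical_matrix(params: ModelParams, q: float) -> np.ndarray:
    """Linearized dynamics at wavenumber ``q`` (exact 2x2 matrix).

    At ``q = 0`` this reduces to the reaction Jacobian.  Pass the discrete
    wavenumber ``q_eff = sqrt(2 - 2 cos(q dx)) / dx`` to obtain the matrix
    that governs single-mode growth in the finite-difference simulator.
    """
    if q < 0.0:
        raise ValueError("q must be >= 0")
    phi0 = params.phi0
    M = np.diag([params.D_A * phi0, params.D_I * phi0])
    H = local_hessian(phi0, phi0, params)
    R = reaction_jacobian(params)
    q2 = q * q
    return -q2 * M @ (H + params.w**2 * q2 * np.eye(2)) + R


def _sigma_max_vectorized(params: ModelParams, q: np.ndarray) -> np.ndarray:
    """Largest real part of the eigenvalues of J(q), for an array of q."""
    phi0 = params.phi0
    H = local_hessian(phi0, phi0, params)
    R = reaction_jacobian(params)
    q2 = np.asarray(q, dtype=float) ** 2
    w2 = params.w**2
    mA = params.D_A * phi0
    mI = params.D_I * phi0
    # entries of J(q) = -q^2 M (H + w^2 q^2 I) + R
    a = -q2 * mA * (H[0, 0] + w2 * q2) + R[0, 0]
    b = -q2 * mA * H[0, 1] + R[0, 1]
    c = -q2 * mI * H[1, 0] + R[1, 0]
    d = -q2 * mI * (H[1, 1] + w2 * q2) + R[1, 1]
    tr = a + d
    # stable form of the discriminant; clamp roundoff-level values to zero so
    # degenerate pairs (e.g. the double root -k at q=0) come out exact
    half_diff = 0.5 * (a - d)
    disc = half_diff * half_diff + b * c
    scale = np.maximum(np.maximum(np.abs(a), np.abs(d)), np.maximum(np.abs(b), np.abs(c))) ** 2
    disc = np.where(disc < 1e-13 * scale, 0.0, disc)
    sigma = 0.5 * tr + np.sqrt(disc)
    return sigma


def sigma_max_at(params: ModelParams, q: float) -> float:
    """Largest eigenvalue real part of the dynamical matrix at one ``q``."""
    return float(_sigma_max_vectorized(params, np.asarray([q]))[0])


def dispersion_relation(params: ModelParams, q_grid: Optional[Sequence[float]] = None) -> DispersionCurve:
    """Evaluate ``sigma_max(q)`` on a grid and classify stability.

    ``q = 0`` is always prepended as a reference (its growth rate equals
    ``-k``); the fastest-growing mode and the instability verdict consider
    only ``q > 0``.  Ties at plateaus resolve to the smallest ``q``.
    """
    if q_grid is None:
        q_grid = default_q_grid(params.w)
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise ValueError("q_grid must be nonempty")
    if np.any(q < 0.0):
        raise ValueError("wavenumbers must be >= 0")
    q = np.unique(q)
    if q[0] > 0.0:
        q = np.concatenate([[0.0], q])
    sigma = _sigma_max_vectorized(params, q)
    positive = q > 0.0
    i_star = int(np.argmax(sigma[positive]))
    q_pos = q[positive]
    s_pos = sigma[positive]
    sigma_star = float(s_pos[i_star])
    # ties -> smallest q
    ties = np.flatnonzero(s_pos >= sigma_star - 0.0)
    i_star = int(ties[0]) if ties.size else i_star
    return DispersionCurve(
        q=q,
        sigma_max=sigma,
        q_star=float(q_pos[i_star]),
        sigma_star=sigma_star,
        unstable=bool(sigma_star > INSTABILITY_TOL * params.D_A / params.w**2),
        params=params,
    )


def effective_diffusivity_matrix(params: ModelParams) -> np.ndarray:
    """First-order (in chi) effective diffusivity matrix of the linearization.

    ``D = [[D_A(1+psi), D_A(psi + chi phi0)], [D_I(psi + chi phi0), D_I(1+psi)]]``
    with ``psi = phi0 / (1 - 2 phi0)``; identically equal to
    ``diag(D_A phi0, D_I phi0) @ local_hessian(phi0, phi0)``.
    """
    phi0 = params.phi0
    psi = phi0 / (1.0 - 2.0 * phi0)
    return np.array(
        [
            [params.D_A * (1.0 + psi), params.D_A * (psi + params.chi * phi0)],
            [params.D_I * (psi + params.chi * phi0), params.D_I * (1.0 + psi)],
        ]
    )


def _is_unstable(params: ModelParams, q_grid: np.ndarray) -> bool:
    sigma = _sigma_max_vectorized(params, q_grid)
    return bool(np.max(sigma) > INSTABILITY_TOL * params.D_A / params.w**2)


def chi_star(
    params: ModelParams,
    chi_bracket: tuple[float, float] = (-15.0, 10.0),
    tol: float = 1e-4,
    prescan: int = 26,
    q_grid: Optional[np.ndarray] = None,
) -> float:
    """Minimal interaction strength supporting patterns, by bisection.

    Scans ``chi`` over the bracket on ``prescan`` equally spaced points, finds
    the upper stable-to-unstable transition (the largest stable ``chi``
    followed by an unstable one) and bisects it to within ``tol``.  The
    ``chi`` field of ``params`` is ignored.  If every prescan point is
    unstable the whole bracket supports patterns and the lower bracket end
    is returned; if none is stable above an unstable region a
    :class:`BracketError` is raised with diagnostics.
    """
    if q_grid is None:
        q_grid = default_q_grid(params.w)
    chis = np.linspace(chi_bracket[0], chi_bracket[1], prescan)
    verdicts = [_is_unstable(params.with_(chi=float(c)), q_grid) for c in chis]
    if all(verdicts):
        return float(chi_bracket[0])
    # largest stable chi that is followed by an unstable one
    lo = hi = None
    for i in range(len(chis) - 1, 0, -1):
        if verdicts[i] and not verdicts[i - 1]:
            lo, hi = float(chis[i - 1]), float(chis[i])
            break
    if lo is None:
        s_lo = dispersion_relation(params.with_(chi=chi_bracket[0]), q_grid).sigma_star
        s_hi = dispersion_relation(params.with_(chi=chi_bracket[1]), q_grid).sigma_star
        raise BracketError(
            "no stable-to-unstable transition in bracket "
            f"{chi_bracket}; sigma_star at ends: {s_lo:.3e}, {s_hi:.3e}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _is_unstable(params.with_(chi=mid), q_grid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


_AXIS_SETTERS = {
    "h": lambda p, v: p.with_(h=v),
    "k": lambda p, v: p.with_(k=v),
    "chi": lambda p, v: p.with_(chi=v),
    "phi0": lambda p, v: p.with_(phi0=v),
    "D_I": lambda p, v: p.with_(D_I=v),
    "D_A": lambda p, v: p.with_(D_A=v),
    "D_I/D_A": lambda p, v: p.with_(D_I=v * p.D_A),
}


def set_axis(params: ModelParams, axis: str, value: float) -> ModelParams:
    """Return params with the named axis (including ``D_I/D_A``) set."""
    try:
        return _AXIS_SETTERS[axis](params, float(value))
    except KeyError:
        raise ValueError(f"unknown axis {axis!r}; one of {sorted(_AXIS_SETTERS)}") from None


def stability_boundary(
    base: ModelParams,
    axis: str,
    axis_range: tuple[float, float],
    resolution: int,
    chi_range: tuple[float, float] = (-15.0, 10.0),
    n_chi_scan: int = 26,
    tol: float = 1e-4,
) -> list[tuple[float, list[float]]]:
    """Locate the chi values where the stability verdict flips, per axis value.

    For each of ``resolution`` values of ``axis`` the chi interval is scanned
    on ``n_chi_scan`` points and every verdict flip is refined by bisection.
    Points where bracketing fails are recorded with an empty boundary list
    and a warning.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    q_grid = default_q_grid(base.w)
    out: list[tuple[float, list[float]]] = []
    for val in np.linspace(axis_range[0], axis_range[1], resolution):
        p = set_axis(base, axis, float(val))
        chis = np.linspace(chi_range[0], chi_range[1], n_chi_scan)
        try:
            verdicts = [_is_unstable(p.with_(chi=float(c)), q_grid) for c in chis]
            boundaries = []
            for i in range(len(chis) - 1):
                if verdicts[i] != verdicts[i + 1]:
                    lo, hi = float(chis[i]), float(chis[i + 1])
                    ref = verdicts[i]
                    while hi - lo > tol:
                        mid = 0.5 * (lo + hi)
                        if _is_unstable(p.with_(chi=mid), q_grid) == ref:
                            lo = mid
                        else:
                            hi = mid
                    boundaries.append(0.5 * (lo + hi))
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"boundary search failed at {axis}={val}: {exc}")
            boundaries = []
        out.append((float(val), boundaries))
    return out


def lsa_length_scale(params: ModelParams, q_grid: Optional[np.ndarray] = None) -> float:
    """Wavelength ``2 pi / q_star`` of the fastest-growing linear mode."""
    curve = dispersion_relation(params, q_grid)
    if not curve.unstable:
        raise StableStateError(
            f"homogeneous state is linearly stable (sigma_star={curve.sigma_star:.3e}); "
            "no fastest-growing mode"
        )
    return 2.0 * np.pi / curve.q_star
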