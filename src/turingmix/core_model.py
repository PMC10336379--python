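"""Thermodynamics and reaction kinetics of the two-species interacting mixture.

The mixture consists of an activator ``A``, an inhibitor ``I`` and an inert
solvent ``S`` with volume fractions ``phiA + phiI + phiS = 1``.  The local
free-energy density (in units of ``k_B T / nu``) is the Flory--Huggins form

    f = phiA ln phiA + phiI ln phiI + phiS ln phiS + chi phiA phiI
        + (w**2 / 2) (|grad phiA|**2 + |grad phiI|**2)

and the chemical reactions follow a Hill--Langmuir production term with
linear degradation,

    R_i = k * (2 phi0 / (1 + (phiI/phiA)**h) - phi_i),   i = A, I.

All quantities are nondimensional: lengths in units of the interfacial
width ``w``, times in units of ``w**2 / D_A``, energy densities in units of
``k_B T / nu``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Union

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelParams",
    "DomainError",
    "homogeneous_state",
    "reaction_rates",
    "reaction_jacobian",
    "local_chemical_potentials",
    "free_energy_density",
    "local_hessian",
    "chi_plus",
    "chi_minus",
]


class DomainError(ValueError):
    """A volume fraction left the open simplex {phiA>0, phiI>0, phiA+phiI<1}."""


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the model, in nondimensional units.

    Attributes
    ----------
    phi0 : float
        Mean volume fraction of each of the two species, ``0 < phi0 < 1/2``.
    chi : float
        Flory interaction parameter; positive means effective repulsion
        between the two species, negative means attraction.
    h : float
        Hill exponent of the production term, ``h >= 1``.
    k : float
        Reaction (degradation) rate in units of ``D_A / w**2``.
    D_A, D_I : float
        Diffusivities of activator and inhibitor.
    w : float
        Interfacial width parameter (the length unit; default 1).
    """

    phi0: float
    chi: float = 0.0
    h: float = 1.0
    k: float = 0.0
    D_A: float = 1.0
    D_I: float = 1.0
    w: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.phi0 < 0.5:
            raise ValueError(f"phi0 must lie in (0, 1/2), got {self.phi0}")
        if self.h < 1.0:
            raise ValueError(f"h must be >= 1, got {self.h}")
        if self.k < 0.0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        for name in ("D_A", "D_I", "w"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yml", ".yaml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: Union[str, Path]) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


# -- kinetics --------------------------------------------------------------


def homogeneous_state(params: ModelParams) -> tuple[float, float]:
    """Homogeneous fixed point (phiA, phiI) = (phi0, phi0) of the reactions."""
    return (params.phi0, params.phi0)


def reaction_rates(phiA, phiI, params: ModelParams):
    """Hill--Langmuir production with linear degradation for both species.

    Returns ``(R_A, R_I)`` with
    ``R_i = k * (2 phi0 / (1 + (phiI/phiA)**h) - phi_i)``.  Applies
    elementwise to arrays.  The Hill ratio is evaluated through a logistic
    of log-fractions, so extreme ratios neither overflow nor lose the
    saturation limits 0 and ``2 phi0``.
    """
    phiA = np.asarray(phiA, dtype=float)
    phiI = np.asarray(phiI, dtype=float)
    if np.any(phiA <= 0.0):
        idx = np.unravel_index(int(np.argmin(phiA)), phiA.shape)
        raise DomainError(f"phiA must be > 0; offending value {phiA[idx]} at index {idx}")
    if np.any(phiI < 0.0):
        idx = np.unravel_index(int(np.argmin(phiI)), phiI.shape)
        raise DomainError(f"phiI must be >= 0; offending value {phiI[idx]} at index {idx}")
    # 2*phi0 / (1 + r**h) with r = phiI/phiA, via the stable logistic form.
    with np.errstate(divide="ignore"):
        log_ratio = np.log(phiI) - np.log(phiA)
    production = 2.0 * params.phi0 * expit(-params.h * log_ratio)
    rA = params.k * (production - phiA)
    rI = params.k * (production - phiI)
    if rA.ndim == 0:
        return (float(rA), float(rI))
    return (rA, rI)


def reaction_jacobian(params: ModelParams) -> np.ndarray:
    """Derivatives of the reaction rates at the homogeneous state.

    Closed form ``[[k(h/2-1), -k h/2], [k h/2, -k(h/2+1)]]``; trace ``-2k``
    and determinant ``k**2`` (both eigenvalues equal ``-k``).
    """
    k, h = params.k, params.h
    return np.array([[k * (h / 2.0 - 1.0), -k * h / 2.0], [k * h / 2.0, -k * (h / 2.0 + 1.0)]])


# -- thermodynamics --------------------------------------------------------


def _check_simplex(phiA, phiI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    phiA = np.asarray(phiA, dtype=float)
    phiI = np.asarray(phiI, dtype=float)
    phiS = 1.0 - phiA - phiI
    if np.any(phiA <= 0.0) or np.any(phiI <= 0.0) or np.any(phiS <= 0.0):
        bad = np.argmin(np.minimum(np.minimum(phiA, phiI), phiS))
        idx = np.unravel_index(int(bad), np.broadcast(phiA, phiI).shape)
        raise DomainError(
            f"fractions outside the open simplex at index {idx}: "
            f"phiA={np.broadcast_to(phiA, np.broadcast(phiA, phiI).shape)[idx]}, "
            f"phiI={np.broadcast_to(phiI, np.broadcast(phiA, phiI).shape)[idx]}"
        )
    return phiA, phiI, phiS


def local_chemical_potentials(phiA, phiI, params: ModelParams):
    """Local part of the exchange chemical potentials (no gradient term).

    ``mu_i = ln phi_i - ln phiS + chi * phi_j`` with ``phiS = 1 - phiA - phiI``.
    The square-gradient contribution ``-w**2 lap(phi_i)`` is added by the
    simulator, which owns the discretization.
    """
    phiA, phiI, phiS = _check_simplex(phiA, phiI)
    lS = np.log(phiS)
    muA = np.log(phiA) - lS + params.chi * phiI
    muI = np.log(phiI) - lS + params.chi * phiA
    if muA.ndim == 0:
        return (float(muA), float(muI))
    return (muA, muI)


def free_energy_density(phiA, phiI, gradsqA=0.0, gradsqI=0.0, params: ModelParams = None):
    """Free-energy density, including optional squared-gradient contributions.

    ``gradsqA``/``gradsqI`` are ``|grad phi_i|**2`` evaluated by the caller;
    they default to 0 (uniform state).
    """
    phiA, phiI, phiS = _check_simplex(phiA, phiI)
    gradsqA = np.asarray(gradsqA, dtype=float)
    gradsqI = np.asarray(gradsqI, dtype=float)
    if np.any(gradsqA < 0.0) or np.any(gradsqI < 0.0):
        raise ValueError("squared-gradient arguments must be >= 0")
    f = (
        phiA * np.log(phiA)
        + phiI * np.log(phiI)
        + phiS * np.log(phiS)
        + params.chi * phiA * phiI
        + 0.5 * params.w**2 * (gradsqA + gradsqI)
    )
    if f.ndim == 0:
        return float(f)
    return f


def local_hessian(phiA, phiI, params: ModelParams) -> np.ndarray:
    """Second derivatives ``d mu_i / d phi_j`` of the local free energy.

    Symmetric 2x2 matrix; positive definite iff the local mixture is
    thermodynamically stable.
    """
    phiA, phiI, phiS = _check_simplex(phiA, phiI)
    inv_S = 1.0 / phiS
    return np.array(
        [
            [1.0 / phiA + inv_S, inv_S + params.chi],
            [inv_S + params.chi, 1.0 / phiI + inv_S],
        ]
    )


# -- phase-separation thresholds ------------------------------------------


def _check_phi0(phi0: float) -> float:
    phi0 = float(phi0)
    if not 0.0 < phi0 < 0.5:
        raise ValueError(f"phi0 must lie in (0, 1/2), got {phi0}")
    return phi0


def chi_plus(phi0: float) -> float:
    """Segregative (A-vs-I) spinodal threshold ``chi_+ = 1/phi0``.

    Above this interaction strength the two species demix spontaneously even
    without reactions: the (1, -1) eigenvalue ``1/phi0 - chi`` of the local
    Hessian at the homogeneous state turns negative.
    """
    return 1.0 / _check_phi0(phi0)


def chi_minus(phi0: float) -> float:
    """Associative (A+I vs solvent) binodal threshold.

    ``chi_- = 8 arctanh(1 - 4 phi0) / (4 phi0 - 1)``: the interaction at which
    the homogeneous composition sits exactly on the binodal of the symmetric
    mixture.  Continuously extended to ``-8`` at ``phi0 = 1/4``.
    """
    phi0 = _check_phi0(phi0)
    y = 1.0 - 4.0 * phi0
    if abs(y) < 1e-6:
        # arctanh(y)/y = 1 + y^2/3 + y^4/5 + ...
        return -8.0 * (1.0 + y * y / 3.0)
    return -8.0 * math.atanh(y) / y
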