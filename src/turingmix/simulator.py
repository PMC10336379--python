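"""Conservative finite-difference integration on periodic 1D/2D grids.

Discretization follows the classic conservative scheme for fourth-order
interface dynamics: second-order central stencils for the Laplacian inside
the chemical potentials, chemical-potential gradients evaluated on a
staggered grid (cell faces) with arithmetically averaged mobilities
``D_i phi_i``, divergence of the face fluxes back to cell centers, and an
explicit Euler update.  Face fluxes telescope under periodic boundaries, so
each species' total fraction is conserved to roundoff when reactions are
off.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np

from . import _kernels
from .core_model import (
    DomainError,
    ModelParams,
    free_energy_density,
    local_chemical_potentials,
    local_hessian,
    reaction_rates,
)

__all__ = [
    "Grid",
    "FieldState",
    "SimConfig",
    "SimResult",
    "BlowUpError",
    "ConfigError",
    "initial_condition",
    "full_chemical_potentials",
    "flux_divergence",
    "mobility",
    "stable_dt",
    "step",
    "simulate",
    "simulate_ideal",
    "total_free_energy",
    "save_result",
    "load_state",
]

SCHEMA_VERSION = 1


class BlowUpError(RuntimeError):
    """Integration left the open simplex; reduce dt or check parameters."""

    def __init__(self, message: str, time: float = float("nan"), index=None):
        super().__init__(message)
        self.time = time
        self.index = index


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Grid:
    """Periodic, equidistant grid in one or two dimensions."""

    shape: tuple
    dx: float = 1.0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in (self.shape if np.iterable(self.shape) else (self.shape,)))
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (1, 2):
            raise ValueError("only 1D and 2D grids are supported")
        if any(s < 8 for s in shape):
            raise ValueError("grid needs at least 8 points per axis")
        if self.dx <= 0:
            raise ValueError("dx must be > 0")

    @property
    def dims(self) -> int:
        return len(self.shape)

    @property
    def lengths(self) -> tuple:
        return tuple(s * self.dx for s in self.shape)

    @property
    def cell_volume(self) -> float:
        return self.dx ** self.dims


@dataclass
class FieldState:
    """Volume-fraction fields of both species on a grid, at one time."""

    grid: Grid
    phiA: np.ndarray
    phiI: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.phiA = np.asarray(self.phiA, dtype=float)
        self.phiI = np.asarray(self.phiI, dtype=float)
        if self.phiA.shape != self.grid.shape or self.phiI.shape != self.grid.shape:
            raise ValueError("field shapes must match the grid")

    @property
    def phiS(self) -> np.ndarray:
        return 1.0 - self.phiA - self.phiI

    def validate(self) -> None:
        if not (
            np.all(self.phiA > 0.0)
            and np.all(self.phiI > 0.0)
            and np.all(self.phiA + self.phiI < 1.0)
        ):
            bad = np.argmin(np.minimum(np.minimum(self.phiA, self.phiI), self.phiS))
            idx = np.unravel_index(int(bad), self.grid.shape)
            raise DomainError(f"simplex invariant violated at index {idx}")

    def copy(self) -> "FieldState":
        return FieldState(self.grid, self.phiA.copy(), self.phiI.copy(), self.time)


@dataclass
class SimConfig:
    """Time-integration configuration.

    ``dt="auto"`` resolves to :func:`stable_dt` with the given safety factor.
    ``snapshot_every`` is a time interval; ``None`` stores only the final
    state.  ``early_stop`` enables the optional stationarity criterion
    (relative change of the (amplitude, covariance, length) triple below
    1e-6 over a window of 100 snapshots); it is off by default to mirror the
    fixed-duration replication protocol.
    """

    t_end: float
    dt: Union[float, str] = "auto"
    snapshot_every: Optional[float] = None
    seed: int = 0
    noise_amplitude: float = 1e-3
    safety: float = 0.5
    early_stop: bool = False

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ConfigError("t_end must be > 0")
        if self.dt != "auto" and (not isinstance(self.dt, (int, float)) or self.dt <= 0):
            raise ConfigError("dt must be positive or 'auto'")
        if not 0.0 < self.safety <= 1.0:
            raise ConfigError("safety must lie in (0, 1]")
        if self.noise_amplitude < 0.0:
            raise ConfigError("noise_amplitude must be >= 0")


@dataclass
class SimResult:
    """Final state plus snapshots, with full provenance."""

    state: FieldState
    snapshots: List[FieldState]
    params: ModelParams
    config: SimConfig
    dt: float
    stopped_early: bool = False


def initial_condition(params: ModelParams, grid: Grid, config: SimConfig) -> FieldState:
    """Homogeneous state plus independent, seeded uniform noise per cell.

    Both fields get i.i.d. noise in ``[-noise_amplitude, +noise_amplitude]``
    drawn from ``default_rng(config.seed)``; identical seeds give
    bit-identical states.
    """
    a = config.noise_amplitude
    phi0 = params.phi0
    if phi0 - a <= 0.0 or 2.0 * (phi0 + a) >= 1.0:
        raise ConfigError(
            f"noise_amplitude {a} incompatible with the simplex at phi0={phi0}"
        )
    rng = np.random.default_rng(config.seed)
    phiA = phi0 + rng.uniform(-a, a, size=grid.shape)
    phiI = phi0 + rng.uniform(-a, a, size=grid.shape)
    state = FieldState(grid, phiA, phiI, 0.0)
    state.validate()
    return state


def _lap(f: np.ndarray, dx: float) -> np.ndarray:
    out = -2.0 * f.ndim * f
    for ax in range(f.ndim):
        out = out + np.roll(f, -1, axis=ax) + np.roll(f, 1, axis=ax)
    return out / (dx * dx)


def full_chemical_potentials(state: FieldState, params: ModelParams):
    """Exchange chemical potentials including the square-gradient term.

    Adds ``-w**2 lap(phi_i)`` (3-point / 5-point periodic stencil) to the
    local part.  For uniform fields the Laplacian vanishes exactly.
    """
    try:
        muA, muI = local_chemical_potentials(state.phiA, state.phiI, params)
    except DomainError as exc:
        raise BlowUpError(
            f"state left the simplex while evaluating chemical potentials ({exc}); "
            "reduce dt",
            time=state.time,
        ) from exc
    w2 = params.w**2
    dx = state.grid.dx
    muA = muA - w2 * _lap(state.phiA, dx)
    muI = muI - w2 * _lap(state.phiI, dx)
    return muA, muI


def mobility(phi: np.ndarray, D: float) -> np.ndarray:
    """Onsager mobility ``D * phi`` (isolated so alternatives can be swapped)."""
    return D * phi


def _single_flux_divergence(phi: np.ndarray, mu: np.ndarray, D: float, dx: float) -> np.ndarray:
    mob = mobility(phi, D)
    div = np.zeros_like(phi)
    for ax in range(phi.ndim):
        face_mob = 0.5 * (mob + np.roll(mob, -1, axis=ax))
        grad_mu = (np.roll(mu, -1, axis=ax) - mu) / dx
        flux = face_mob * grad_mu
        div = div + (flux - np.roll(flux, 1, axis=ax)) / dx
    return div


def flux_divergence(state: FieldState, mu, params: ModelParams):
    """Divergence of the staggered-grid fluxes ``D_i phi_i grad mu_i``.

    Gradients live on cell faces; mobilities at faces are arithmetic means
    of the adjacent cells.  The grid sum of each output is zero to roundoff
    (telescoping under periodic boundaries).
    """
    muA, muI = mu
    dx = state.grid.dx
    divA = _single_flux_divergence(state.phiA, muA, params.D_A, dx)
    divI = _single_flux_divergence(state.phiI, muI, params.D_I, dx)
    return divA, divI


def stable_dt(params: ModelParams, grid: Grid, safety: float = 0.5) -> float:
    """Explicit-Euler step bound for the stiffest resolvable mode.

    ``dt = safety / sigma_bound`` with
    ``sigma_bound = max_i D_i phi_max (H_max q_max**2 + w**2 q_max**4) + 2k``,
    ``q_max = pi/dx`` per axis (times ``sqrt(dims)`` combined), a headroom
    ``phi_max = 2 phi0`` and ``H_max`` the largest absolute Hessian entry at
    the homogeneous state.
    """
    if not 0.0 < safety <= 1.0:
        raise ValueError("safety must lie in (0, 1]")
    H = local_hessian(params.phi0, params.phi0, params)
    H_max = float(np.max(np.abs(H)))
    q_max2 = grid.dims * (np.pi / grid.dx) ** 2
    phi_max = 2.0 * params.phi0
    D_max = max(params.D_A, params.D_I)
    sigma_bound = D_max * phi_max * (H_max * q_max2 + params.w**2 * q_max2**2) + 2.0 * params.k
    return safety / sigma_bound


def step(state: FieldState, params: ModelParams, dt: float) -> FieldState:
    """One explicit Euler step (reference numpy path).

    The homogeneous state is an exact fixed point; with ``k = 0`` the grid
    sum of each field is conserved to roundoff.  Raises :class:`BlowUpError`
    if the update leaves the open simplex.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    mu = full_chemical_potentials(state, params)
    divA, divI = flux_divergence(state, mu, params)
    rA, rI = reaction_rates(state.phiA, state.phiI, params)
    phiA = state.phiA + dt * (divA + rA)
    phiI = state.phiI + dt * (divI + rI)
    new = FieldState(state.grid, phiA, phiI, state.time + dt)
    try:
        new.validate()
    except DomainError as exc:
        raise BlowUpError(
            f"blow-up at t={state.time + dt:.6g}: {exc}; try dt <= {dt / 4:.3e}",
            time=state.time + dt,
        ) from exc
    return new


def _run_kernel(state: FieldState, params: ModelParams, dt: float, nsteps: int) -> None:
    """Advance ``state`` in place by ``nsteps`` via the compiled kernel."""
    args = (
        params.phi0,
        params.chi,
        params.h,
        params.k,
        params.D_A,
        params.D_I,
        params.w**2,
        state.grid.dx,
        dt,
        nsteps,
    )
    if state.grid.dims == 1:
        bad = _kernels.run_1d(state.phiA, state.phiI, *args)
    else:
        bad = _kernels.run_2d(state.phiA, state.phiI, *args)
    if bad >= 0:
        t = state.time + (bad + 1) * dt
        raise BlowUpError(
            f"blow-up at t={t:.6g} (step {bad} of chunk); try dt <= {dt / 4:.3e}",
            time=t,
        )
    state.time += nsteps * dt


def _resolve_dt(params: ModelParams, grid: Grid, config: SimConfig) -> float:
    if config.dt == "auto":
        return stable_dt(params, grid, config.safety)
    return float(config.dt)


def simulate(init: FieldState, params: ModelParams, config: SimConfig) -> SimResult:
    """Integrate from ``init`` until ``t_end`` (or stationarity, if enabled)."""
    init.validate()
    state = init.copy()
    dt = _resolve_dt(params, state.grid, config)
    n_total = int(np.ceil(config.t_end / dt))
    if config.snapshot_every is None:
        chunk = n_total
    else:
        chunk = max(1, int(round(config.snapshot_every / dt)))
    snapshots: List[FieldState] = []
    history: List[tuple] = []
    stopped_early = False
    done = 0
    while done < n_total:
        n = min(chunk, n_total - done)
        _run_kernel(state, params, dt, n)
        done += n
        if config.snapshot_every is not None:
            snapshots.append(state.copy())
            if config.early_stop:
                from .metrics import pattern_metrics_triple

                history.append(pattern_metrics_triple(state))
                if _stationary(history):
                    stopped_early = True
                    break
    return SimResult(
        state=state,
        snapshots=snapshots,
        params=params,
        config=config,
        dt=dt,
        stopped_early=stopped_early,
    )


def _stationary(history: List[tuple], window: int = 100, rtol: float = 1e-6) -> bool:
    if len(history) < window + 1:
        return False
    recent = np.asarray(history[-(window + 1):], dtype=float)
    lo = np.nanmin(recent, axis=0)
    hi = np.nanmax(recent, axis=0)
    scale = np.maximum(np.nanmax(np.abs(recent), axis=0), 1e-30)
    return bool(np.all((hi - lo) / scale < rtol))


def simulate_ideal(
    init: FieldState,
    params: ModelParams,
    config: SimConfig,
    D: Optional[np.ndarray] = None,
) -> SimResult:
    """Integrate the ideal-diffusion dynamics with a constant diffusivity matrix.

    Used for the ideal-limit comparison: with ``chi = 0`` and pattern
    wavelengths much larger than ``w`` the full model reduces to this one.
    ``D`` defaults to the first-order effective diffusivity matrix.  1D only.
    """
    from .stability import effective_diffusivity_matrix

    if init.grid.dims != 1:
        raise NotImplementedError("ideal-diffusion integration is 1D only")
    if D is None:
        D = effective_diffusivity_matrix(params)
    init.validate()
    state = init.copy()
    dt = _resolve_dt(params, state.grid, config)
    n_total = int(np.ceil(config.t_end / dt))
    bad = _kernels.run_ideal_1d(
        state.phiA,
        state.phiI,
        params.phi0,
        params.h,
        params.k,
        float(D[0, 0]),
        float(D[0, 1]),
        float(D[1, 0]),
        float(D[1, 1]),
        state.grid.dx,
        dt,
        n_total,
    )
    if bad >= 0:
        raise BlowUpError(f"ideal-model blow-up at step {bad}", time=bad * dt)
    state.time += n_total * dt
    return SimResult(state=state, snapshots=[], params=params, config=config, dt=dt)


def total_free_energy(state: FieldState, params: ModelParams) -> float:
    """Discrete total free energy (density summed times cell volume).

    Gradient terms use forward differences so the staggered flux scheme is
    the exact gradient flow of this functional in continuous time.
    """
    dx = state.grid.dx
    gradsqA = np.zeros_like(state.phiA)
    gradsqI = np.zeros_like(state.phiI)
    for ax in range(state.grid.dims):
        gradsqA = gradsqA + ((np.roll(state.phiA, -1, axis=ax) - state.phiA) / dx) ** 2
        gradsqI = gradsqI + ((np.roll(state.phiI, -1, axis=ax) - state.phiI) / dx) ** 2
    f = free_energy_density(state.phiA, state.phiI, gradsqA, gradsqI, params)
    return float(np.sum(f) * state.grid.cell_volume)


# -- persistence -----------------------------------------------------------


def save_result(path: Union[str, Path], result: SimResult) -> None:
    """Write final state (and snapshots) to HDF5 with full provenance."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["params"] = json.dumps(result.params.to_dict())
        f.attrs["grid_shape"] = result.state.grid.shape
        f.attrs["grid_dx"] = result.state.grid.dx
        cfg = asdict(result.config)
        f.attrs["config"] = json.dumps(cfg)
        f.attrs["dt"] = result.dt
        f.attrs["time"] = result.state.time
# track_times=False keeps repeated runs bit-identical (no embedded mtimes)
        f.create_dataset("phiA", data=result.state.phiA, track_times=False)
        f.create_dataset("phiI", data=result.state.phiI, track_times=False)
        if result.snapshots:
            g = f.create_group("snapshots")
            g.create_dataset("times", data=[s.time for s in result.snapshots], track_times=False)
            g.create_dataset(
                "phiA", data=np.stack([s.phiA for s in result.snapshots]), track_times=False
            )
            g.create_dataset(
                "phiI", data=np.stack([s.phiI for s in result.snapshots]), track_times=False
            )


def load_state(path: Union[str, Path]) -> tuple:
    """Read ``(FieldState, ModelParams)`` back from :func:`save_result` output."""
    import h5py

    with h5py.File(path, "r") as f:
        params = ModelParams.from_dict(json.loads(f.attrs["params"]))
        grid = Grid(tuple(int(s) for s in f.attrs["grid_shape"]), float(f.attrs["grid_dx"]))
        state = FieldState(grid, f["phiA"][...], f["phiI"][...], float(f.attrs["time"]))
    return state, params
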