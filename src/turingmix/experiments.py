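"""Scan drivers: parameter-plane sweeps, 1D-vs-2D comparison, figure tables.

Each scan cell runs one seeded simulation plus a linear stability verdict;
per-cell seeds derive deterministically from the master seed and the cell
index, so scans are reproducible and insensitive to evaluation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_model import ModelParams
from .metrics import pattern_metrics, try_dominant_length
from .simulator import (
    BlowUpError,
    FieldState,
    Grid,
    SimConfig,
    SimResult,
    initial_condition,
    simulate,
)
from .stability import chi_star, dispersion_relation, set_axis

__all__ = [
    "ScanTable",
    "cell_seed",
    "scan_phase_diagram",
    "compare_1d_2d",
    "chi_star_table",
    "droplet_count",
]

SCHEMA_VERSION = 1


def cell_seed(master_seed: int, i: int, j: int = 0) -> int:
    """Deterministic per-cell seed derived from the master seed and cell index."""
    return int(np.random.SeedSequence([int(master_seed), int(i), int(j)]).generate_state(1)[0])


@dataclass
class ScanTable:
    """Rectangular two-axis sweep with one metrics record per cell."""

    axis1: str
    axis2: str
    values1: np.ndarray
    values2: np.ndarray
    table: pd.DataFrame
    base: ModelParams
    config: SimConfig
    master_seed: int
    schema_version: int = SCHEMA_VERSION

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)

    def manifest(self) -> dict:
        from . import __version__

        return {
            "schema_version": self.schema_version,
            "version": __version__,
            "axis1": self.axis1,
            "axis2": self.axis2,
            "values1": list(map(float, self.values1)),
            "values2": list(map(float, self.values2)),
            "base_params": self.base.to_dict(),
            "config": {
                "t_end": self.config.t_end,
                "dt": self.config.dt,
                "noise_amplitude": self.config.noise_amplitude,
                "safety": self.config.safety,
            },
            "master_seed": self.master_seed,
        }

    def write_manifest(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def scan_phase_diagram(
    base: ModelParams,
    axis1: tuple,
    axis2: tuple,
    sim: SimConfig,
    grid: Optional[Grid] = None,
    master_seed: int = 0,
) -> ScanTable:
    """Simulate every cell of a two-axis parameter sweep and collect metrics.

    ``axis1``/``axis2`` are ``(name, values)`` with names among
    {chi, h, k, D_I, D_A, D_I/D_A, phi0}.  Cells whose integration blows up
    are recorded with ``failed=True`` and the scan continues.
    """
    if grid is None:
        grid = Grid((200,), dx=1.0)
    name1, values1 = axis1
    name2, values2 = axis2
    values1 = np.asarray(values1, dtype=float)
    values2 = np.asarray(values2, dtype=float)
    rows = []
    for i, v1 in enumerate(values1):
        for j, v2 in enumerate(values2):
            p = set_axis(set_axis(base, name1, v1), name2, v2)
            seed = cell_seed(master_seed, i, j)
            curve = dispersion_relation(p)
            row = {
                name1: v1,
                name2: v2,
                "seed": seed,
                "lsa_unstable": curve.unstable,
                "sigma_star": curve.sigma_star,
                "failed": False,
                "amplitude": np.nan,
                "covariance": np.nan,
                "length": np.nan,
            }
            cfg = SimConfig(
                t_end=sim.t_end,
                dt=sim.dt,
                snapshot_every=sim.snapshot_every,
                seed=seed,
                noise_amplitude=sim.noise_amplitude,
                safety=sim.safety,
                early_stop=sim.early_stop,
            )
            try:
                init = initial_condition(p, grid, cfg)
                result = simulate(init, p, cfg)
                m = pattern_metrics(result.state)
                row["amplitude"] = m.amplitude
                row["covariance"] = m.covariance
                row["length"] = m.length if m.length is not None else np.nan
            except BlowUpError as exc:
                row["failed"] = True
                row["error"] = str(exc)
            rows.append(row)
    return ScanTable(
        axis1=name1,
        axis2=name2,
        values1=values1,
        values2=values2,
        table=pd.DataFrame(rows),
        base=base,
        config=sim,
        master_seed=master_seed,
    )


def compare_1d_2d(
    params_list: Sequence[ModelParams],
    sim: Union[SimConfig, Sequence[SimConfig]],
    L: int = 128,
    dx: float = 1.0,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Matched 1D (length L) and 2D (L x L) runs; lengths and their mismatch.

    ``sim`` may be a single config or one per parameter set (fast-growing
    sets need shorter runs).  Rows with an undefined length in either
    dimension carry NaN in ``rel_diff``.
    """
    n = int(round(L / dx))
    if isinstance(sim, SimConfig):
        sims = [sim] * len(params_list)
    else:
        sims = list(sim)
        if len(sims) != len(params_list):
            raise ValueError("need one SimConfig per parameter set")
    rows = []
    for idx, (p, sim) in enumerate(zip(params_list, sims)):
        row = {"chi": p.chi, "h": p.h, "k": p.k, "D_I": p.D_I}
        for dims, key in ((1, "ell_1d"), (2, "ell_2d")):
            grid = Grid((n,) * dims, dx=dx)
            cfg = SimConfig(
                t_end=sim.t_end,
                dt=sim.dt,
                seed=cell_seed(master_seed, idx, dims),
                noise_amplitude=sim.noise_amplitude,
                safety=sim.safety,
            )
            init = initial_condition(p, grid, cfg)
            result = simulate(init, p, cfg)
            row[key] = try_dominant_length(result.state.phiA, dx) or np.nan
            if dims == 2:
                row["n_components"] = droplet_count(result.state.phiA)
        row["rel_diff"] = (
            abs(row["ell_2d"] - row["ell_1d"]) / row["ell_1d"]
            if np.isfinite(row["ell_1d"]) and np.isfinite(row["ell_2d"])
            else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def droplet_count(field: np.ndarray) -> int:
    """Number of connected components of the above-median region (4-connectivity).

    A crude droplet-vs-stripe classifier: isolated spots give many small
    components, stripes give a few elongated ones.
    """
    from scipy import ndimage

    mask = field > np.median(field)
    # periodic labelling: label, then merge components touching across edges
    labels, n = ndimage.label(mask)
    if n == 0:
        return 0
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    if field.ndim == 1:
        if labels[0] and labels[-1]:
            union(labels[0], labels[-1])
    else:
        for a, b in zip(labels[0, :], labels[-1, :]):
            if a and b:
                union(a, b)
        for a, b in zip(labels[:, 0], labels[:, -1]):
            if a and b:
                union(a, b)
    return len({find(x) for x in range(1, n + 1)})


def chi_star_table(
    base: ModelParams,
    h_values: Sequence[float],
    ratio_values: Sequence[float],
    **kwargs,
) -> pd.DataFrame:
    """Minimal pattern-supporting interaction on an (h, D_I/D_A) grid."""
    rows = []
    for h in h_values:
        for r in ratio_values:
            p = set_axis(set_axis(base, "h", h), "D_I/D_A", r)
            try:
                cs = chi_star(p, **kwargs)
            except Exception as exc:
                cs = np.nan
                rows.append({"h": h, "D_I/D_A": r, "chi_star": cs, "error": str(exc)})
                continue
            rows.append({"h": h, "D_I/D_A": r, "chi_star": cs})
    return pd.DataFrame(rows)
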