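"""Langevin dynamics in a periodic cubic box.

The integrator is the BAOAB splitting of Langevin dynamics, which
gives accurate configurational sampling at the large timesteps CG
models permit.  With friction = 0 the O-step becomes the identity and
the scheme reduces to velocity Verlet, which is used for the NVE
sanity checks.  A Verlet-skin neighbor list built on a periodic
KD-tree keeps force evaluation tractable.

A protocol run is energy minimization, an equilibration phase long
enough for condensate formation (a density-plateau detector is
provided), then a production phase with periodic snapshots and
per-frame energy decompositions; replicas differ only by seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .potentials import (EnergyBreakdown, energy_and_forces,
                         max_nonbonded_cutoff)
from .units import FS_PER_PS, KB


@dataclass
class SimState:
    positions: np.ndarray       # nm, unwrapped
    velocities: np.ndarray      # nm/ps
    box_length: float
    time: float = 0.0           # ps
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))

    def copy(self) -> "SimState":
        rng = np.random.default_rng()
        rng.bit_generator.state = self.rng.bit_generator.state
        return SimState(self.positions.copy(), self.velocities.copy(),
                        self.box_length, self.time, rng)


@dataclass
class Schedule:
    """Run phases; steps are integrator steps at ``timestep_fs``."""

    minimize: bool = True
    equilibration_steps: int = 1000
    production_steps: int = 10000
    timestep_fs: float = 10.0
    snapshot_interval: int = 500
    temperature: float = 300.0
    n_replicas: int = 3

    def validate(self):
        if self.timestep_fs <= 0 or self.snapshot_interval <= 0:
            raise ValueError("timestep and snapshot interval must be > 0")


class NeighborList:
    """Verlet list with displacement-triggered rebuilds.

    Pairs are exclusion-filtered at rebuild time; ``native_mask``
    marks surviving pairs that carry a native contact instead of the
    generic WF attraction.
    """

    def __init__(self, system, skin: float = 0.3):
        self.system = system
        self.skin = skin
        self.cutoff = max_nonbonded_cutoff(system) + skin
        self._ref_positions = None
        self.pairs = None
        self.native_mask = None

    def update(self, positions: np.ndarray, force: bool = False):
        from .potentials import nonbonded_pairs

        if (force or self._ref_positions is None
                or self._max_displacement(positions) > 0.5 * self.skin):
            box = self.system.box_length
            tree = cKDTree(positions % box, boxsize=box)
            pr = tree.query_pairs(self.cutoff, output_type="ndarray")
            if pr.size:
                raw = (pr[:, 0].astype(np.int64), pr[:, 1].astype(np.int64))
            else:
                raw = (np.zeros(0, dtype=np.int64),
                       np.zeros(0, dtype=np.int64))
            ii, jj, native = nonbonded_pairs(positions, self.system,
                                             pairs=raw)
            self.pairs = (ii, jj)
            self.native_mask = native
            self._ref_positions = positions.copy()
        return self.pairs

    def _max_displacement(self, positions):
        d = positions - self._ref_positions
        return float(np.abs(d).max())


def initialize_state(system, temperature: float,
                     seed: int) -> SimState:
    """Maxwell-Boltzmann velocities at the target temperature."""
    rng = np.random.default_rng(seed)
    sigma_v = np.sqrt(KB * temperature / system.mass)[:, None]
    vel = rng.normal(size=(system.n_beads, 3)) * sigma_v
    vel -= (system.mass[:, None] * vel).sum(axis=0) / system.mass.sum()
    return SimState(system.positions.copy(), vel, system.box_length,
                    rng=rng)


def kinetic_temperature(state: SimState, system) -> float:
    ke = 0.5 * (system.mass[:, None] * state.velocities ** 2).sum()
    return float(2.0 * ke / (3.0 * system.n_beads * KB))


def minimize(state: SimState, system, tolerance: float = 10.0,
             max_iter: int = 500) -> SimState:
    """L-BFGS energy minimization; total energy never increases."""
    from scipy.optimize import minimize as _sp_min

    e0, _ = energy_and_forces(state.positions, system,
                              compute_forces=False)
    if not np.isfinite(e0.total):
        raise ValueError("non-finite energy at start of minimization")

    # displacement-capped steepest descent first: keeps steep-core
    # relaxation from overshooting shallow wells
    pos = state.positions.copy()
    energy = e0.total
    step_cap = 0.02
    for _ in range(80):
        brk, F = energy_and_forces(pos, system)
        fmax = np.abs(F).max()
        if fmax < tolerance:
            break
        trial = pos + F * min(step_cap / fmax, 2e-3)
        e_trial = energy_and_forces(trial, system,
                                    compute_forces=False)[0].total
        if e_trial >= energy:
            break
        pos, energy = trial, e_trial

    def fun(x):
        p = x.reshape(-1, 3)
        brk, F = energy_and_forces(p, system)
        return brk.total, -F.reshape(-1)

    res = _sp_min(fun, pos.reshape(-1), jac=True, method="L-BFGS-B",
                  options={"maxiter": max_iter, "gtol": tolerance})
    new = state.copy()
    if np.isfinite(res.fun) and res.fun <= energy:
        new.positions = res.x.reshape(-1, 3)
    else:
        new.positions = pos
    return new


def langevin_step(state: SimState, system, dt_fs: float, friction: float,
                  temperature: float, nlist: Optional[NeighborList] = None,
                  cached_force: Optional[np.ndarray] = None):
    """One BAOAB step; returns (state, new_force).

    Deterministic given the state's RNG stream.  Positions are kept
    unwrapped; periodicity enters through minimum-image forces.
    """
    dt = dt_fs / FS_PER_PS
    m = system.mass[:, None]
    if cached_force is None:
        _, cached_force = energy_and_forces(state.positions, system,
                                            nlist=nlist)
    if not np.all(np.isfinite(cached_force)):
        raise FloatingPointError("non-finite force encountered")
    v = state.velocities + 0.5 * dt * cached_force / m
    x = state.positions + 0.5 * dt * v
    if friction > 0:
        c1 = np.exp(-friction * dt)
        c2 = np.sqrt((1.0 - c1 ** 2) * KB * temperature / system.mass)
        v = c1 * v + c2[:, None] * state.rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    _, new_force = energy_and_forces(x, system, nlist=nlist)
    if not np.all(np.isfinite(new_force)):
        raise FloatingPointError("non-finite force encountered")
    v = v + 0.5 * dt * new_force / m
    state.positions = x
    state.velocities = v
    state.time += dt
    return state, new_force


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Snapshots (unwrapped positions) plus per-frame energy channels."""

    times: np.ndarray                 # ps
    positions: np.ndarray             # (n_frames, n_beads, 3), nm
    box_length: float
    seed: int
    temperature: float
    energies: pd.DataFrame            # one row per frame
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            times=self.times,
            positions=self.positions,
            box_length=self.box_length,
            seed=self.seed,
            temperature=self.temperature,
            energy_columns=np.array(list(self.energies.columns)),
            energy_values=self.energies.to_numpy(),
            metadata=json.dumps(self.metadata),
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        with np.load(path, allow_pickle=False) as z:
            energies = pd.DataFrame(
                z["energy_values"],
                columns=[str(c) for c in z["energy_columns"]])
            return cls(
                times=z["times"],
                positions=z["positions"],
                box_length=float(z["box_length"]),
                seed=int(z["seed"]),
                temperature=float(z["temperature"]),
                energies=energies,
                metadata=json.loads(str(z["metadata"])),
            )

    def __eq__(self, other) -> bool:
        return (np.array_equal(self.times, other.times)
                and np.array_equal(self.positions, other.positions)
                and self.box_length == other.box_length
                and self.seed == other.seed
                and self.temperature == other.temperature
                and self.energies.equals(other.energies)
                and self.metadata == other.metadata)


def run_protocol(system, schedule: Schedule,
                 base_seed: Optional[int] = None) -> list[Trajectory]:
    """Minimize, equilibrate, then run production for each replica.

    Replicas differ only by seed (``base_seed + replica``).  Snapshots
    with their energy decomposition are recorded during production at
    ``snapshot_interval``; with ``production_steps = 0`` snapshots are
    taken during equilibration instead.
    """
    schedule.validate()
    base_seed = system.config.seed if base_seed is None else base_seed
    out = []
    for rep in range(schedule.n_replicas):
        seed = int(base_seed) + rep
        out.append(_run_single(system, schedule, seed))
    return out


def _run_single(system, schedule: Schedule, seed: int) -> Trajectory:
    state = initialize_state(system, schedule.temperature, seed)
    nlist = NeighborList(system)
    if schedule.minimize:
        state = minimize(state, system)
        state.rng = np.random.default_rng(seed + 10_000_019)
    force = None
    times, frames, rows = [], [], []

    def snapshot():
        brk, _ = energy_and_forces(state.positions, system, nlist=nlist,
                                   compute_forces=False)
        times.append(state.time)
        frames.append(state.positions.copy())
        rows.append(brk.as_dict())

    record_equil = schedule.production_steps == 0
    for step in range(schedule.equilibration_steps):
        state, force = langevin_step(
            state, system, schedule.timestep_fs, system.config.friction,
            schedule.temperature, nlist, force)
        if record_equil and (step + 1) % schedule.snapshot_interval == 0:
            snapshot()
    for step in range(schedule.production_steps):
        state, force = langevin_step(
            state, system, schedule.timestep_fs, system.config.friction,
            schedule.temperature, nlist, force)
        if (step + 1) % schedule.snapshot_interval == 0:
            snapshot()
    if not frames:
        snapshot()
    energies = pd.DataFrame(rows).astype(float)
    return Trajectory(
        times=np.array(times),
        positions=np.array(frames),
        box_length=system.box_length,
        seed=seed,
        temperature=schedule.temperature,
        energies=energies,
        metadata={
            "equilibration_steps": schedule.equilibration_steps,
            "production_steps": schedule.production_steps,
            "timestep_fs": schedule.timestep_fs,
            "friction": system.config.friction,
        },
    )


def density_plateau_reached(values, window: int = 20,
                            rel_slope_tol: float = 0.02) -> bool:
    """Sliding-window slope test: the last ``window`` samples count as
    a plateau when the fitted linear drift over the window is below
    ``rel_slope_tol`` of the window mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < window:
        return False
    y = values[-window:]
    x = np.arange(window, dtype=float)
    slope = np.polyfit(x, y, 1)[0]
    mean = np.abs(y.mean())
    if mean < 1e-12:
        return bool(abs(slope) < 1e-12)
    return bool(abs(slope * window / mean) < rel_slope_tol)
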