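"""Langevin dynamics for coarse-grained beads under a learned potential.

The integrator is the BAOAB splitting of the Langevin equation — half kick,
half drift, Ornstein-Uhlenbeck velocity refresh, half drift, half kick —
chosen for its configurational accuracy at large timesteps.  With zero
friction and zero temperature it reduces exactly to velocity Verlet, which is
what the energy-conservation tests exercise.

Defaults follow the package's CG simulation protocol: 4 fs timestep, 1 ps^-1
friction, 350 K.  Bead masses are the aggregated heavy-atom + hydrogen masses
so the thermostat sees the same total mass as the fine-grained system.
Everything is seeded; two runs with the same seed are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .cg_mapping import CGFrame, CGMap
from .units import FORCE_TO_ACC, KB, PS_INV_TO_FS_INV

__all__ = [
    "SimulationError",
    "SimState",
    "SimConfig",
    "Trajectory",
    "init_state",
    "langevin_step",
    "run",
    "write_trajectory",
    "read_trajectory",
]


class SimulationError(RuntimeError):
    """Raised when the propagation produces non-finite forces or coordinates."""


@dataclass
class SimState:
    """Instantaneous state of a CG simulation."""

    coords: np.ndarray        # (n, 3) A
    velocities: np.ndarray    # (n, 3) A/fs
    masses: np.ndarray        # (n,) a.m.u.
    bead_types: np.ndarray    # (n,) int
    temperature: float        # K (thermostat target)
    step: int = 0
    forces: np.ndarray | None = None  # cached (n, 3) kcal/mol/A

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.bead_types = np.asarray(self.bead_types, dtype=np.int64)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        for arr in (self.coords, self.velocities, self.masses):
            if not np.all(np.isfinite(arr)):
                raise ValueError("state contains non-finite values")

    def kinetic_energy(self) -> float:
        """Kinetic energy in kcal/mol."""
        v2 = np.sum(self.masses[:, None] * self.velocities**2)
        return 0.5 * v2 / FORCE_TO_ACC

    def kinetic_temperature(self) -> float:
        """Instantaneous temperature from equipartition (K)."""
        dof = 3 * len(self.masses)
        return 2.0 * self.kinetic_energy() / (dof * KB)

    def save(self, path) -> None:
        np.savez(
            path,
            coords=self.coords,
            velocities=self.velocities,
            masses=self.masses,
            bead_types=self.bead_types,
            temperature=self.temperature,
            step=self.step,
        )

    @classmethod
    def load(cls, path) -> "SimState":
        with np.load(path) as d:
            return cls(
                coords=d["coords"],
                velocities=d["velocities"],
                masses=d["masses"],
                bead_types=d["bead_types"],
                temperature=float(d["temperature"]),
                step=int(d["step"]),
            )


@dataclass
class SimConfig:
    """Integration settings (timestep fs, friction ps^-1, temperature K)."""

    timestep: float = 4.0
    friction: float = 1.0
    temperature: float = 350.0
    n_steps: int = 1000
    seed: int = 0
    output_stride: int = 100

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.n_steps < 0 or self.output_stride < 1:
            raise ValueError("n_steps >= 0 and output_stride >= 1 required")


@dataclass
class Trajectory:
    """Saved frames of one run (coords in A, potential energies in kcal/mol)."""

    coords: np.ndarray                 # (T, n, 3)
    bead_types: np.ndarray             # (n,)
    potential_energies: np.ndarray     # (T,)
    config: SimConfig
    velocities: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def _eval_forces(model, coords: np.ndarray, bead_types: np.ndarray) -> np.ndarray:
    if callable(model) and not hasattr(model, "forces"):
        return np.asarray(model(coords), dtype=float)
    return model.forces(CGFrame(coords=coords, bead_types=bead_types))


def _eval_energy(model, coords: np.ndarray, bead_types: np.ndarray) -> float:
    if hasattr(model, "energy"):
        return float(model.energy(CGFrame(coords=coords, bead_types=bead_types)))
    return float("nan")


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def init_state(
    frame: CGFrame,
    cg_map: CGMap | np.ndarray,
    temperature: float,
    seed: int = 0,
) -> SimState:
    """Start a simulation from *frame* with Maxwell-Boltzmann velocities.

    *cg_map* may be a :class:`CGMap` (masses taken from it) or a plain mass
    array.  At ``temperature == 0`` the velocities are exactly zero.
    """
    masses = cg_map.bead_masses if isinstance(cg_map, CGMap) else np.asarray(cg_map, float)
    if masses.shape != (frame.n_beads,):
        raise ValueError("mass array does not match bead count")
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * temperature * FORCE_TO_ACC / masses)
    velocities = sigma[:, None] * rng.standard_normal((frame.n_beads, 3))
    return SimState(
        coords=frame.coords.copy(),
        velocities=velocities,
        masses=masses.copy(),
        bead_types=frame.bead_types.copy(),
        temperature=float(temperature),
    )


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def langevin_step(
    state: SimState,
    model,
    config: SimConfig,
    rng: np.random.Generator,
) -> SimState:
    """One BAOAB update of *state* in place; returns the state.

    *model* is any object with ``forces(CGFrame)`` (and optionally
    ``energy``), or a bare callable ``coords -> forces``.
    """
    dt = config.timestep
    gamma = config.friction * PS_INV_TO_FS_INV  # fs^-1
    inv_m = (FORCE_TO_ACC / state.masses)[:, None]

    if state.forces is None:
        state.forces = _eval_forces(model, state.coords, state.bead_types)

    # B: half kick
    state.velocities += 0.5 * dt * state.forces * inv_m
    # A: half drift
    state.coords += 0.5 * dt * state.velocities
    # O: Ornstein-Uhlenbeck refresh
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(1.0 - c1 * c1)
        sigma = np.sqrt(KB * config.temperature * FORCE_TO_ACC / state.masses)[:, None]
        state.velocities = c1 * state.velocities + c2 * sigma * rng.standard_normal(
            state.velocities.shape
        )
    # A: half drift
    state.coords += 0.5 * dt * state.velocities
    # B: half kick with fresh forces
    forces = _eval_forces(model, state.coords, state.bead_types)
    if not np.all(np.isfinite(forces)):
        raise SimulationError(f"non-finite forces at step {state.step}")
    state.forces = forces
    state.velocities += 0.5 * dt * forces * inv_m
    state.step += 1
    return state


def run(state: SimState, model, config: SimConfig) -> Trajectory:
    """Propagate ``config.n_steps`` BAOAB steps, saving every ``output_stride``.

    The initial frame is always recorded; with ``n_steps == 0`` the trajectory
    holds only that frame.  Deterministic under ``config.seed``; the final
    *state* (mutated in place) can be saved and reloaded to restart.
    """
    rng = np.random.default_rng(config.seed)
    frames = [state.coords.copy()]
    energies = [_eval_energy(model, state.coords, state.bead_types)]
    for i in range(config.n_steps):
        langevin_step(state, model, config, rng)
        if (i + 1) % config.output_stride == 0:
            frames.append(state.coords.copy())
            energies.append(_eval_energy(model, state.coords, state.bead_types))
    return Trajectory(
        coords=np.array(frames),
        bead_types=state.bead_types.copy(),
        potential_energies=np.array(energies),
        config=config,
    )


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Self-describing HDF5: coords, types, energies and config attributes."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("coords", data=traj.coords.astype("<f4"))
        fh.create_dataset("bead_types", data=traj.bead_types, dtype="int64")
        fh.create_dataset("potential_energy", data=traj.potential_energies)
        if traj.velocities is not None:
            fh.create_dataset("velocities", data=traj.velocities.astype("<f4"))
        for key in ("timestep", "friction", "temperature", "n_steps", "seed",
                    "output_stride"):
            fh.attrs[key] = getattr(traj.config, key)


def read_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        config = SimConfig(
            timestep=float(fh.attrs["timestep"]),
            friction=float(fh.attrs["friction"]),
            temperature=float(fh.attrs["temperature"]),
            n_steps=int(fh.attrs["n_steps"]),
            seed=int(fh.attrs["seed"]),
            output_stride=int(fh.attrs["output_stride"]),
        )
        return Trajectory(
            coords=fh["coords"][()].astype(float),
            bead_types=fh["bead_types"][()],
            potential_energies=fh["potential_energy"][()],
            config=config,
            velocities=fh["velocities"][()].astype(float) if "velocities" in fh else None,
        )
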