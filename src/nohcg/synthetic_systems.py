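"""Synthetic toy systems: closed-form force fields, sampling and fixtures.

Everything the pipeline needs can be generated here without downloads:

* toy molecules — chains of heavy "carbon" sites, each carrying a fixed number
  of satellite hydrogens on stiff harmonic bonds, with harmonic (or quartic
  double-well) heavy-heavy bonds, harmonic angles and Lennard-Jones contacts
  between distant heavy pairs;
* coordinate-force datasets sampled with Langevin dynamics from the exact
  analytic potential, optionally with Gaussian force noise of known width;
* the CG-solvable dimer, whose exact coarse-grained free energy along the
  bond length reduces to a one-dimensional integral: because the hydrogens
  interact only with their own heavy site, their forces cancel exactly inside
  each bead and the bead-bead potential of mean force *is* the heavy-heavy
  bond potential, with the radial Jacobian term ``-2 k_B T ln r`` accounting
  for the growth of configuration space with distance;
* mdCATH-like HDF5 fixtures with controllable residue counts, heavy-atom
  counts and helix/sheet fractions for exercising the dataset curation.

The hydrogens are light and stiffly bonded, so their fluctuations are fast
relative to the bead coordinates and the aggregated force labels are a
low-noise estimator of the coarse-grained mean force.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .cg_dynamics import SimConfig, SimState, langevin_step
from .cg_mapping import AllAtomFrame, Atom, Topology
from .units import ELEMENT_MASSES, FORCE_TO_ACC, KB

__all__ = [
    "ToySpec",
    "AnalyticPMF",
    "ToyForceField",
    "make_toy_molecule",
    "toy_forces",
    "sample_dataset",
    "SampledDataset",
    "analytic_cg_pmf",
    "basin_free_energy_difference",
    "design_asymmetric_dimer",
    "default_dimer_spec",
    "radial_pmf",
    "alanine_dipeptide_topology",
    "FixtureDomain",
    "random_fixture_domain",
    "write_fixture_h5",
]

#: temperatures (K) pooled when sampling multi-temperature toy datasets
FIXTURE_TEMPERATURES = (320, 348, 379, 413, 450)


@dataclass(frozen=True)
class ToySpec:
    """Parameters of a toy molecule and its closed-form force field.

    Units: kcal/mol for energies, A for lengths, K for temperature.  With
    ``double_well`` set to ``(a, w, tilt)`` the first heavy-heavy bond becomes
    ``a ((r - r0)^2 - w^2)^2 + tilt (r - r0)`` (quartic double well with minima
    near ``r0 +/- w``); otherwise all heavy-heavy bonds are harmonic
    ``0.5 k (r - r0)^2``.
    """

    n_heavy: int = 2
    h_counts: tuple[int, ...] = (3, 3)
    bond_r0: float = 4.0
    bond_k: float = 60.0
    double_well: tuple[float, float, float] | None = None
    angle_k: float = 25.0
    angle_theta0: float = 1.9106  # tetrahedral, rad
    lj_epsilon: float = 0.15
    lj_sigma: float = 3.4
    h_bond_k: float = 340.0
    h_bond_r0: float = 1.09
    temperature: float = 350.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_heavy < 1 or len(self.h_counts) != self.n_heavy:
            raise ValueError("h_counts must list one hydrogen count per heavy site")
        if any(h < 0 or h > 4 for h in self.h_counts):
            raise ValueError("hydrogen counts must lie in [0, 4]")
        if self.bond_k <= 0 or self.h_bond_k <= 0 or self.lj_sigma <= 0:
            raise ValueError("force constants and sigma must be positive")


@dataclass
class AnalyticPMF:
    """Exact free energy along a reaction coordinate (min-shifted to 0)."""

    grid: np.ndarray          # bin centres, A
    values: np.ndarray        # kcal/mol
    description: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must align")


# ---------------------------------------------------------------------------
# Topology and geometry
# ---------------------------------------------------------------------------

# unit vectors towards tetrahedral corners, used to place satellite hydrogens
_TETRAHEDRAL = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


def _bond_potential(spec: ToySpec, r: np.ndarray):
    """Energy and dU/dr of the (first) heavy-heavy bond potential."""
    dr = np.asarray(r, dtype=float) - spec.bond_r0
    if spec.double_well is not None:
        a, w, tilt = spec.double_well
        u = a * (dr**2 - w**2) ** 2 + tilt * dr
        du = 4.0 * a * dr * (dr**2 - w**2) + tilt
    else:
        u = 0.5 * spec.bond_k * dr**2
        du = spec.bond_k * dr
    return u, du


def _equilibrium_bond_length(spec: ToySpec) -> float:
    """Location of the global minimum of the heavy-heavy bond potential."""
    if spec.double_well is None:
        return spec.bond_r0
    a, w, tilt = spec.double_well
    grid = np.linspace(spec.bond_r0 - 2 * w, spec.bond_r0 + 2 * w, 2001)
    u, _ = _bond_potential(spec, grid)
    return float(grid[np.argmin(u)])


def make_toy_molecule(spec: ToySpec) -> tuple[Topology, AllAtomFrame]:
    """Build the toy topology and a geometry near the potential minimum.

    Heavy sites are laid out as a planar zigzag with the equilibrium bond
    length and angle; hydrogens sit at the ideal bond length along tetrahedral
    directions.  Deterministic: identical output for identical specs.
    """
    r_eq = _equilibrium_bond_length(spec)
    heavy_pos = np.zeros((spec.n_heavy, 3))
    direction_angle = 0.0
    for i in range(1, spec.n_heavy):
        if i >= 2:
            # alternate turn to realize the equilibrium angle in the xy plane
            turn = np.pi - spec.angle_theta0
            direction_angle += turn if i % 2 == 0 else -turn
        step = np.array([np.cos(direction_angle), np.sin(direction_angle), 0.0])
        heavy_pos[i] = heavy_pos[i - 1] + r_eq * step

    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    coords: list[np.ndarray] = []
    heavy_index: list[int] = []
    for i in range(spec.n_heavy):
        heavy_index.append(len(atoms))
        atoms.append(Atom("C", i, "TOY", f"X{i + 1}"))
        coords.append(heavy_pos[i])
        if i > 0:
            bonds.append((heavy_index[i - 1], heavy_index[i]))
        for k in range(spec.h_counts[i]):
            atoms.append(Atom("H", i, "TOY", f"HX{i + 1}{k + 1}"))
            bonds.append((heavy_index[i], len(atoms) - 1))
            coords.append(heavy_pos[i] + spec.h_bond_r0 * _TETRAHEDRAL[k])
    topo = Topology(atoms=atoms, bonds=bonds)
    return topo, AllAtomFrame(coords=np.array(coords))


def alanine_dipeptide_topology() -> tuple[Topology, AllAtomFrame]:
    """Capped alanine dipeptide (ACE-ALA-NME): 22 atoms, 10 heavy.

    Coordinates are a deterministic rough geometry sufficient for mapping and
    selection tests; they are not an energy minimum of any force field.
    """
    # (name, element, res_index, res_name, n_H)
    spec = [
        ("CH3", "C", 0, "ACE", 3), ("C", "C", 0, "ACE", 0), ("O", "O", 0, "ACE", 0),
        ("N", "N", 1, "ALA", 1), ("CA", "C", 1, "ALA", 1), ("CB", "C", 1, "ALA", 3),
        ("C", "C", 1, "ALA", 0), ("O", "O", 1, "ALA", 0),
        ("N", "N", 2, "NME", 1), ("CH3", "C", 2, "NME", 3),
    ]
    rng = np.random.default_rng(2025)
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    coords: list[np.ndarray] = []
    heavy_positions = 1.45 * np.arange(len(spec))[:, None] * np.array([1.0, 0.0, 0.0])
    heavy_positions = heavy_positions + 0.3 * rng.standard_normal((len(spec), 3))
    for (name, element, res_i, res_n, n_h), pos in zip(spec, heavy_positions):
        parent = len(atoms)
        atoms.append(Atom(element, res_i, res_n, name))
        coords.append(pos)
        for k in range(n_h):
            atoms.append(Atom("H", res_i, res_n, f"H{name}{k + 1}"))
            bonds.append((parent, len(atoms) - 1))
            coords.append(pos + 1.09 * _TETRAHEDRAL[k])
    return Topology(atoms=atoms, bonds=bonds), AllAtomFrame(coords=np.array(coords))


# ---------------------------------------------------------------------------
# Closed-form force field
# ---------------------------------------------------------------------------

class ToyForceField:
    """Analytic energy and forces of a toy molecule (double precision).

    Terms: heavy-heavy bonds (harmonic, or the double well on the first bond),
    harmonic angles on consecutive heavy triples, Lennard-Jones between heavy
    pairs at least three bonds apart, and stiff harmonic hydrogen bonds.
    Hydrogens interact with nothing but their own heavy site, which is what
    makes the dimer's coarse-grained free energy exactly computable.
    """

    def __init__(self, topology: Topology, spec: ToySpec):
        self.spec = spec
        self.heavy = [i for i, a in enumerate(topology.atoms) if a.element != "H"]
        attach = topology.hydrogen_attachments()
        self.h_bonds = sorted(attach.items())  # (hydrogen, heavy) pairs
        self.n_atoms = topology.n_atoms
        if len(self.heavy) != spec.n_heavy:
            raise ValueError("topology does not match spec heavy-site count")
        nh = len(self.heavy)
        self.lj_pairs = [
            (self.heavy[i], self.heavy[j])
            for i in range(nh)
            for j in range(i + 3, nh)
        ]
        self.masses = np.array(
            [ELEMENT_MASSES[a.element] for a in topology.atoms], dtype=float
        )

    # -- energy/forces ------------------------------------------------------

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = np.asarray(coords, dtype=float)
        forces = np.zeros_like(coords)
        energy = 0.0
        spec = self.spec

        def radial(i, j, u_fn):
            nonlocal energy
            d = coords[i] - coords[j]
            r = float(np.linalg.norm(d))
            if r < 1e-6:
                raise ValueError(f"atoms {i} and {j} overlap (r={r:.2e} A)")
            u, du = u_fn(r)
            energy += u
            f = -(du / r) * d
            forces[i] += f
            forces[j] -= f

        # heavy-heavy bonds; the double well (if any) lives on the first bond
        for b in range(len(self.heavy) - 1):
            i, j = self.heavy[b], self.heavy[b + 1]
            if b == 0:
                radial(i, j, lambda r: _bond_potential(spec, r))
            else:
                radial(i, j, lambda r: (
                    0.5 * spec.bond_k * (r - spec.bond_r0) ** 2,
                    spec.bond_k * (r - spec.bond_r0),
                ))

        # angles on consecutive heavy triples
        for b in range(len(self.heavy) - 2):
            i, j, k = self.heavy[b], self.heavy[b + 1], self.heavy[b + 2]
            energy += self._angle(coords, forces, i, j, k)

        # LJ between distant heavy pairs
        eps, sig = spec.lj_epsilon, spec.lj_sigma
        for i, j in self.lj_pairs:
            def lj(r):
                sr6 = (sig / r) ** 6
                u = 4.0 * eps * (sr6**2 - sr6)
                du = 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / r
                return u, du
            radial(i, j, lj)

        # hydrogen satellites
        kh, r0h = spec.h_bond_k, spec.h_bond_r0
        for h, parent in self.h_bonds:
            radial(h, parent, lambda r: (0.5 * kh * (r - r0h) ** 2, kh * (r - r0h)))

        return energy, forces

    def _angle(self, coords, forces, i, j, k) -> float:
        """Harmonic angle term 0.5 k (theta - theta0)^2 with analytic gradient."""
        spec = self.spec
        rij = coords[i] - coords[j]
        rkj = coords[k] - coords[j]
        nij = np.linalg.norm(rij)
        nkj = np.linalg.norm(rkj)
        cos_t = float(np.clip(rij @ rkj / (nij * nkj), -1.0, 1.0))
        theta = np.arccos(cos_t)
        sin_t = max(np.sqrt(1.0 - cos_t**2), 1e-8)
        du_dtheta = spec.angle_k * (theta - spec.angle_theta0)
        # dtheta/dr via standard angle-gradient expressions
        di = (cos_t * rij / nij - rkj / nkj) / (nij * sin_t)
        dk = (cos_t * rkj / nkj - rij / nij) / (nkj * sin_t)
        forces[i] -= du_dtheta * di
        forces[k] -= du_dtheta * dk
        forces[j] += du_dtheta * (di + dk)
        return 0.5 * spec.angle_k * (theta - spec.angle_theta0) ** 2

    def forces(self, coords_or_frame) -> np.ndarray:
        coords = getattr(coords_or_frame, "coords", coords_or_frame)
        return self.energy_forces(coords)[1]

    def energy(self, coords_or_frame) -> float:
        coords = getattr(coords_or_frame, "coords", coords_or_frame)
        return self.energy_forces(coords)[0]

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        return self.forces(coords)


def toy_forces(topology: Topology, frame: AllAtomFrame, spec: ToySpec) -> AllAtomFrame:
    """Evaluate the closed-form forces at the frame's coordinates."""
    ff = ToyForceField(topology, spec)
    _, forces = ff.energy_forces(frame.coords)
    return AllAtomFrame(coords=frame.coords.copy(), forces=forces)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

@dataclass
class SampledDataset:
    """Frames with exact (optionally noise-corrupted) force labels."""

    frames: list[AllAtomFrame]
    temperature: float
    equilibrated: bool
    noise_sigma: float = 0.0


def sample_dataset(
    spec: ToySpec,
    n_frames: int,
    temperature: float | None = None,
    seed: int | None = None,
    timestep: float = 0.5,
    friction: float = 10.0,
    equilibration_steps: int = 4000,
    sample_stride: int = 10,
    force_noise_sigma: float = 0.0,
) -> SampledDataset:
    """Sample all-atom coordinate-force pairs by Langevin dynamics.

    A short timestep (0.5 fs) resolves the stiff hydrogen bonds; frames are
    taken every *sample_stride* steps after *equilibration_steps* of burn-in.
    Stored force labels are the exact analytic forces, plus independent
    Gaussian noise of width *force_noise_sigma* (kcal/mol/A) when requested —
    the known noise floor for trainer tests.  Fully reproducible from
    ``(spec, seed)``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    temperature = spec.temperature if temperature is None else temperature
    seed = spec.seed if seed is None else seed
    topo, frame0 = make_toy_molecule(spec)
    ff = ToyForceField(topo, spec)
    rng = np.random.default_rng(seed)

    state = SimState(
        coords=frame0.coords.copy(),
        velocities=np.sqrt(KB * temperature * FORCE_TO_ACC / ff.masses)[:, None]
        * rng.standard_normal((topo.n_atoms, 3)),
        masses=ff.masses,
        bead_types=np.zeros(topo.n_atoms, dtype=np.int64),
        temperature=temperature,
    )
    config = SimConfig(
        timestep=timestep,
        friction=friction,
        temperature=temperature,
        n_steps=0,
        seed=seed,
    )
    for _ in range(equilibration_steps):
        langevin_step(state, ff, config, rng)

    frames: list[AllAtomFrame] = []
    for _ in range(n_frames):
        for _ in range(sample_stride):
            langevin_step(state, ff, config, rng)
        _, forces = ff.energy_forces(state.coords)
        if force_noise_sigma > 0:
            forces = forces + force_noise_sigma * rng.standard_normal(forces.shape)
        frames.append(AllAtomFrame(coords=state.coords.copy(), forces=forces))

    # crude equilibration heuristic: a few friction times of burn-in
    equilibrated = equilibration_steps * timestep * friction * 1e-3 >= 3.0
    return SampledDataset(
        frames=frames,
        temperature=temperature,
        equilibrated=equilibrated,
        noise_sigma=force_noise_sigma,
    )


# ---------------------------------------------------------------------------
# Analytic CG free energy of the dimer
# ---------------------------------------------------------------------------

def _check_dimer(spec: ToySpec) -> None:
    if spec.n_heavy != 2:
        raise NotImplementedError(
            "the analytic CG free energy is available for the two-site dimer only"
        )


def analytic_cg_pmf(
    spec: ToySpec,
    grid: np.ndarray | None = None,
    temperature: float | None = None,
    include_jacobian: bool = True,
) -> AnalyticPMF:
    """Exact CG free energy of the dimer along its bond length.

    Because hydrogens couple only to their own bead, integrating them out
    contributes a constant and the bond-length density is
    ``p(r) dr ~ r^2 exp(-U_b(r)/k_B T) dr``.  The free energy is
    ``G(r) = U_b(r) - 2 k_B T ln r`` (Jacobian included by default; disable it
    to recover the bare bond potential), min-shifted to 0.  Normalization is
    by numerical quadrature, though it cancels in the shift.
    """
    _check_dimer(spec)
    temperature = spec.temperature if temperature is None else temperature
    kt = KB * temperature
    if grid is None:
        half_width = 1.0 if spec.double_well is not None else 3.0 * np.sqrt(kt / spec.bond_k)
        grid = np.linspace(spec.bond_r0 - half_width, spec.bond_r0 + half_width, 81)
    grid = np.asarray(grid, dtype=float)
    u, _ = _bond_potential(spec, grid)
    g = u - (2.0 * kt * np.log(grid) if include_jacobian else 0.0)
    u_min = float(np.min(u))

    def density(r):
        ub, _ = _bond_potential(spec, r)
        return r**2 * np.exp(-(ub - u_min) / kt)

    z, err = quad(density, max(grid[0] - 2.0, 1e-3), grid[-1] + 2.0, limit=200)
    if not np.isfinite(z) or z <= 0:
        raise ValueError("quadrature normalization failed")
    g = g - np.min(g)
    return AnalyticPMF(
        grid=grid,
        values=g,
        description=(
            f"dimer bond-length free energy at {temperature:.0f} K; "
            f"quadrature normalization Z={z:.6g} (abs err {err:.2g})"
        ),
    )


def basin_free_energy_difference(
    spec: ToySpec, temperature: float | None = None
) -> float:
    """F(right basin) - F(left basin) of the double-well dimer, by quadrature.

    Basins are separated at the barrier position ``r0``; each basin's free
    energy is ``-k_B T ln`` of its Boltzmann weight including the ``r^2``
    Jacobian.
    """
    _check_dimer(spec)
    if spec.double_well is None:
        raise ValueError("basin analysis requires a double-well dimer")
    temperature = spec.temperature if temperature is None else temperature
    kt = KB * temperature
    a, w, _ = spec.double_well
    u0, _ = _bond_potential(spec, np.array([spec.bond_r0 - w]))
    u_ref = float(u0[0])

    def density(r):
        ub, _ = _bond_potential(spec, r)
        return r**2 * np.exp(-(ub - u_ref) / kt)

    lo, mid, hi = spec.bond_r0 - 3 * w, spec.bond_r0, spec.bond_r0 + 3 * w
    z_left, _ = quad(density, max(lo, 1e-3), mid, limit=200)
    z_right, _ = quad(density, mid, hi, limit=200)
    return float(-kt * np.log(z_right / z_left))


def design_asymmetric_dimer(
    delta_f: float = 1.0,
    barrier: float = 2.0,
    well_half_width: float = 0.5,
    bond_r0: float = 4.0,
    h_counts: tuple[int, int] = (3, 3),
    temperature: float = 350.0,
    seed: int = 0,
) -> ToySpec:
    """Double-well dimer whose basin free-energy difference equals *delta_f*.

    The quartic steepness is set from the requested barrier height
    (``a = barrier / w^4``) and the linear tilt is solved by root finding so
    that the quadrature basin free-energy difference (Jacobian included)
    matches *delta_f* (kcal/mol, right minus left basin) at *temperature*.
    """
    a = barrier / well_half_width**4
    base = ToySpec(
        n_heavy=2,
        h_counts=h_counts,
        bond_r0=bond_r0,
        double_well=(a, well_half_width, 0.0),
        lj_epsilon=0.0,
        temperature=temperature,
        seed=seed,
    )

    def mismatch(tilt):
        spec = replace(base, double_well=(a, well_half_width, tilt))
        return basin_free_energy_difference(spec) - delta_f

    scale = delta_f / (2 * well_half_width) if delta_f != 0 else 1.0
    lo, hi = -4 * abs(scale) - 1.0, 4 * abs(scale) + 1.0
    tilt = brentq(mismatch, lo, hi, xtol=1e-10)
    return replace(base, double_well=(a, well_half_width, float(tilt)))


def default_dimer_spec(seed: int = 0) -> ToySpec:
    """The package's reference CG-solvable dimer (designed basin gap 1 kcal/mol)."""
    return design_asymmetric_dimer(delta_f=1.0, seed=seed)


def radial_pmf(
    distances: np.ndarray,
    grid: np.ndarray,
    temperature: float,
    min_count: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Free energy (kcal/mol) over bond-length bins from sampled distances.

    *grid* gives bin centres (uniform spacing assumed); bins with fewer than
    *min_count* samples are returned as NaN.  The histogram of scalar
    distances carries the radial Jacobian automatically, so the result is
    directly comparable with :func:`analytic_cg_pmf`.  Min-shifted to 0 over
    valid bins.
    """
    grid = np.asarray(grid, dtype=float)
    spacing = grid[1] - grid[0]
    edges = np.concatenate([grid - spacing / 2, [grid[-1] + spacing / 2]])
    counts, _ = np.histogram(distances, bins=edges)
    values = np.full(grid.shape, np.nan)
    valid = counts >= min_count
    if not valid.any():
        raise ValueError("no bin reached the minimum count")
    values[valid] = -KB * temperature * np.log(counts[valid].astype(float))
    values -= np.nanmin(values)
    return values, counts


def dimer_pmf_recovery(
    seed: int = 1,
    n_frames_per_temperature: int = 10000,
    n_steps: int = 1_000_000,
    temperatures=FIXTURE_TEMPERATURES,
    force_noise_sigma: float = 1.0,
    simulation_temperature: float = 350.0,
    timestep: float = 4.0,
    friction: float = 1.0,
    train_epochs: int = 800,
    min_count: int = 25,
) -> dict:
    """Full pipeline on the reference dimer: map, aggregate, train, simulate.

    Samples all-atom coordinate-force pairs of the double-well dimer at the
    pooled temperatures, aggregates them onto no-hydrogen beads, trains the
    pair potential by force matching, runs CG Langevin dynamics at the
    simulation temperature, and compares the simulated bond-length free
    energy with the exact quadrature result.

    Returns a dict with the trained model, trajectory, analytic and simulated
    free energies, and the maximum absolute error over populated bins
    (``"pmf_max_error"``, kcal/mol).
    """
    from .cg_dynamics import SimConfig, init_state, run
    from .cg_mapping import BeadTypeTable, CGFrame, aggregate_forces, build_noh_map
    from .dataset_builder import CGDataset
    from .neural_potential import PairRBFPotential, TrainConfig, train

    spec = default_dimer_spec(seed=seed)
    table = BeadTypeTable.standard_protein()
    topo, frame0 = make_toy_molecule(spec)
    cg_map = build_noh_map(topo, table)

    dataset = CGDataset()
    for i, temp in enumerate(temperatures):
        sampled = sample_dataset(
            spec,
            n_frames=n_frames_per_temperature,
            temperature=temp,
            seed=seed * 1000 + i,
            force_noise_sigma=force_noise_sigma,
        )
        for fr in sampled.frames:
            dataset.frames.append(aggregate_forces(fr, cg_map))
            dataset.domain_ids.append("dimer")
            dataset.temperatures.append(int(temp))

    model = PairRBFPotential(n_types=table.n_types, cutoff=10.0, n_basis=32)
    config = TrainConfig(
        epochs=train_epochs, batch_size=512, learning_rate=5e-2,
        lr_decay=0.997, seed=seed,
    )
    trained, history = train(model, dataset, dataset, config)

    start = CGFrame(
        coords=frame0.coords[cg_map.heavy_indices], bead_types=cg_map.bead_types
    )
    state = init_state(start, cg_map, simulation_temperature, seed=seed)
    sim = SimConfig(
        timestep=timestep, friction=friction, temperature=simulation_temperature,
        n_steps=n_steps, seed=seed, output_stride=10,
    )
    trajectory = run(state, trained, sim)
    distances = np.linalg.norm(
        trajectory.coords[:, 0] - trajectory.coords[:, 1], axis=1
    )
    pmf = analytic_cg_pmf(spec, temperature=simulation_temperature)
    simulated, counts = radial_pmf(
        distances, pmf.grid, simulation_temperature, min_count=min_count
    )
    mask = np.isfinite(simulated)
    return {
        "spec": spec,
        "model": trained,
        "history": history,
        "trajectory": trajectory,
        "distances": distances,
        "analytic_pmf": pmf,
        "simulated_pmf": simulated,
        "populated": mask,
        "counts": counts,
        "n_training_frames": len(dataset),
        "pmf_max_error": float(np.max(np.abs(simulated[mask] - pmf.values[mask]))),
    }


# ---------------------------------------------------------------------------
# mdCATH-like HDF5 fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureDomain:
    """Synthetic stand-in for one mdCATH domain group."""

    domain_id: str
    n_residues: int
    n_noh_atoms: int
    helix_fraction: float
    sheet_fraction: float
    bead_types: np.ndarray
    #: temperature (K) -> (coords [F,n,3], forces [F,n,3])
    trajectories: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def random_fixture_domain(
    domain_id: str,
    n_residues: int,
    n_noh_atoms: int,
    helix_fraction: float,
    sheet_fraction: float,
    n_frames: int,
    rng: np.random.Generator,
    temperatures=FIXTURE_TEMPERATURES,
    n_types: int = 12,
) -> FixtureDomain:
    """A domain with the requested metadata and random-walk coordinates.

    Coordinates are compact Gaussian clouds and forces are standard-normal
    draws scaled to a realistic magnitude; they are statistical stand-ins,
    not physical conformations.
    """
    types = rng.integers(0, n_types, size=n_noh_atoms)
    dom = FixtureDomain(
        domain_id=domain_id,
        n_residues=n_residues,
        n_noh_atoms=n_noh_atoms,
        helix_fraction=helix_fraction,
        sheet_fraction=sheet_fraction,
        bead_types=types,
    )
    radius = 3.0 * n_noh_atoms ** (1 / 3)
    for temp in temperatures:
        coords = radius * rng.standard_normal((n_frames, n_noh_atoms, 3)) / np.sqrt(3)
        forces = 10.0 * rng.standard_normal((n_frames, n_noh_atoms, 3))
        dom.trajectories[int(temp)] = (coords, forces)
    return dom


def write_fixture_h5(domains: list[FixtureDomain], path) -> None:
    """Write fixture domains in the dataset_builder HDF5 dialect."""
    import h5py

    with h5py.File(path, "w") as fh:
        for dom in domains:
            g = fh.create_group(dom.domain_id)
            g.attrs["residues"] = dom.n_residues
            g.attrs["noh_atoms"] = dom.n_noh_atoms
            g.attrs["helix_fraction"] = dom.helix_fraction
            g.attrs["sheet_fraction"] = dom.sheet_fraction
            g.create_dataset("types", data=np.asarray(dom.bead_types, dtype=np.int64))
            for temp, (coords, forces) in sorted(dom.trajectories.items()):
                tg = g.create_group(str(temp))
                tg.create_dataset("coords", data=np.asarray(coords, dtype="<f4"))
                tg.create_dataset("forces", data=np.asarray(forces, dtype="<f4"))
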