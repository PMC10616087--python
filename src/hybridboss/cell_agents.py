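"""Off-lattice cell agents: cycle, death, volume, pairwise mechanics.

Cells are spheres with a position, radius and a phase in {cycling, apoptotic,
necrotic, removed}.  Mechanics follows the usual overdamped pairwise
potential picture: short-range polynomial repulsion inside the radii sum,
weaker adhesion out to a multiple of it, forces summed to a velocity and
integrated with forward Euler.  The cycle is a single-rate stochastic
division model (division probability ``rate * dt`` per step, daughters with
half the mother's volume), optionally damped by mechanical pressure (simple
contact inhibition).  Death phases shrink exponentially and are removed
after a fixed duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import count
from typing import Sequence

import numpy as np

__all__ = [
    "Phase", "MechanicsParams", "CyclePar", "DeathParams", "CellAgent",
    "spheroid_init", "mechanics_step", "cycle_step", "death_step",
]


class Phase:
    CYCLING = "cycling"
    APOPTOTIC = "apoptotic"
    NECROTIC = "necrotic"
    REMOVED = "removed"

    ALL = (CYCLING, APOPTOTIC, NECROTIC, REMOVED)
    DEAD = (APOPTOTIC, NECROTIC)


@dataclass
class MechanicsParams:
    """Pairwise interaction parameters (all >= 0).

    ``repulsion``/``adhesion`` are force scales (µm/min at unit drag);
    ``max_interaction_factor`` multiplies the radii sum to give the adhesion
    cut-off; ``drag`` is the overdamped mobility divisor.
    """

    repulsion: float = 10.0
    adhesion: float = 0.4
    max_interaction_factor: float = 1.25
    drag: float = 1.0

    def __post_init__(self) -> None:
        if min(self.repulsion, self.adhesion, self.max_interaction_factor) < 0 or self.drag <= 0:
            raise ValueError("mechanics parameters must be >= 0 (drag > 0)")


@dataclass
class DeathParams:
    """Exponential shrink rate (1/min) and residence time (min) of dying cells."""

    shrink_rate: float = 0.005
    duration: float = 480.0


_cell_ids = count()


@dataclass
class CellAgent:
    """One cell: geometry, phase, substrate exchange rates and pools."""

    position: np.ndarray
    radius: float = 8.4
    phase: str = Phase.CYCLING
    phase_elapsed: float = 0.0
    division_rate: float = 0.0
    division_multiplier: float = 1.0
    cell_type: str = "default"
    id: int = field(default_factory=lambda: next(_cell_ids))
    uptake_rate: dict[str, float] = field(default_factory=dict)
    secretion_rate: dict[str, float] = field(default_factory=dict)
    secretion_target: dict[str, float] = field(default_factory=dict)
    internalised: dict[str, float] = field(default_factory=dict)
    receptors: dict = field(default_factory=dict)  # substrate -> ReceptorPool
    intracellular = None  # IntracellularAttachment, set by the coupling layer
    pressure: float = 0.0
    contact_inhibition_pressure: float = 0.0  # 0 disables contact inhibition
    dead_cells_exchange: bool = False
    _voxel: tuple | None = field(default=None, repr=False, compare=False)
    _slot: int = field(default=-1, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius ** 3

    @volume.setter
    def volume(self, v: float) -> None:
        self.radius = (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def alive(self) -> bool:
        return self.phase == Phase.CYCLING

    def exchanges_substrates(self) -> bool:
        if self.phase == Phase.REMOVED:
            return False
        return self.alive or self.dead_cells_exchange

    def effective_division_rate(self) -> float:
        rate = self.division_rate * self.division_multiplier
        if self.contact_inhibition_pressure > 0:
            rate *= max(0.0, 1.0 - self.pressure / self.contact_inhibition_pressure)
        return rate

    def start_apoptosis(self) -> None:
        if self.phase == Phase.CYCLING:
            self.phase = Phase.APOPTOTIC
            self.phase_elapsed = 0.0

    def start_necrosis(self) -> None:
        if self.phase == Phase.CYCLING:
            self.phase = Phase.NECROTIC
            self.phase_elapsed = 0.0


# ---------------------------------------------------------------------------
# Spheroid initialisation
# ---------------------------------------------------------------------------

def spheroid_init(radius: float, cell_radius: float) -> np.ndarray:
    """Hexagonal-close-packed positions (spacing ``2*cell_radius``) inside a
    sphere of the given radius centred at the origin.  Always includes the
    centre point."""
    if radius < cell_radius:
        raise ValueError("spheroid radius must be >= cell_radius")
    r = cell_radius
    positions = []
    # HCP lattice: layers along z at pitch sqrt(6)*2/3*r, rows at sqrt(3)*r
    kmax = int(radius / (2.0 * math.sqrt(6.0) / 3.0 * r)) + 2
    jmax = int(radius / (math.sqrt(3.0) * r)) + 2
    imax = int(radius / (2.0 * r)) + 2
    for k in range(-kmax, kmax + 1):
        z = 2.0 * math.sqrt(6.0) / 3.0 * r * k
        for j in range(-jmax, jmax + 1):
            y = math.sqrt(3.0) * r * (j + (k % 2) / 3.0)
            for i in range(-imax, imax + 1):
                x = r * (2 * i + ((j + k) % 2))
                if x * x + y * y + z * z <= radius * radius + 1e-9:
                    positions.append((x, y, z))
    return np.array(sorted(positions), dtype=float)


# ---------------------------------------------------------------------------
# Mechanics
# ---------------------------------------------------------------------------

def mechanics_step(cells: Sequence[CellAgent], params: MechanicsParams, dt: float,
                   rng: np.random.Generator | None = None) -> None:
    """Overdamped pairwise mechanics, forward-Euler position update in place.

    Repulsion ``c_r*(1-d/R_sum)^2`` for d < R_sum, adhesion
    ``-c_a*(1-d/R_max)^2`` for d < R_max, applied symmetrically.  Also
    records a scalar ``pressure`` per cell (sum of repulsion overlap terms)
    used by the optional contact-inhibition rule.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    active = [c for c in cells if c.phase != Phase.REMOVED]
    n = len(active)
    if n == 0:
        return
    pos = np.array([c.position for c in active])
    rad = np.array([c.radius for c in active])

    from scipy.spatial import cKDTree

    cutoff = params.max_interaction_factor * 2.0 * rad.max()
    pairs = cKDTree(pos).query_pairs(cutoff, output_type="ndarray")
    forces = np.zeros((n, 3))
    pressure = np.zeros(n)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        diff = pos[i] - pos[j]
        dist = np.linalg.norm(diff, axis=1)
        zero = dist == 0.0
        if zero.any():
            rng = rng if rng is not None else np.random.default_rng()
            for k in np.flatnonzero(zero):
                u = rng.standard_normal(3)
                diff[k] = 1e-6 * u / np.linalg.norm(u)
            dist[zero] = 1e-6
        rsum = rad[i] + rad[j]
        rmax = params.max_interaction_factor * rsum
        overlap = np.clip(1.0 - dist / rsum, 0.0, None)
        rep = params.repulsion * overlap ** 2
        adh = np.where(dist < rmax, params.adhesion * (1.0 - dist / rmax) ** 2, 0.0)
        mag = rep - adh
        fvec = (mag / dist)[:, None] * diff
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)  # symmetric pairs: Newton's third law
        np.add.at(pressure, i, overlap ** 2)
        np.add.at(pressure, j, overlap ** 2)
    velocities = forces / params.drag
    for c, v, p in zip(active, velocities, pressure):
        c.position = c.position + v * dt
        c.pressure = float(p)
        c._voxel = None


# ---------------------------------------------------------------------------
# Cycle and death
# ---------------------------------------------------------------------------

def cycle_step(cell: CellAgent, dt: float, rng: np.random.Generator) -> CellAgent | None:
    """Advance the stochastic cycle; returns a daughter cell on division.

    Division occurs with probability ``effective_rate * dt`` (clamped to 1);
    mother and daughter each get half the mother's volume, the daughter is
    displaced by one (new) radius in a uniform random direction and inherits
    the mother's exchange rates and Boolean state.
    """
    if cell.phase != Phase.CYCLING:
        return None
    p = min(1.0, cell.effective_division_rate() * dt)
    if p <= 0.0 or rng.random() >= p:
        return None
    half_volume = cell.volume / 2.0
    cell.volume = half_volume
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    daughter = CellAgent(
        position=cell.position + cell.radius * u,
        radius=cell.radius,
        division_rate=cell.division_rate,
        division_multiplier=cell.division_multiplier,
        cell_type=cell.cell_type,
        uptake_rate=dict(cell.uptake_rate),
        secretion_rate=dict(cell.secretion_rate),
        secretion_target=dict(cell.secretion_target),
        contact_inhibition_pressure=cell.contact_inhibition_pressure,
        dead_cells_exchange=cell.dead_cells_exchange,
    )
    for name, pool in cell.receptors.items():
        daughter.receptors[name] = pool.copy()
    if cell.intracellular is not None:
        daughter.intracellular = cell.intracellular.spawn_daughter()
    return daughter


def death_step(cell: CellAgent, dt: float, params: DeathParams) -> None:
    """Shrink a dying cell exponentially; remove it after the configured
    residence time."""
    if cell.phase not in Phase.DEAD:
        return
    cell.volume = cell.volume * math.exp(-params.shrink_rate * dt)
    cell.phase_elapsed += dt
    if cell.phase_elapsed > params.duration:
        cell.phase = Phase.REMOVED
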