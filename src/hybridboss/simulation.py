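"""The hybrid main loop.

Advances simulation time in diffusion-sized ticks; per tick, in fixed order:
boundary pulses -> diffusion/decay (with Dirichlet re-imposed) -> cell
secretion/uptake and receptor kinetics -> mechanics (every dt_mechanics) ->
cycle and death (every dt_cells) -> per-cell intracellular updates at each
cell's own scheduled regulatory time.  Snapshots are written every
``snapshot_interval`` minutes, starting at t=0.

Randomness discipline: a master seed spawns one stream for the world
(mechanics tie-breaks, cycle draws), one per cell (Boolean engine, drug
draws), and daughters branch off their mother's stream, so a run is
bit-reproducible from (config, seed) and replicate k of a config uses the
deterministic child seed (seed, k).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .analysis import SnapshotTable
from .cell_agents import (CellAgent, DeathParams, MechanicsParams, Phase,
                          cycle_step, death_step, mechanics_step, spheroid_init)
from .config_io import (CellTypeConfig, SimulationConfig, write_manifest,
                        write_snapshot)
from .coupling import IntracellularAttachment, update_cell_intracellular
from .microenvironment import MicroenvGrid
from .receptors import ReceptorPool

__all__ = ["RunResult", "run_simulation", "run_replicates", "replicate_seed"]


@dataclass
class RunResult:
    snapshots: SnapshotTable
    grid: MicroenvGrid
    cells: list[CellAgent]
    out_dir: Path | None = None


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic child seed for one replicate of a configuration."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate,))


def _build_cells(config: SimulationConfig, ct: CellTypeConfig,
                 cell_ss: np.random.SeedSequence) -> list[CellAgent]:
    positions = (spheroid_init(config.spheroid_radius, ct.cell_radius)
                 if config.spheroid_radius > 0 else np.zeros((1, 3)))
    cells: list[CellAgent] = []
    streams = cell_ss.spawn(len(positions))
    for i, pos in enumerate(positions):
        cell = CellAgent(
            position=pos, radius=ct.cell_radius, division_rate=ct.division_rate,
            cell_type=ct.name, id=i,
            uptake_rate=dict(ct.uptake_rate), secretion_rate=dict(ct.secretion_rate),
            secretion_target=dict(ct.secretion_target),
            contact_inhibition_pressure=ct.contact_inhibition_pressure)
        for rc in ct.receptors:
            cell.receptors[rc.substrate] = ReceptorPool(
                r_free=rc.receptors_per_cell, k_on=rc.k_on, k_off=rc.k_off,
                k_endo=rc.k_endo, k_recycle=rc.k_recycle)
        if ct.intracellular is not None:
            ic = ct.intracellular
            cell.intracellular = IntracellularAttachment.create(
                network=ic.network, init=ic.initial_condition, settings=ic.settings(),
                rng=np.random.default_rng(streams[i]), mutants=ic.mutants,
                input_mappings=ic.input_mappings, output_mappings=ic.output_mappings)
        cells.append(cell)
    return cells


def _apply_pulses(grid: MicroenvGrid, config: SimulationConfig, t: float) -> None:
    """Substrates with a pulse schedule get Dirichlet walls at the active
    pulse value, 0 outside pulses (wash-out); later overlapping entries win."""
    pulsed = {p.substrate for p in config.pulses}
    for name in pulsed:
        value = 0.0
        for pulse in config.pulses:
            if pulse.substrate == name and pulse.active(t):
                value = pulse.value
        grid.substrates[name].dirichlet_value = value


def run_simulation(config: SimulationConfig, seed: int | None = None,
                   out_dir: str | Path | None = None) -> RunResult:
    """Run one replicate of the configured hybrid simulation."""
    seed = config.seed if seed is None else seed
    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    world_ss, cells_ss = master.spawn(2)
    world_rng = np.random.default_rng(world_ss)

    grid = MicroenvGrid(config.bounds, config.dx, config.substrates)
    _apply_pulses(grid, config, 0.0)
    grid.apply_dirichlet()

    ct = config.cell_type(config.spheroid_cell_type)
    cells = _build_cells(config, ct, cells_ss)
    next_cell_id = len(cells)
    mech = MechanicsParams(repulsion=ct.repulsion, adhesion=ct.adhesion,
                           max_interaction_factor=ct.max_interaction_factor,
                           drag=ct.drag)
    death_params = DeathParams(shrink_rate=ct.apoptosis_shrink_rate,
                               duration=ct.apoptosis_duration)
    output_nodes = (ct.intracellular.network.output_nodes
                    if ct.intracellular is not None else [])

    has_secretion = any(ct.secretion_rate.values())
    cache = _PopulationCache(grid, cells)
    if not has_secretion:
        for name, rate in ct.uptake_rate.items():
            if rate:
                cache.track_uptake(name)
    receptor_rates: dict[str, dict[str, float]] = {}
    for rc in ct.receptors:
        cache.track_receptors(rc.substrate)
        receptor_rates[rc.substrate] = {"k_on": rc.k_on, "k_off": rc.k_off,
                                        "k_endo": rc.k_endo, "k_recycle": rc.k_recycle}

    dt = config.dt_diffusion
    n_ticks = int(round(config.max_time / dt))
    eps = 1e-9
    next_mec = config.dt_mechanics
    next_cell = config.dt_cells
    next_snap = config.snapshot_interval

    snapshot_frames = []
    snapshot_times: list[float] = []

    def take_snapshot(index: int, t: float) -> None:
        if out_dir is not None:
            write_snapshot(out_dir, index, t, cells, grid, output_nodes)
        snapshot_frames.append(_snapshot_frame(t, cells, output_nodes))
        snapshot_times.append(t)

    take_snapshot(0, 0.0)
    snap_index = 1

    for tick in range(1, n_ticks + 1):
        t = tick * dt
        _apply_pulses(grid, config, t)
        grid.diffusion_decay_step(dt)
        if has_secretion:
            grid.secrete_uptake_step(cells, dt)
        elif cache.uptake:
            cache.uptake_step(dt)
        for name in cache.rec:
            cache.receptor_step(dt, receptor_rates[name], name)

        if t + eps >= next_mec:
            mechanics_step(cells, mech, config.dt_mechanics, world_rng)
            cache.refresh_positions()
            next_mec += config.dt_mechanics

        if t + eps >= next_cell:
            for cell in list(cells):
                if cell.phase == Phase.CYCLING:
                    daughter = cycle_step(cell, config.dt_cells, world_rng)
                    if daughter is not None:
                        daughter.id = next_cell_id
                        next_cell_id += 1
                        # daughter pools re-copied from the live array state
                        cache.sync_receptors_to_cell(cell)
                        for nm, pool in cell.receptors.items():
                            daughter.receptors[nm] = pool.copy()
                        cells.append(daughter)
                        cache.add(daughter)
                        cache.refresh_cell(cell)
                elif cell.phase in Phase.DEAD:
                    death_step(cell, config.dt_cells, death_params)
                    cache.refresh_cell(cell)
            next_cell += config.dt_cells

        for cell in cells:
            att = cell.intracellular
            if att is None or cell.phase != Phase.CYCLING:
                continue  # dying/removed cells stop signalling
            if t + eps >= att.next_update_time:
                cache.sync_receptors_to_cell(cell)
                update_cell_intracellular(
                    cell, grid, config.drugs, t,
                    redraw_inhibition=(config.redraw_inhibition == "per_step"))
                assert att.next_update_time > t + eps, "regulatory update skipped"
                if cell.phase != Phase.CYCLING:
                    cache.refresh_cell(cell)

        if t + eps >= next_snap:
            take_snapshot(snap_index, t)
            snap_index += 1
            next_snap += config.snapshot_interval

    cache.sync_receptors_all()
    table = SnapshotTable(_concat_frames(snapshot_frames, output_nodes))
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        write_manifest(out_path, config,
                       seed if isinstance(seed, int) else -1, snapshot_times)
    return RunResult(snapshots=table, grid=grid, cells=cells, out_dir=out_path)


class _PopulationCache:
    """Array-resident view of the alive population for the per-tick
    vectorised microenvironment couplings (voxel indices, volumes, receptor
    pools).  Slots are append-only; cells deactivate in place when they stop
    cycling.  Receptor state lives in the arrays between regulatory updates
    and is written back to each cell's pool object on demand."""

    def __init__(self, grid: MicroenvGrid, cells: list[CellAgent]):
        self.grid = grid
        self.cells: list[CellAgent] = []
        self.active = np.zeros(0, dtype=bool)
        self.volume = np.zeros(0)
        self.lin = np.zeros(0, dtype=np.int64)
        self.uptake: dict[str, np.ndarray] = {}
        self.rec: dict[str, dict[str, np.ndarray]] = {}
        for cell in cells:
            self.add(cell)

    def _grow(self, arr: np.ndarray, value, dtype=float) -> np.ndarray:
        return np.append(arr, np.asarray([value], dtype=dtype))

    def add(self, cell: CellAgent) -> None:
        slot = len(self.cells)
        cell._slot = slot
        self.cells.append(cell)
        self.active = self._grow(self.active, cell.exchanges_substrates(), bool)
        self.volume = self._grow(self.volume, cell.volume)
        self.lin = self._grow(self.lin, self._linear_voxel(cell), np.int64)
        for name in self.uptake:
            self.uptake[name] = self._grow(self.uptake[name],
                                           cell.uptake_rate.get(name, 0.0))
        for name, bank in self.rec.items():
            pool = cell.receptors.get(name)
            for key in ("r_free", "r_bound", "r_internalised"):
                bank[key] = self._grow(bank[key], getattr(pool, key) if pool else 0.0)

    def track_uptake(self, name: str) -> None:
        self.uptake[name] = np.array([c.uptake_rate.get(name, 0.0) for c in self.cells])

    def track_receptors(self, name: str) -> None:
        pools = [c.receptors.get(name) for c in self.cells]
        self.rec[name] = {
            key: np.array([getattr(p, key) if p else 0.0 for p in pools])
            for key in ("r_free", "r_bound", "r_internalised")}

    def _linear_voxel(self, cell: CellAgent) -> int:
        i, j, k = self.grid.cell_voxel(cell)
        _, ny, nz = self.grid.shape
        return (i * ny + j) * nz + k

    def refresh_positions(self) -> None:
        """Recompute voxel indices after the population moved (vectorised)."""
        if not self.cells:
            return
        g = self.grid
        pos = np.array([c.position for c in self.cells])
        idx = []
        for axis in range(3):
            lo = g.bounds[2 * axis]
            t = np.clip((pos[:, axis] - lo) / g.dx, 0.0, None)
            i = np.floor(t).astype(np.int64)
            i -= ((t == np.floor(t)) & (i > 0)).astype(np.int64)
            idx.append(np.clip(i, 0, g.shape[axis] - 1))
        self.lin = (idx[0] * g.shape[1] + idx[1]) * g.shape[2] + idx[2]
        for cell, i, j, k in zip(self.cells, *idx):
            cell._voxel = (int(i), int(j), int(k))

    def refresh_cell(self, cell: CellAgent) -> None:
        slot = cell._slot
        self.active[slot] = cell.exchanges_substrates()
        self.volume[slot] = cell.volume

    def sync_receptors_to_cell(self, cell: CellAgent) -> None:
        slot = cell._slot
        for name, bank in self.rec.items():
            pool = cell.receptors.get(name)
            if pool is not None:
                pool.r_free = float(bank["r_free"][slot])
                pool.r_bound = float(bank["r_bound"][slot])
                pool.r_internalised = float(bank["r_internalised"][slot])

    def sync_receptors_all(self) -> None:
        for cell in self.cells:
            if cell.receptors:
                self.sync_receptors_to_cell(cell)

    # -- per-tick physics ---------------------------------------------------
    def uptake_step(self, dt: float) -> None:
        """Vectorised equivalent of the sequential per-cell implicit uptake
        (pure uptake, no secretion): cells sharing a voxel compose their
        divisors by a segmented cumulative product, preserving the exact
        sequential bookkeeping and mass budget."""
        g = self.grid
        vvox = g.voxel_volume
        for name, rates in self.uptake.items():
            mask = self.active & (rates > 0.0)
            if not mask.any():
                continue
            lin = self.lin[mask]
            f = dt * (self.volume[mask] / vvox) * rates[mask]
            order = np.argsort(lin, kind="stable")
            lin_o, f_o = lin[order], f[order]
            starts = np.flatnonzero(np.r_[True, np.diff(lin_o) != 0])
            logcp = np.cumsum(np.log1p(f_o))
            base = np.repeat(logcp[starts] - np.log1p(f_o[starts]), np.diff(np.r_[starts, len(f_o)]))
            cp = np.exp(logcp - base)  # within-voxel cumulative product of (1+f)
            flat = g.fields[name].ravel()
            rho0 = flat[lin_o[starts]]
            rho_after = np.repeat(rho0, np.diff(np.r_[starts, len(f_o)])) / cp
            taken = dt * (self.volume[mask][order]) * rates[mask][order] * rho_after
            flat[lin_o[starts]] = rho0 / cp[np.r_[starts[1:] - 1, len(cp) - 1]]
            cell_idx = np.flatnonzero(mask)[order]
            for ci, tk in zip(cell_idx, taken):
                cell = self.cells[ci]
                cell.internalised[name] = cell.internalised.get(name, 0.0) + tk

    def receptor_step(self, dt: float, k: dict[str, float], name: str) -> None:
        """Vectorised three-pool receptor kinetics against each active
        cell's voxel concentration, with net consumption removed from the
        field (scaled in the rare overdrawn-voxel tick)."""
        import math as _math

        bank = self.rec[name]
        mask = self.active
        if not mask.any():
            return
        g = self.grid
        flat = g.fields[name].ravel()
        lin = self.lin[mask]
        ligand = flat[lin]
        rf = bank["r_free"][mask]
        rb = bank["r_bound"][mask]
        ri = bank["r_internalised"][mask]
        fastest = max(float(np.max(k["k_on"] * ligand)) + k["k_off"] + k["k_endo"],
                      k["k_recycle"], 1e-12)
        n_sub = max(1, int(_math.ceil(dt * fastest / 0.2)))
        h = dt / n_sub
        consumed = np.zeros(rf.shape)
        for _ in range(n_sub):
            bind = k["k_on"] * ligand * rf * h
            release = k["k_off"] * rb * h
            endo = k["k_endo"] * rb * h
            recycle = k["k_recycle"] * ri * h
            rf += release + recycle - bind
            rb += bind - release - endo
            ri += endo - recycle
            consumed += bind - release
        bank["r_free"][mask] = rf
        bank["r_bound"][mask] = rb
        bank["r_internalised"][mask] = ri
        delta = np.zeros(flat.shape)
        np.add.at(delta, lin, consumed / g.voxel_volume)
        over = delta > flat
        if over.any():
            scale = np.where(over & (delta > 0), flat / np.maximum(delta, 1e-300), 1.0)
            delta = delta * scale
        flat -= delta
        np.maximum(flat, 0.0, out=flat)


def _snapshot_frame(t: float, cells, output_nodes):
    import pandas as pd

    records = []
    for cell in cells:
        if cell.phase == Phase.REMOVED:
            continue
        rec = {"time": t, "id": cell.id, "x": cell.position[0], "y": cell.position[1],
               "z": cell.position[2], "radius": cell.radius, "phase": cell.phase,
               "layer": ""}
        for node in output_nodes:
            rec[node] = (int(cell.intracellular.node_value(node))
                         if cell.intracellular is not None else 0)
        records.append(rec)
    from .analysis import CELL_COLUMNS
    return pd.DataFrame(records, columns=CELL_COLUMNS + list(output_nodes))


def _concat_frames(frames, output_nodes):
    import pandas as pd

    return pd.concat(frames, ignore_index=True)


def run_replicates(config: SimulationConfig, n: int | None = None,
                   out_root: str | Path | None = None) -> list[RunResult]:
    """Run n replicates with deterministic child seeds of the config seed."""
    n = config.replicates if n is None else n
    results = []
    for k in range(n):
        out_dir = Path(out_root) / f"replicate_{k:02d}" if out_root is not None else None
        results.append(run_simulation(config, seed=replicate_seed(config.seed, k),
                                      out_dir=out_dir))
    return results
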