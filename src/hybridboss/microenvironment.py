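"""Voxelised substrate fields: diffusion, decay, Dirichlet supply, cell exchange.

The domain is a 3D box split into cubic voxels of edge ``dx``.  Each substrate
diffuses with an unconditionally stable operator-split (locally one
dimensional) implicit scheme — one tridiagonal solve per axis per step, in
fixed x, y, z order — decays as ``rho / (1 + lambda*dt)``, and can be held at
a fixed concentration on any subset of the six box walls (Dirichlet faces,
modelling supply from the surroundings).  Non-Dirichlet faces are no-flux.

Cells couple to the field at their nearest voxel only: target-driven
secretion and first-order uptake are applied with an implicit update whose
removed mass is booked into the cell's internalised pool exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

FACES = ("xmin", "xmax", "ymin", "ymax", "zmin", "zmax")

__all__ = ["SubstrateSpec", "MicroenvGrid", "FACES"]


@dataclass
class SubstrateSpec:
    """Physical parameters of one diffusing substrate.

    diffusion_coefficient in µm²/min, decay_rate in 1/min; Dirichlet value in
    concentration units applied on ``dirichlet_faces`` (all six by default
    when a value is set).
    """

    name: str
    diffusion_coefficient: float = 0.0
    decay_rate: float = 0.0
    dirichlet_value: float | None = None
    dirichlet_faces: tuple[str, ...] = FACES

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0 or self.decay_rate < 0:
            raise ValueError("diffusion_coefficient and decay_rate must be >= 0")
        bad = set(self.dirichlet_faces) - set(FACES)
        if bad:
            raise ValueError(f"unknown Dirichlet faces {sorted(bad)}")


class _ThomasSolver:
    """Pre-factorised constant-coefficient tridiagonal solver for
    (I - alpha * Lap1D) with no-flux ends, vectorised over trailing columns."""

    def __init__(self, n: int, alpha: float):
        self.n = n
        self.alpha = alpha
        lower = np.full(n, -alpha)
        diag = np.full(n, 1.0 + 2.0 * alpha)
        diag[0] = diag[-1] = 1.0 + alpha  # no-flux boundary rows
        upper = np.full(n, -alpha)
        # forward sweep factors
        cp = np.empty(n)
        denom = np.empty(n)
        denom[0] = diag[0]
        cp[0] = upper[0] / denom[0]
        for i in range(1, n):
            denom[i] = diag[i] - lower[i] * cp[i - 1]
            cp[i] = upper[i] / denom[i]
        self._cp = cp
        self._denom = denom
        self._lower = lower

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve along axis 0 of ``rhs`` (shape (n, ...)) in place-free form."""
        n = self.n
        d = np.empty_like(rhs)
        d[0] = rhs[0] / self._denom[0]
        for i in range(1, n):
            d[i] = (rhs[i] - self._lower[i] * d[i - 1]) / self._denom[i]
        x = np.empty_like(rhs)
        x[-1] = d[-1]
        for i in range(n - 2, -1, -1):
            x[i] = d[i] - self._cp[i] * x[i + 1]
        return x


class MicroenvGrid:
    """Voxelised concentration fields over a 3D box domain."""

    def __init__(self, bounds: Sequence[float], dx: float,
                 substrates: Iterable[SubstrateSpec]):
        if len(bounds) != 6:
            raise ValueError("bounds must be (x0, x1, y0, y1, z0, z1)")
        self.bounds = tuple(float(b) for b in bounds)
        x0, x1, y0, y1, z0, z1 = self.bounds
        if dx <= 0:
            raise ValueError("dx must be > 0")
        self.dx = float(dx)
        self.shape = (max(1, round((x1 - x0) / dx)),
                      max(1, round((y1 - y0) / dx)),
                      max(1, round((z1 - z0) / dx)))
        for extent, n in zip((x1 - x0, y1 - y0, z1 - z0), self.shape):
            if not math.isclose(extent, n * dx, rel_tol=1e-9):
                raise ValueError("domain extent must be a multiple of dx on every axis")
        self.substrates: dict[str, SubstrateSpec] = {}
        self.fields: dict[str, np.ndarray] = {}
        for spec in substrates:
            if spec.name in self.substrates:
                raise ValueError(f"duplicate substrate {spec.name!r}")
            self.substrates[spec.name] = spec
            self.fields[spec.name] = np.zeros(self.shape)
        self._solvers: dict[tuple[int, float], _ThomasSolver] = {}
        self._clamp_count = 0

    # -- geometry -----------------------------------------------------------
    @property
    def voxel_volume(self) -> float:
        return self.dx ** 3

    def voxel_centers(self, axis: int) -> np.ndarray:
        lo = self.bounds[2 * axis]
        return lo + (np.arange(self.shape[axis]) + 0.5) * self.dx

    def nearest_voxel(self, position: Sequence[float]) -> tuple[int, int, int]:
        """Index of the voxel whose centre is nearest; ties break toward the
        lower index; positions outside the domain are clamped (warned)."""
        idx = []
        for axis in range(3):
            lo, hi = self.bounds[2 * axis], self.bounds[2 * axis + 1]
            x = position[axis]
            if x < lo or x > hi:
                self._clamp_count += 1
                if self._clamp_count <= 5:
                    logger.warning("position %s outside domain on axis %d; clamped"
                                   "%s", position, axis,
                                   " (further clamp warnings suppressed)"
                                   if self._clamp_count == 5 else "")
                x = min(max(x, lo), hi)
            t = (x - lo) / self.dx
            i = int(math.floor(t))
            if i > 0 and t == math.floor(t):
                i -= 1  # equidistant from two centres: choose the lower index
            idx.append(min(max(i, 0), self.shape[axis] - 1))
        return tuple(idx)

    # -- dynamics -----------------------------------------------------------
    def _solver(self, n: int, alpha: float) -> _ThomasSolver:
        key = (n, alpha)
        if key not in self._solvers:
            self._solvers[key] = _ThomasSolver(n, alpha)
        return self._solvers[key]

    def diffusion_decay_step(self, dt: float) -> None:
        """One operator-split implicit diffusion step plus implicit decay.

        Axis sweeps run in fixed x, y, z order; Dirichlet faces are re-imposed
        after each sweep; decay applies ``rho <- rho / (1 + lambda*dt)`` once.
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        for name, spec in self.substrates.items():
            rho = self.fields[name]
            if not np.isfinite(rho).all():
                raise FloatingPointError(f"non-finite concentrations in {name!r}")
            if spec.diffusion_coefficient > 0:
                alpha = spec.diffusion_coefficient * dt / self.dx ** 2
                for axis in range(3):
                    n = self.shape[axis]
                    if n == 1:
                        continue
                    solver = self._solver(n, alpha)
                    moved = np.moveaxis(rho, axis, 0)
                    flat = moved.reshape(n, -1)
                    out = solver.solve(flat)
                    rho = np.moveaxis(out.reshape(moved.shape), 0, axis)
                    self.fields[name] = rho
                    self._impose_dirichlet(name)
                    rho = self.fields[name]
            if spec.decay_rate > 0:
                rho = rho / (1.0 + spec.decay_rate * dt)
            # keep the array C-contiguous: downstream couplings mutate ravel views
            self.fields[name] = np.ascontiguousarray(rho)
            self._impose_dirichlet(name)

    def apply_dirichlet(self) -> None:
        """Impose all configured Dirichlet boundary values."""
        for name in self.substrates:
            self._impose_dirichlet(name)

    def _impose_dirichlet(self, name: str) -> None:
        spec = self.substrates[name]
        if spec.dirichlet_value is None:
            return
        rho = self.fields[name]
        v = spec.dirichlet_value
        faces = spec.dirichlet_faces
        if "xmin" in faces:
            rho[0, :, :] = v
        if "xmax" in faces:
            rho[-1, :, :] = v
        if "ymin" in faces:
            rho[:, 0, :] = v
        if "ymax" in faces:
            rho[:, -1, :] = v
        if "zmin" in faces:
            rho[:, :, 0] = v
        if "zmax" in faces:
            rho[:, :, -1] = v

    def cell_voxel(self, cell) -> tuple[int, int, int]:
        """Nearest voxel of a cell, cached until the cell moves."""
        if cell._voxel is None:
            cell._voxel = self.nearest_voxel(cell.position)
        return cell._voxel

    def concentration_for_cell(self, name: str, cell) -> float:
        return float(self.fields[name][self.cell_voxel(cell)])

    def total_mass(self, name: str) -> float:
        return float(self.fields[name].sum() * self.voxel_volume)

    def concentration_at(self, name: str, position: Sequence[float]) -> float:
        return float(self.fields[name][self.nearest_voxel(position)])

    # -- cell exchange ------------------------------------------------------
    def secrete_uptake_step(self, cells, dt: float) -> None:
        """Implicit secretion/uptake exchange with each cell's nearest voxel.

        Per cell: ``rho <- (rho + dt*f*S*rho_star) / (1 + dt*f*(U+S))`` with
        ``f = V_cell / V_voxel``; the uptaken mass ``dt*V_cell*U*rho_new`` is
        added to the cell's internalised pool, which makes the voxel + pool
        budget exact by construction.  Cells sharing a voxel are processed in
        order, each seeing the previous one's updated concentration.
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        vvox = self.voxel_volume
        for cell in cells:
            if not cell.exchanges_substrates():
                continue
            idx = self.cell_voxel(cell)
            f = cell.volume / vvox
            for name in self.substrates:
                uptake = cell.uptake_rate.get(name, 0.0)
                secrete = cell.secretion_rate.get(name, 0.0)
                if uptake == 0.0 and secrete == 0.0:
                    continue
                target = cell.secretion_target.get(name, 0.0)
                rho = self.fields[name][idx]
                rho_new = (rho + dt * f * secrete * target) / (1.0 + dt * f * (uptake + secrete))
                if rho_new < 0:
                    raise FloatingPointError(
                        f"negative concentration for {name!r} at voxel {idx}")
                self.fields[name][idx] = rho_new
                taken = dt * cell.volume * uptake * rho_new
                if taken:
                    cell.internalised[name] = cell.internalised.get(name, 0.0) + taken
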