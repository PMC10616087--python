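"""Per-cell receptor pools: ligand binding, internalisation and recycling.

A three-pool kinetic model of surface receptor trafficking, with 1:1
ligand:receptor stoichiometry::

    dR_b/dt =  k_on*L*R_f - (k_off + k_endo)*R_b
    dR_i/dt =  k_endo*R_b - k_recycle*R_i
    dR_f/dt = -k_on*L*R_f + k_off*R_b + k_recycle*R_i

Receptor number is conserved exactly; the ligand mass consumed from the
local voxel is the net binding flux (binding minus release; ligand carried
by internalised receptors is degraded on recycling).  Setting
``k_endo = k_recycle = 0`` recovers a plain reversible surface-binding
model.  Integration is explicit Euler with automatic sub-stepping so pools
stay nonnegative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ReceptorPool", "receptor_step", "receptor_step_many", "bound_fraction"]


@dataclass
class ReceptorPool:
    """State and rate constants of one cell's receptor system.

    Pools are in receptor units (interchangeable with ligand mass units at
    the assumed 1:1 stoichiometry); ``k_on`` in 1/(concentration*min), the
    other rates in 1/min.
    """

    r_free: float
    r_bound: float = 0.0
    r_internalised: float = 0.0
    k_on: float = 0.0
    k_off: float = 0.0
    k_endo: float = 0.0
    k_recycle: float = 0.0

    def __post_init__(self) -> None:
        if min(self.r_free, self.r_bound, self.r_internalised) < 0:
            raise ValueError("receptor pools must be >= 0")
        if min(self.k_on, self.k_off, self.k_endo, self.k_recycle) < 0:
            raise ValueError("rate constants must be >= 0")

    @property
    def r_total(self) -> float:
        return self.r_free + self.r_bound + self.r_internalised

    @property
    def bound_fraction(self) -> float:
        total = self.r_total
        if total <= 0:
            raise ValueError("bound_fraction undefined for an empty receptor pool")
        return self.r_bound / total

    def copy(self) -> "ReceptorPool":
        return ReceptorPool(self.r_free, self.r_bound, self.r_internalised,
                            self.k_on, self.k_off, self.k_endo, self.k_recycle)


def receptor_step(pool: ReceptorPool, ligand_concentration: float, dt: float,
                  max_available_mass: float | None = None) -> float:
    """Advance the pool by ``dt`` minutes at the given (held) local ligand
    concentration; returns the net ligand mass consumed from the voxel.

    ``max_available_mass`` optionally caps cumulative net consumption at the
    mass actually present in the voxel (binding is scaled down in the rare
    step where the cap binds).
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if ligand_concentration < 0:
        raise ValueError("ligand concentration must be >= 0")
    total_before = pool.r_total
    fastest = max(pool.k_on * ligand_concentration + pool.k_off + pool.k_endo,
                  pool.k_recycle, 1e-12)
    n_sub = max(1, int(math.ceil(dt * fastest / 0.2)))
    h = dt / n_sub
    consumed = 0.0
    for _ in range(n_sub):
        bind = pool.k_on * ligand_concentration * pool.r_free * h
        if max_available_mass is not None:
            headroom = max_available_mass - consumed + pool.k_off * pool.r_bound * h
            if bind > headroom:
                bind = max(0.0, headroom)
        release = pool.k_off * pool.r_bound * h
        endo = pool.k_endo * pool.r_bound * h
        recycle = pool.k_recycle * pool.r_internalised * h
        pool.r_free += release + recycle - bind
        pool.r_bound += bind - release - endo
        pool.r_internalised += endo - recycle
        consumed += bind - release
        if min(pool.r_free, pool.r_bound, pool.r_internalised) < -1e-9 * max(total_before, 1.0):
            raise FloatingPointError("receptor pool went negative; sub-stepping bug")
        pool.r_free = max(pool.r_free, 0.0)
        pool.r_bound = max(pool.r_bound, 0.0)
        pool.r_internalised = max(pool.r_internalised, 0.0)
    drift = pool.r_total - total_before
    if abs(drift) > 1e-9 * max(total_before, 1.0):
        raise FloatingPointError("receptor conservation violated")
    return consumed


def bound_fraction(pool: ReceptorPool) -> float:
    """Fraction of receptors currently ligand-bound, in [0, 1]."""
    return pool.bound_fraction


def receptor_step_many(pools: list[ReceptorPool], ligand: "np.ndarray", dt: float
                       ) -> "np.ndarray":
    """Vectorised :func:`receptor_step` over many pools at per-pool (held)
    ligand concentrations; returns the net consumed mass per pool.

    Same explicit sub-stepped Euler scheme; the sub-step count is shared
    (set by the fastest pool) so the population advances in lockstep.
    """
    import numpy as np

    if not pools:
        return np.zeros(0)
    rf = np.array([p.r_free for p in pools])
    rb = np.array([p.r_bound for p in pools])
    ri = np.array([p.r_internalised for p in pools])
    k_on = np.array([p.k_on for p in pools])
    k_off = np.array([p.k_off for p in pools])
    k_endo = np.array([p.k_endo for p in pools])
    k_rec = np.array([p.k_recycle for p in pools])
    ligand = np.asarray(ligand, dtype=float)

    fastest = float(np.max(np.maximum(k_on * ligand + k_off + k_endo, k_rec)))
    n_sub = max(1, int(math.ceil(dt * max(fastest, 1e-12) / 0.2)))
    h = dt / n_sub
    consumed = np.zeros(len(pools))
    for _ in range(n_sub):
        bind = k_on * ligand * rf * h
        release = k_off * rb * h
        endo = k_endo * rb * h
        recycle = k_rec * ri * h
        rf += release + recycle - bind
        rb += bind - release - endo
        ri += endo - recycle
        consumed += bind - release
    for p, a, b, c in zip(pools, rf, rb, ri):
        p.r_free, p.r_bound, p.r_internalised = float(a), float(b), float(c)
    return consumed
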