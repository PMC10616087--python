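"""Dose-response curves, ICx inversion, and stochastic node inhibition.

Viability follows a two-parameter Hill sigmoid ``f(c) = 1/(1+(c/ec50)^h)``
(normalised: f(0)=1, monotone decreasing to 0).  The ICx concentration is
the closed-form inversion at viability ``1 - x/100``.  Drug coupling to a
Boolean model is stochastic: at the cell's local concentration ``[X]`` the
drug's target node is pinned OFF with probability ``1 - f([X])``, drawn
independently per cell and per regulatory update, so a population held at
the IC90 shows the target inhibited in 90% of the cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DoseResponseCurve", "DrugSpec", "viability", "icx", "fit_curve",
    "inhibition_probability", "apply_drug",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Normalised sigmoid viability curve with midpoint ``ec50`` (> 0,
    concentration units) and Hill slope ``hill_slope`` (> 0)."""

    ec50: float
    hill_slope: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill_slope <= 0:
            raise ValueError("ec50 and hill_slope must be > 0")

    def viability(self, conc: float) -> float:
        if conc < 0:
            raise ValueError("concentration must be >= 0")
        if conc == 0:
            return 1.0
        return 1.0 / (1.0 + (conc / self.ec50) ** self.hill_slope)

    def icx(self, x: float) -> float:
        """Concentration reducing viability by x percent (0 < x < 100)."""
        if not 0 < x < 100:
            raise ValueError("x must be in (0, 100)")
        frac = x / 100.0
        return self.ec50 * (frac / (1.0 - frac)) ** (1.0 / self.hill_slope)

    def inhibition_probability(self, conc: float) -> float:
        return 1.0 - self.viability(conc)


@dataclass(frozen=True)
class DrugSpec:
    """A drug: the substrate name it diffuses as, the Boolean node it
    inhibits, and its dose-response curve."""

    name: str
    target_node: str
    curve: DoseResponseCurve
    substrate: str | None = None

    @property
    def substrate_name(self) -> str:
        return self.substrate if self.substrate is not None else self.name


# -- functional wrappers ----------------------------------------------------

def viability(curve: DoseResponseCurve, conc: float) -> float:
    return curve.viability(conc)


def icx(curve: DoseResponseCurve, x: float) -> float:
    return curve.icx(x)


def inhibition_probability(curve: DoseResponseCurve, conc: float) -> float:
    return curve.inhibition_probability(conc)


def fit_curve(points: Sequence[tuple[float, float]]) -> DoseResponseCurve:
    """Least-squares Hill fit of (concentration, viability) pairs.

    Deterministic multi-start: ec50 seeded at each positive observed
    concentration and hill_slope over a fixed grid; parameters optimised in
    log space with scipy's trust-region least squares.
    """
    from scipy.optimize import least_squares

    pts = [(float(c), float(v)) for c, v in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 dose-response points")
    conc = np.array([c for c, _ in pts])
    viab = np.array([v for _, v in pts])
    if np.ptp(viab) < 1e-12:
        raise ValueError("degenerate dose-response data: viability is constant")
    positive = conc[conc > 0]
    if positive.size == 0:
        raise ValueError("need at least one positive concentration")

    def residuals(theta: np.ndarray) -> np.ndarray:
        ec50, h = np.exp(theta)
        with np.errstate(over="ignore"):
            pred = 1.0 / (1.0 + np.where(conc > 0, (conc / ec50), 0.0) ** h)
        pred = np.where(conc == 0, 1.0, pred)
        return pred - viab

    starts = [(e, h) for e in np.unique(positive) for h in (0.5, 1.0, 2.0, 4.0)]
    best = None
    for e0, h0 in starts:
        sol = least_squares(residuals, x0=np.log([e0, h0]), method="trf")
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    ec50, h = np.exp(best.x)
    return DoseResponseCurve(ec50=float(ec50), hill_slope=float(h))


def apply_drug(cell, drugs: Sequence[DrugSpec], grid, rng: np.random.Generator
               ) -> dict[str, bool]:
    """Draw this update's drug inhibitions for one cell.

    For each drug, a Bernoulli draw with p = 1 - f([X]) at the cell's
    nearest-voxel concentration; success pins the target node OFF for the
    coming regulatory interval.  Draws are independent across drugs, cells
    and updates.  Returns {node_name: False} pins.
    """
    pins: dict[str, bool] = {}
    for drug in drugs:
        conc = grid.concentration_for_cell(drug.substrate_name, cell)
        p = drug.curve.inhibition_probability(conc)
        if p > 0 and rng.random() < p:
            pins[drug.target_node] = False
    return pins
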