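"""Post-processing of simulation snapshots.

Growth curves (alive/dead counts over snapshot times), trapezoidal area
under the growth curve (AUC), the Growth Index GI = log2(AUC_treated /
AUC_untreated), Bliss-independence synergy scoring (reference effect
E_X + E_Y - E_X*E_Y and Combination Index CI = E_hat / E_observed, CI < 1
synergy, CI > 1 antagonism), concentric 50-µm spherical-layer decomposition
with per-layer growth/GI, POV-Ray scene export and plain-CSV data frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cell_agents import Phase

__all__ = [
    "SnapshotTable", "GrowthCurve", "growth_curve", "auc", "growth_index",
    "bliss_reference", "combination_index", "effect_from_growth",
    "layer_decompose", "per_layer_growth", "per_layer_gi",
    "povray_export", "to_csv", "read_csv", "plot_growth",
]

CELL_COLUMNS = ["time", "id", "x", "y", "z", "radius", "phase", "layer"]


@dataclass
class SnapshotTable:
    """Per-cell records over snapshot times, as one long data frame.

    Columns: time, id, x, y, z, radius, phase, layer, plus one column per
    declared Boolean output node.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"snapshot table lacks columns {missing}")
        times = self.times
        if len(times) > 1 and not (np.diff(times) > 0).all():
            raise ValueError("snapshot times must be strictly increasing")
        bad = set(self.frame["phase"].unique()) - set(Phase.ALL)
        if bad:
            raise ValueError(f"unknown phases {sorted(bad)}")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time"].unique())

    def at(self, time: float) -> pd.DataFrame:
        return self.frame[self.frame["time"] == time]

    @property
    def node_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in CELL_COLUMNS]


@dataclass
class GrowthCurve:
    """Alive (cycling) and dead (apoptotic + necrotic) counts per time."""

    times: np.ndarray
    alive: np.ndarray
    dead: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.alive = np.asarray(self.alive, dtype=float)
        if self.dead is None:
            self.dead = np.zeros_like(self.alive)
        self.dead = np.asarray(self.dead, dtype=float)
        if not (len(self.times) == len(self.alive) == len(self.dead)):
            raise ValueError("times/alive/dead lengths must match")
        if (self.alive < 0).any() or (self.dead < 0).any():
            raise ValueError("counts must be >= 0")


def growth_curve(snapshots: SnapshotTable) -> GrowthCurve:
    """Count alive (cycling) and dead (apoptotic/necrotic, removed excluded)
    cells at each snapshot time."""
    times = snapshots.times
    if len(times) == 0:
        raise ValueError("need at least one snapshot")
    alive, dead = [], []
    for t in times:
        frame = snapshots.at(t)
        alive.append(int((frame["phase"] == Phase.CYCLING).sum()))
        dead.append(int(frame["phase"].isin(Phase.DEAD).sum()))
    return GrowthCurve(times, alive, dead)


def auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the alive-count curve, in cells*min."""
    if len(curve.times) < 2:
        raise ValueError("AUC needs at least 2 time points")
    return float(np.trapezoid(curve.alive, curve.times))


def growth_index(auc_treated: float, auc_untreated: float) -> float:
    """GI = log2(AUC_treated / AUC_untreated); negative means growth
    reduction under treatment."""
    if auc_treated <= 0 or auc_untreated <= 0:
        raise ValueError("AUCs must be > 0")
    return math.log2(auc_treated / auc_untreated)


def bliss_reference(e_x: float, e_y: float) -> float:
    """Bliss independence reference effect E_X + E_Y - E_X*E_Y for two
    non-interacting drugs with single effects in [0, 1]."""
    if not (0.0 <= e_x <= 1.0 and 0.0 <= e_y <= 1.0):
        raise ValueError("single-drug effects must lie in [0, 1]")
    return e_x + e_y - e_x * e_y


def combination_index(e_hat: float, e_observed: float) -> float:
    """CI = predicted / observed combined effect; < 1 synergy, > 1 antagonism."""
    if e_observed <= 0:
        raise ValueError("observed combined effect must be > 0")
    return e_hat / e_observed


def effect_from_growth(auc_treated: float, auc_untreated: float) -> float:
    """Inhibition effect E = 1 - AUC_treated/AUC_untreated, clamped to [0,1]."""
    if auc_treated <= 0 or auc_untreated <= 0:
        raise ValueError("AUCs must be > 0")
    return min(1.0, max(0.0, 1.0 - auc_treated / auc_untreated))


# ---------------------------------------------------------------------------
# Spherical layers
# ---------------------------------------------------------------------------

def layer_decompose(positions: np.ndarray, centre: Sequence[float] = (0, 0, 0),
                    thickness: float = 50.0) -> np.ndarray:
    """Concentric-shell index per cell: layer k covers Euclidean distances
    [(k-1)*thickness, k*thickness) from the centre; layer 1 is innermost."""
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    dist = np.linalg.norm(pos - np.asarray(centre, dtype=float), axis=1)
    return (np.floor(dist / thickness) + 1).astype(int)


def per_layer_growth(snapshots: SnapshotTable, centre: Sequence[float] = (0, 0, 0),
                     thickness: float = 50.0) -> dict[int, GrowthCurve]:
    """Growth curve per spherical layer; membership is re-evaluated at every
    snapshot (cells may change layer as the spheroid grows)."""
    frame = snapshots.frame
    layers = layer_decompose(frame[["x", "y", "z"]].to_numpy(), centre, thickness)
    times = snapshots.times
    out: dict[int, GrowthCurve] = {}
    for layer in sorted(np.unique(layers)):
        sub = frame[layers == layer]
        alive = [int(((sub["time"] == t) & (sub["phase"] == Phase.CYCLING)).sum())
                 for t in times]
        dead = [int(((sub["time"] == t) & sub["phase"].isin(Phase.DEAD)).sum())
                for t in times]
        out[int(layer)] = GrowthCurve(times, alive, dead)
    return out


def per_layer_gi(treated: SnapshotTable, untreated: SnapshotTable,
                 centre: Sequence[float] = (0, 0, 0), thickness: float = 50.0
                 ) -> dict[int, float | None]:
    """Per-layer Growth Index; layers with zero AUC on either arm report
    ``None`` (missing, not an error)."""
    curves_t = per_layer_growth(treated, centre, thickness)
    curves_u = per_layer_growth(untreated, centre, thickness)
    out: dict[int, float | None] = {}
    for layer in sorted(set(curves_t) | set(curves_u)):
        try:
            a_t = auc(curves_t[layer]) if layer in curves_t else 0.0
            a_u = auc(curves_u[layer]) if layer in curves_u else 0.0
        except ValueError:
            a_t = a_u = 0.0
        out[layer] = growth_index(a_t, a_u) if a_t > 0 and a_u > 0 else None
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_PHASE_COLOURS = {
    Phase.CYCLING: (0.2, 0.4, 1.0),   # living cells: blue
    Phase.APOPTOTIC: (1.0, 0.15, 0.15),  # apoptotic: red
    Phase.NECROTIC: (0.45, 0.30, 0.15),
}


def povray_export(snapshot: pd.DataFrame, camera_distance: float = 400.0) -> str:
    """Render one snapshot's cells as a POV-Ray scene: one sphere per
    non-removed cell, coloured by phase (living blue, apoptotic red)."""
    cells = snapshot[snapshot["phase"] != Phase.REMOVED]
    if len(cells) == 0:
        raise ValueError("snapshot has no renderable cells")
    lines = [
        "// generated by hybridboss",
        "#version 3.7;",
        "global_settings { assumed_gamma 1.0 }",
        "background { color rgb <1,1,1> }",
        f"camera {{ location <{camera_distance:.1f}, {camera_distance:.1f}, "
        f"{camera_distance:.1f}> look_at <0, 0, 0> }}",
        f"light_source {{ <{camera_distance:.1f}, {2 * camera_distance:.1f}, "
        f"{camera_distance:.1f}> color rgb <1,1,1> }}",
    ]
    for row in cells.itertuples():
        r, g, b = _PHASE_COLOURS.get(row.phase, (0.5, 0.5, 0.5))
        lines.append(
            f"sphere {{ <{row.x:.3f}, {row.y:.3f}, {row.z:.3f}>, {row.radius:.3f} "
            f"pigment {{ color rgb <{r:.2f}, {g:.2f}, {b:.2f}> }} }}"
        )
    return "\n".join(lines) + "\n"


def to_csv(snapshots: SnapshotTable, out_dir: str | Path) -> tuple[Path, Path]:
    """Write cells.csv (long per-cell table) and counts.csv (growth curve);
    stable column order, round-trips through :func:`read_csv`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells_path = out / "cells.csv"
    counts_path = out / "counts.csv"
    cols = CELL_COLUMNS + snapshots.node_columns
    snapshots.frame[cols].to_csv(cells_path, index=False, float_format="%.10g")
    if len(snapshots.times) > 0:
        curve = growth_curve(snapshots)
        counts = pd.DataFrame({"time": curve.times, "alive": curve.alive.astype(int),
                               "dead": curve.dead.astype(int)})
    else:
        counts = pd.DataFrame(columns=["time", "alive", "dead"])
    counts.to_csv(counts_path, index=False, float_format="%.10g")
    return cells_path, counts_path


def read_csv(cells_path: str | Path) -> SnapshotTable:
    frame = pd.read_csv(cells_path)
    if len(frame) and frame["layer"].isna().all():
        frame["layer"] = ""
    frame["layer"] = frame["layer"].fillna("")
    return SnapshotTable(frame)


def plot_growth(curves: Mapping[str, GrowthCurve], path: str | Path) -> None:
    """Save an alive-count time-course plot (one line per labelled curve)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve.times, curve.alive, label=label)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("alive cells")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
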