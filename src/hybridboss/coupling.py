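"""Per-cell Boolean engine attachment and signal mapping.

This layer couples the continuous world (substrate concentrations,
internalised pools, receptor occupancy) to the Boolean input nodes through
transfer functions, and the Boolean output nodes back to agent behaviour
(apoptosis, necrosis, division-rate modulation).  Each cell carries its own
engine state and update schedule on the regulatory time scale: every
``time_step`` minutes (optionally jittered) the inputs are re-evaluated and
pinned, transient drug inhibitions are drawn, the network is advanced by
``time_step / scaling`` Boolean-time units, and the outputs are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boolean_engine import (
    BooleanNetwork, EngineSettings, InitialCondition, MutantSpec, NetworkState,
    apply_mutants, run_interval,
)
from .cell_agents import CellAgent
from .pharmacodynamics import DrugSpec, apply_drug

__all__ = [
    "step_transfer", "hill_transfer", "InputMapping", "OutputMapping",
    "IntracellularAttachment", "update_cell_intracellular", "apply_output_mapping",
]

SOURCES = ("voxel_concentration", "internalised_pool", "bound_receptor_fraction")
ACTIONS = ("trigger_apoptosis", "trigger_necrosis", "set_division_rate", "custom_flag")


def step_transfer(x: float, theta: float) -> int:
    """Step transfer function H(x): 1 when x >= theta (boundary inclusive),
    0 otherwise."""
    if x < 0:
        raise ValueError("signal must be >= 0")
    return 1 if x >= theta else 0


def hill_transfer(x: float, n: float, half_max: float) -> float:
    """Smooth transfer: occupancy-style saturation x^n / (x^n + half_max^n)."""
    if x < 0:
        raise ValueError("signal must be >= 0")
    if x == 0:
        return 0.0
    return x ** n / (x ** n + half_max ** n)


@dataclass(frozen=True)
class InputMapping:
    """Continuous signal -> Boolean input node.

    ``source`` is one of voxel_concentration / internalised_pool /
    bound_receptor_fraction (all parameterised by ``substrate``); the value
    is thresholded at ``theta`` with a step transfer by default, or mapped
    through a Hill function used as a Bernoulli pin probability when
    ``smoothing='hill'``.
    """

    source: str
    substrate: str
    target_node: str
    theta: float = 0.0
    smoothing: str = "step"
    hill_n: float = 2.0

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown input source {self.source!r}")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.smoothing not in ("step", "hill"):
            raise ValueError(f"unknown smoothing {self.smoothing!r}")

    def signal(self, cell: CellAgent, grid) -> float:
        if self.source == "voxel_concentration":
            return grid.concentration_for_cell(self.substrate, cell)
        if self.source == "internalised_pool":
            return cell.internalised.get(self.substrate, 0.0)
        pool = cell.receptors.get(self.substrate)
        if pool is None:
            raise KeyError(f"cell has no receptor pool for {self.substrate!r}")
        return pool.bound_fraction

    def transfer(self, x: float, rng: np.random.Generator) -> bool:
        if self.smoothing == "step":
            return bool(step_transfer(x, self.theta))
        return rng.random() < hill_transfer(x, self.hill_n, self.theta)


@dataclass(frozen=True)
class OutputMapping:
    """Boolean output node -> agent behaviour.

    ``set_division_rate`` multiplies the base division rate by ``multiplier``
    while the node is ON and restores it when OFF; death triggers are
    idempotent, and apoptosis takes precedence over necrosis when both fire
    in the same update.
    """

    source_node: str
    action: str
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown output action {self.action!r}")


@dataclass
class IntracellularAttachment:
    """The Boolean engine instance riding on one cell."""

    network: BooleanNetwork
    state: NetworkState
    settings: EngineSettings
    mutants: list[MutantSpec] = field(default_factory=list)
    input_mappings: list[InputMapping] = field(default_factory=list)
    output_mappings: list[OutputMapping] = field(default_factory=list)
    next_update_time: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    input_pins: dict[str, bool] = field(default_factory=dict)
    drug_pins: dict[str, bool] | None = None  # cached once in per-cell mode
    flags: set = field(default_factory=set)

    @classmethod
    def create(cls, network: BooleanNetwork, init: InitialCondition,
               settings: EngineSettings, rng: np.random.Generator,
               mutants: Sequence[MutantSpec] = (),
               input_mappings: Sequence[InputMapping] = (),
               output_mappings: Sequence[OutputMapping] = (),
               first_update_time: float | None = None) -> "IntracellularAttachment":
        for m in input_mappings:
            if m.target_node not in network.index:
                raise ValueError(f"input mapping targets unknown node {m.target_node!r}")
        for m in output_mappings:
            if m.source_node not in network.index:
                raise ValueError(f"output mapping reads unknown node {m.source_node!r}")
        state = NetworkState(init.sample(network, rng))
        apply_mutants(state, network, mutants)
        if first_update_time is None:
            # desynchronise the population: first update uniform in [0, time_step)
            first_update_time = float(rng.random() * settings.time_step)
        return cls(network=network, state=state, settings=settings,
                   mutants=list(mutants), input_mappings=list(input_mappings),
                   output_mappings=list(output_mappings),
                   next_update_time=first_update_time, rng=rng)

    def spawn_daughter(self) -> "IntracellularAttachment":
        """Daughter inherits the mother's Boolean state, with an independent
        child RNG stream and the same schedule."""
        child = IntracellularAttachment(
            network=self.network, state=self.state.copy(), settings=self.settings,
            mutants=list(self.mutants), input_mappings=list(self.input_mappings),
            output_mappings=list(self.output_mappings),
            next_update_time=self.next_update_time, rng=self.rng.spawn(1)[0],
            input_pins=dict(self.input_pins))
        return child

    def node_value(self, name: str) -> bool:
        return self.state.value(self.network, name)

    def output_values(self) -> dict[str, bool]:
        return {n: self.node_value(n) for n in self.network.output_nodes}


def update_cell_intracellular(cell: CellAgent, grid, drugs: Sequence[DrugSpec],
                              sim_time: float,
                              rng: np.random.Generator | None = None,
                              redraw_inhibition: bool = True) -> None:
    """One regulatory update of a cell's Boolean engine.

    Pins inputs from their mapped signals, draws transient drug inhibitions
    (re-drawn every update by default; with ``redraw_inhibition=False`` the
    first draw is cached for the cell's lifetime), advances the engine by
    ``time_step / scaling`` Boolean-time units with all pins held, applies
    the output mappings, and schedules the next update (lognormal jitter
    when ``time_stochasticity`` > 0).
    """
    att: IntracellularAttachment = cell.intracellular
    if att is None:
        return
    rng = rng if rng is not None else att.rng
    drugs = [d for d in drugs if d.target_node in att.network.index]

    pins: dict[str, bool] = {}
    for mapping in att.input_mappings:
        pins[mapping.target_node] = mapping.transfer(mapping.signal(cell, grid), rng)
    if redraw_inhibition or att.drug_pins is None:
        att.drug_pins = apply_drug(cell, drugs, grid, rng)
    pins.update(att.drug_pins)  # drug pins last one regulatory interval
    att.input_pins = pins

    transient = [MutantSpec(node, value) for node, value in pins.items()]
    all_pins = att.mutants + transient
    apply_mutants(att.state, att.network, all_pins)
    att.state = run_interval(att.network, att.state, all_pins,
                             att.settings.boolean_interval(), rng)
    apply_output_mapping(cell, att.output_values(), att.output_mappings)
    att.next_update_time = sim_time + att.settings.next_wall_interval(rng)


def apply_output_mapping(cell: CellAgent, node_values: dict[str, bool],
                         mappings: Sequence[OutputMapping]) -> None:
    """Apply output-node values to the agent (idempotent).

    Simultaneous death triggers resolve in favour of apoptosis.
    """
    apoptosis = any(m.action == "trigger_apoptosis" and node_values.get(m.source_node)
                    for m in mappings)
    necrosis = any(m.action == "trigger_necrosis" and node_values.get(m.source_node)
                   for m in mappings)
    if apoptosis:
        cell.start_apoptosis()
    elif necrosis:
        cell.start_necrosis()
    multiplier = 1.0
    for m in mappings:
        if m.action == "set_division_rate" and node_values.get(m.source_node):
            multiplier *= m.multiplier
    cell.division_multiplier = multiplier
    if cell.intracellular is not None:
        for m in mappings:
            if m.action == "custom_flag":
                if node_values.get(m.source_node):
                    cell.intracellular.flags.add(m.source_node)
                else:
                    cell.intracellular.flags.discard(m.source_node)
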