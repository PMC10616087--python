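"""XML simulation configuration and snapshot persistence.

The configuration mirrors the simulator's structure: a box domain, the four
time scales (diffusion <= mechanics <= cell <= regulatory), substrates with
optional Dirichlet supply, cell types with phenotype + an ``intracellular``
block (tags: bnd_filename, cfg_filename, time_step, scaling,
time_stochasticity, initial_values, mutants, parameters — defaults 12, 1, 0
and empty lists; the two file paths are required whenever the block is
present) plus input/output mappings and receptor parameters, drugs, a pulse
schedule and snapshot/replicate settings.

Snapshots are plain CSV (one cells table and one substrate-field table per
time point) beside a small XML manifest recording the config hash, seed and
snapshot times, so a finished run can be audited and re-read losslessly.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import CELL_COLUMNS, SnapshotTable
from .boolean_engine import (BooleanNetwork, EngineSettings, InitialCondition,
                             MutantSpec, parse_network)
from .coupling import InputMapping, OutputMapping
from .microenvironment import FACES, SubstrateSpec
from .pharmacodynamics import DoseResponseCurve, DrugSpec

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"

__all__ = [
    "IntracellularConfig", "ReceptorConfig", "CellTypeConfig", "PulseSpec",
    "SimulationConfig", "parse_config", "load_config", "config_hash",
    "write_snapshot", "read_snapshots", "write_manifest", "read_manifest",
    "run_simulation",
]


@dataclass
class IntracellularConfig:
    """The per-cell-type Boolean model block (tag-for-tag)."""

    bnd_filename: str
    cfg_filename: str
    time_step: float = 12.0
    scaling: float = 1.0
    time_stochasticity: float = 0.0
    initial_values: dict[str, float] = field(default_factory=dict)
    mutants: list[MutantSpec] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)
    input_mappings: list[InputMapping] = field(default_factory=list)
    output_mappings: list[OutputMapping] = field(default_factory=list)
    # resolved at load time
    network: BooleanNetwork | None = None
    initial_condition: InitialCondition | None = None

    def settings(self) -> EngineSettings:
        return EngineSettings(time_step=self.time_step, scaling=self.scaling,
                              time_stochasticity=self.time_stochasticity)

    def load_model(self, base_dir: Path) -> None:
        bnd = base_dir / self.bnd_filename
        cfg = base_dir / self.cfg_filename
        for p in (bnd, cfg):
            if not p.exists():
                raise FileNotFoundError(f"intracellular model file not found: {p}")
        self.network, self.initial_condition = parse_network(
            bnd.read_text(), cfg.read_text())
        for name, value in self.parameters.items():
            self.network.set_parameter(name, value)
        self.initial_condition.probabilities.update(self.initial_values)
        for m in self.mutants:
            if m.node not in self.network.index:
                raise ValueError(f"mutant references unknown node {m.node!r}")


@dataclass
class ReceptorConfig:
    """Per-cell-type receptor submodel for one substrate."""

    substrate: str
    receptors_per_cell: float
    k_on: float
    k_off: float = 0.0
    k_endo: float = 0.0
    k_recycle: float = 0.0


@dataclass
class CellTypeConfig:
    name: str = "default"
    cell_radius: float = 8.4
    division_rate: float = 0.0
    apoptosis_shrink_rate: float = 0.005
    apoptosis_duration: float = 480.0
    repulsion: float = 10.0
    adhesion: float = 0.4
    max_interaction_factor: float = 1.25
    drag: float = 1.0
    contact_inhibition_pressure: float = 0.0
    uptake_rate: dict[str, float] = field(default_factory=dict)
    secretion_rate: dict[str, float] = field(default_factory=dict)
    secretion_target: dict[str, float] = field(default_factory=dict)
    receptors: list[ReceptorConfig] = field(default_factory=list)
    intracellular: IntracellularConfig | None = None


@dataclass
class PulseSpec:
    """One boundary-supply episode: the substrate's Dirichlet walls hold
    ``value`` from ``start`` for ``duration`` minutes (0 outside pulses)."""

    substrate: str
    start: float
    duration: float
    value: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be > 0")

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration


@dataclass
class SimulationConfig:
    bounds: tuple[float, ...] = (-120.0, 120.0, -120.0, 120.0, -120.0, 120.0)
    dx: float = 20.0
    max_time: float = 1440.0
    dt_diffusion: float = 0.01
    dt_mechanics: float = 0.1
    dt_cells: float = 6.0
    snapshot_interval: float = 240.0
    substrates: list[SubstrateSpec] = field(default_factory=list)
    cell_types: list[CellTypeConfig] = field(default_factory=list)
    drugs: list[DrugSpec] = field(default_factory=list)
    pulses: list[PulseSpec] = field(default_factory=list)
    spheroid_radius: float = 0.0
    spheroid_cell_type: str = "default"
    replicates: int = 1
    seed: int = 0
    redraw_inhibition: str = "per_step"  # or "per_cell"

    def __post_init__(self) -> None:
        if not (self.dt_diffusion <= self.dt_mechanics <= self.dt_cells):
            raise ValueError("time scales must satisfy dt_diffusion <= dt_mechanics <= dt_cells")
        ratio = self.snapshot_interval / self.dt_cells
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("snapshot_interval must be a multiple of dt_cells")

    def cell_type(self, name: str) -> CellTypeConfig:
        for ct in self.cell_types:
            if ct.name == name:
                return ct
        raise KeyError(f"unknown cell type {name!r}")


# ---------------------------------------------------------------------------
# XML parsing
# ---------------------------------------------------------------------------

_KNOWN_INTRACELLULAR_TAGS = {
    "bnd_filename", "cfg_filename", "time_step", "scaling", "time_stochasticity",
    "initial_values", "mutants", "parameters", "mappings",
}


def _float(el: ET.Element | None, default: float) -> float:
    return default if el is None or el.text is None else float(el.text)


def parse_config(xml_text: str, base_dir: str | Path = ".") -> SimulationConfig:
    """Parse a configuration document; referenced BND/CFG files are resolved
    against ``base_dir`` and loaded immediately."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML configuration: {exc}") from exc
    base = Path(base_dir)

    domain = root.find("domain")
    if domain is not None:
        bounds = tuple(float(domain.get(k)) for k in
                       ("x_min", "x_max", "y_min", "y_max", "z_min", "z_max"))
        dx = float(domain.get("dx"))
    else:
        bounds, dx = SimulationConfig.bounds, SimulationConfig.dx

    overall = root.find("overall")
    kwargs = dict(bounds=bounds, dx=dx)
    if overall is not None:
        for attr, key in (("max_time", "max_time"), ("dt_diffusion", "dt_diffusion"),
                          ("dt_mechanics", "dt_mechanics"), ("dt_cells", "dt_cells"),
                          ("snapshot_interval", "snapshot_interval")):
            if overall.get(attr) is not None:
                kwargs[key] = float(overall.get(attr))

    substrates = []
    for sub in root.findall("substrates/substrate"):
        dirichlet = sub.find("dirichlet")
        value = None
        faces = FACES
        if dirichlet is not None and dirichlet.get("enabled", "true").lower() != "false":
            value = float(dirichlet.get("value"))
            if dirichlet.get("faces") and dirichlet.get("faces") != "all":
                faces = tuple(dirichlet.get("faces").split(","))
        substrates.append(SubstrateSpec(
            name=sub.get("name"),
            diffusion_coefficient=float(sub.get("diffusion_coefficient", 0.0)),
            decay_rate=float(sub.get("decay_rate", 0.0)),
            dirichlet_value=value, dirichlet_faces=faces))

    cell_types = [_parse_cell_type(el, base) for el in
                  root.findall("cell_definitions/cell_definition")]

    drugs = []
    for el in root.findall("drugs/drug"):
        curve = DoseResponseCurve(ec50=float(el.get("ec50")),
                                  hill_slope=float(el.get("hill_slope")))
        drugs.append(DrugSpec(name=el.get("name"), target_node=el.get("target_node"),
                              curve=curve, substrate=el.get("substrate")))

    pulses = [PulseSpec(substrate=el.get("substrate"), start=float(el.get("start")),
                        duration=float(el.get("duration")), value=float(el.get("value")))
              for el in root.findall("pulses/pulse")]

    spheroid = root.find("initial_conditions/spheroid")
    if spheroid is not None:
        kwargs["spheroid_radius"] = float(spheroid.get("radius"))
        kwargs["spheroid_cell_type"] = spheroid.get("cell_type", "default")

    options = root.find("options")
    if options is not None:
        if options.get("replicates"):
            kwargs["replicates"] = int(options.get("replicates"))
        if options.get("seed"):
            kwargs["seed"] = int(options.get("seed"))
        if options.get("redraw_inhibition"):
            kwargs["redraw_inhibition"] = options.get("redraw_inhibition")

    config = SimulationConfig(substrates=substrates, cell_types=cell_types,
                              drugs=drugs, pulses=pulses, **kwargs)
    _validate(config)
    return config


def load_config(path: str | Path) -> SimulationConfig:
    path = Path(path)
    return parse_config(path.read_text(), base_dir=path.parent)


def _parse_cell_type(el: ET.Element, base: Path) -> CellTypeConfig:
    ct = CellTypeConfig(name=el.get("name", "default"))
    phen = el.find("phenotype")
    if phen is not None:
        cycle = phen.find("cycle")
        if cycle is not None:
            ct.division_rate = float(cycle.get("division_rate", 0.0))
            ct.contact_inhibition_pressure = float(
                cycle.get("contact_inhibition_pressure", 0.0))
        death = phen.find("death")
        if death is not None:
            ct.apoptosis_shrink_rate = float(death.get("shrink_rate", ct.apoptosis_shrink_rate))
            ct.apoptosis_duration = float(death.get("duration", ct.apoptosis_duration))
        mech = phen.find("mechanics")
        if mech is not None:
            ct.cell_radius = float(mech.get("cell_radius", ct.cell_radius))
            ct.repulsion = float(mech.get("repulsion", ct.repulsion))
            ct.adhesion = float(mech.get("adhesion", ct.adhesion))
            ct.max_interaction_factor = float(
                mech.get("max_interaction_factor", ct.max_interaction_factor))
            ct.drag = float(mech.get("drag", ct.drag))
        for sec in phen.findall("secretion/substrate"):
            name = sec.get("name")
            ct.uptake_rate[name] = float(sec.get("uptake_rate", 0.0))
            ct.secretion_rate[name] = float(sec.get("secretion_rate", 0.0))
            ct.secretion_target[name] = float(sec.get("secretion_target", 0.0))
        for rec in phen.findall("receptor"):
            ct.receptors.append(ReceptorConfig(
                substrate=rec.get("substrate"),
                receptors_per_cell=float(rec.get("receptors_per_cell")),
                k_on=float(rec.get("k_on")), k_off=float(rec.get("k_off", 0.0)),
                k_endo=float(rec.get("k_endo", 0.0)),
                k_recycle=float(rec.get("k_recycle", 0.0))))
    intr = el.find("intracellular")
    if intr is not None:
        ct.intracellular = _parse_intracellular(intr, base)
    return ct


def _parse_intracellular(el: ET.Element, base: Path) -> IntracellularConfig:
    for child in el:
        if child.tag not in _KNOWN_INTRACELLULAR_TAGS:
            warnings.warn(f"unknown intracellular tag <{child.tag}> ignored", stacklevel=2)
    bnd = el.findtext("bnd_filename")
    cfg = el.findtext("cfg_filename")
    if not bnd or not cfg:
        raise ValueError("intracellular block requires bnd_filename and cfg_filename")
    conf = IntracellularConfig(
        bnd_filename=bnd.strip(), cfg_filename=cfg.strip(),
        time_step=_float(el.find("time_step"), 12.0),
        scaling=_float(el.find("scaling"), 1.0),
        time_stochasticity=_float(el.find("time_stochasticity"), 0.0))
    for iv in el.findall("initial_values/initial_value"):
        conf.initial_values[iv.get("node")] = float(iv.text)
    for mu in el.findall("mutants/mutant"):
        conf.mutants.append(MutantSpec(mu.get("node"), bool(int(mu.text))))
    for pa in el.findall("parameters/parameter"):
        conf.parameters[pa.get("name")] = float(pa.text)
    for im in el.findall("mappings/input"):
        conf.input_mappings.append(InputMapping(
            source=im.get("source"), substrate=im.get("substrate"),
            target_node=im.get("node"), theta=float(im.get("threshold", 0.0)),
            smoothing=im.get("smoothing", "step"),
            hill_n=float(im.get("hill_n", 2.0))))
    for om in el.findall("mappings/output"):
        conf.output_mappings.append(OutputMapping(
            source_node=om.get("node"), action=om.get("action"),
            multiplier=float(om.get("multiplier", 1.0))))
    conf.load_model(base)
    return conf


def _validate(config: SimulationConfig) -> None:
    substrate_names = {s.name for s in config.substrates}
    for drug in config.drugs:
        if drug.substrate_name not in substrate_names:
            raise ValueError(f"drug {drug.name!r} references unknown substrate "
                             f"{drug.substrate_name!r}")
    for pulse in config.pulses:
        if pulse.substrate not in substrate_names:
            raise ValueError(f"pulse references unknown substrate {pulse.substrate!r}")
    for ct in config.cell_types:
        if ct.intracellular is None:
            continue
        network = ct.intracellular.network
        for m in ct.intracellular.input_mappings:
            if m.target_node not in network.index:
                raise ValueError(f"cell type {ct.name!r}: input mapping targets "
                                 f"unknown node {m.target_node!r}")
            if m.substrate not in substrate_names:
                raise ValueError(f"cell type {ct.name!r}: input mapping references "
                                 f"unknown substrate {m.substrate!r}")
        for m in ct.intracellular.output_mappings:
            if m.source_node not in network.index:
                raise ValueError(f"cell type {ct.name!r}: output mapping reads "
                                 f"unknown node {m.source_node!r}")


def config_hash(config: SimulationConfig) -> str:
    """Stable content hash of a configuration (used in run manifests);
    canonicalises nested structures so equal configs hash equally across
    processes."""
    return hashlib.sha256(_canonical(config).encode()).hexdigest()[:16]


def _canonical(obj) -> str:
    import dataclasses

    from .boolean_engine import BooleanNetwork, serialize_network

    if isinstance(obj, BooleanNetwork):
        bnd, cfg = serialize_network(obj)
        return bnd + cfg
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        parts = [f"{f.name}={_canonical(getattr(obj, f.name))}"
                 for f in dataclasses.fields(obj)]
        return f"{type(obj).__name__}({','.join(parts)})"
    if isinstance(obj, dict):
        return "{" + ",".join(f"{k!r}:{_canonical(v)}"
                              for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))) + "}"
    if isinstance(obj, (list, tuple)):
        return "[" + ",".join(_canonical(v) for v in obj) + "]"
    if isinstance(obj, (frozenset, set)):
        return "{" + ",".join(sorted(repr(v) for v in obj)) + "}"
    return repr(obj)


# ---------------------------------------------------------------------------
# Snapshot persistence
# ---------------------------------------------------------------------------

def write_snapshot(out_dir: str | Path, index: int, time: float, cells,
                   grid, output_nodes: list[str] | None = None) -> Path:
    """Write one snapshot: cells_<k>.csv (per-cell records) and
    fields_<k>.csv (per-voxel concentrations)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    output_nodes = output_nodes or []
    records = []
    for cell in cells:
        if cell.phase == "removed":
            continue
        rec = {"time": time, "id": cell.id, "x": cell.position[0],
               "y": cell.position[1], "z": cell.position[2],
               "radius": cell.radius, "phase": cell.phase, "layer": ""}
        for node in output_nodes:
            rec[node] = (int(cell.intracellular.node_value(node))
                         if cell.intracellular is not None else "")
        records.append(rec)
    frame = pd.DataFrame(records, columns=CELL_COLUMNS + output_nodes)
    cells_path = out / f"cells_{index:05d}.csv"
    frame.to_csv(cells_path, index=False, float_format="%.10g")

    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(range(nx), range(ny), range(nz), indexing="ij")
    fields = {"i": ii.ravel(), "j": jj.ravel(), "k": kk.ravel(),
              "x": grid.voxel_centers(0)[ii.ravel()],
              "y": grid.voxel_centers(1)[jj.ravel()],
              "z": grid.voxel_centers(2)[kk.ravel()]}
    for name, rho in grid.fields.items():
        fields[name] = rho.ravel()
    pd.DataFrame(fields).to_csv(out / f"fields_{index:05d}.csv", index=False,
                                float_format="%.10g")
    return cells_path


def write_manifest(out_dir: str | Path, config: SimulationConfig, seed: int,
                   times: list[float]) -> Path:
    root = ET.Element("manifest", version=FORMAT_VERSION)
    ET.SubElement(root, "config_hash").text = config_hash(config)
    ET.SubElement(root, "seed").text = str(seed)
    ET.SubElement(root, "snapshot_times").text = " ".join(f"{t:g}" for t in times)
    path = Path(out_dir) / "manifest.xml"
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
    return path


def read_manifest(out_dir: str | Path) -> dict:
    path = Path(out_dir) / "manifest.xml"
    root = ET.parse(path).getroot()
    if root.get("version") != FORMAT_VERSION:
        raise ValueError(f"snapshot format version mismatch: "
                         f"found {root.get('version')!r}, expected {FORMAT_VERSION!r}")
    times_text = root.findtext("snapshot_times") or ""
    return {"config_hash": root.findtext("config_hash"),
            "seed": int(root.findtext("seed")),
            "snapshot_times": [float(t) for t in times_text.split()]}


def read_snapshots(out_dir: str | Path) -> SnapshotTable:
    """Read all cells_*.csv of a run directory into one SnapshotTable."""
    out = Path(out_dir)
    paths = sorted(out.glob("cells_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no snapshots in {out}")
    frames = [pd.read_csv(p) for p in paths]
    frame = pd.concat(frames, ignore_index=True)
    if "layer" in frame.columns:
        frame["layer"] = frame["layer"].fillna("")
    return SnapshotTable(frame)


def run_simulation(config: SimulationConfig, seed: int | None = None,
                   out_dir: str | Path | None = None):
    """Run the hybrid simulation for this configuration (see
    :mod:`hybridboss.simulation`)."""
    from .simulation import run_simulation as _run
    return _run(config, seed=seed, out_dir=out_dir)
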