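"""Packaged toy models, scenario generators and synthetic data.

Everything here is repo-authored and deliberately small enough to solve by
hand; the published 31-node cell-fate and 133-node prostate networks load
through the same dialect but are not shipped.

* :func:`make_cascade_model` — a 3-node Input -> Mediator -> Death relay
  whose pinned-input dynamics is a two-stage Erlang process in closed form.
* :func:`make_fate_model` — a 9-node cell-fate network with a TNF input and
  three mutually exclusive absorbing output classes (Survival, Apoptosis,
  NonACD), a stress pathway gated by an anti-apoptotic mediator (IAP, the
  drug target in the screening scenarios) and a mitochondrial branch that
  takes over when caspase signalling is blocked.
* TNF-pulse scenarios matching the six classic regimes (no TNF; one 600-min
  pulse; 600-min + stronger 840-min pulse; continuous 1440 min; 10-min
  pulses every 150 min; 10-min pulses every 600 min).
* A drug-screen scenario: spheroid with drug supplied at all six walls at a
  chosen ICx of a synthetic sigmoid curve, targeting IAP.
* Synthetic dose-response point sets for curve-fitting tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boolean_engine import BooleanNetwork, InitialCondition, parse_network
from .config_io import (CellTypeConfig, IntracellularConfig, PulseSpec,
                        ReceptorConfig, SimulationConfig)
from .coupling import InputMapping, OutputMapping
from .microenvironment import SubstrateSpec
from .pharmacodynamics import DoseResponseCurve, DrugSpec

__all__ = [
    "make_cascade_model", "cascade_initial_condition", "make_fate_model",
    "fate_initial_condition", "ScenarioSpec", "make_tnf_scenarios",
    "scenario_config", "drug_screen_config", "make_synthetic_doseresponse",
    "DRUG_TARGET_PAIRS", "CASCADE_BND", "CASCADE_CFG", "FATE_BND", "FATE_CFG",
]

# ---------------------------------------------------------------------------
# Boolean model fixtures (dialect text is the source of truth; the builders
# parse it, so every fixture exercises the parser round-trip path)
# ---------------------------------------------------------------------------

CASCADE_BND = """\
// 3-node relay: Input -> Mediator -> Death (absorbing)
node Input {
  logic = Input;
  rate_up = 0;
  rate_down = 0;
}
node Mediator {
  logic = Input;
  rate_up = @logic ? $k1 : 0;
  rate_down = @logic ? 0 : $k1;
}
node Death {
  logic = Mediator;
  rate_up = @logic ? $k2 : 0;
  rate_down = 0;
}
"""

CASCADE_CFG = """\
$k1 = 1.0;
$k2 = 1.0;
Input.istate = 0;
Mediator.istate = 0;
Death.istate = 0;
Input.is_internal = TRUE;
Death.is_internal = FALSE;
"""


def make_cascade_model() -> BooleanNetwork:
    """3-node cascade with unit rates; with Input pinned ON the Death node
    activates as a two-stage Erlang process: P(Death ON at t) =
    1 - e^{-t} - t e^{-t}."""
    network, _ = parse_network(CASCADE_BND, CASCADE_CFG)
    return network


def cascade_initial_condition() -> InitialCondition:
    return InitialCondition({"Input": 0.0, "Mediator": 0.0, "Death": 0.0})


FATE_BND = """\
// 9-node cell-fate network: TNF input, stress pathway gated by IAP,
// mitochondrial (MPT) branch, three mutually exclusive absorbing outputs.
node TNF {
  logic = TNF;
  rate_up = 0;
  rate_down = 0;
}
node Stress {
  logic = Stress;
  rate_up = $k_stress;
  rate_down = $k_destress;
}
node IAP {
  logic = NOT Casp3;
  rate_up = @logic ? $k_iap : 0;
  rate_down = @logic ? 0 : $k_iap;
}
node Casp8 {
  logic = TNF OR (Stress AND NOT IAP);
  rate_up = @logic ? $k_sig : 0;
  rate_down = @logic ? 0 : $k_rev;
}
node Casp3 {
  logic = Casp8;
  rate_up = @logic ? $k_sig : 0;
  rate_down = @logic ? 0 : $k_rev;
}
node MPT {
  logic = TNF AND NOT Casp8;
  rate_up = @logic ? $k_mpt : 0;
  rate_down = @logic ? 0 : $k_mpt;
}
node Apoptosis {
  logic = Casp3 AND NOT NonACD;
  rate_up = @logic ? $k_fate : 0;
  rate_down = 0;
}
node NonACD {
  logic = MPT AND NOT Apoptosis AND NOT Casp3;
  rate_up = @logic ? $k_nonacd : 0;
  rate_down = 0;
}
node Survival {
  logic = NOT Apoptosis AND NOT NonACD;
  rate_up = @logic ? $k_fate : 0;
  rate_down = @logic ? 0 : $k_fate;
}
"""

FATE_CFG = """\
$k_stress = 0.01;
$k_destress = 0.03;
$k_iap = 0.2;
$k_sig = 0.015;
$k_rev = 0.1;
$k_mpt = 0.0015;
$k_nonacd = 0.05;
$k_fate = 0.1;
TNF.istate = 0;
Stress.istate = 0;
IAP.istate = 1;
Casp8.istate = 0;
Casp3.istate = 0;
MPT.istate = 0;
Apoptosis.istate = 0;
NonACD.istate = 0;
Survival.istate = 1;
Survival.is_internal = FALSE;
Apoptosis.is_internal = FALSE;
NonACD.is_internal = FALSE;
"""


def make_fate_model() -> BooleanNetwork:
    network, _ = parse_network(FATE_BND, FATE_CFG)
    return network


def fate_initial_condition() -> InitialCondition:
    _, init = parse_network(FATE_BND, FATE_CFG)
    return init


# Drug -> target-node metadata of the published prostate screen (names only;
# the dose-response curves used here are synthetic).
DRUG_TARGET_PAIRS = (
    ("Ipatasertib", "AKT"),
    ("Afatinib", "EGFR"),
    ("Ulixertinib", "ERK"),
    ("Luminespib", "HSPs"),
    ("Selumetinib", "MEK1_2"),
    ("Pictilisib", "PI3K"),
)


# ---------------------------------------------------------------------------
# Scenario generators
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """One in-silico experiment layout: initial spheroid, pulse schedule,
    horizon."""

    name: str
    description: str
    spheroid_radius: float = 60.0
    horizon: float = 1440.0
    pulses: list[PulseSpec] = field(default_factory=list)


def make_tnf_scenarios(spheroid_radius: float = 60.0) -> list[ScenarioSpec]:
    """The six TNF-pulse regimes (0.5 ng/mL working concentration)."""
    c = 0.5

    def pulses(entries):
        return [PulseSpec("tnf", start, duration, value)
                for start, duration, value in entries]

    horizon = 1440.0
    return [
        ScenarioSpec("a_no_tnf", "no TNF added", spheroid_radius, horizon, []),
        ScenarioSpec("b_single_pulse", "single 0.5 pulse for 600 min",
                     spheroid_radius, horizon, pulses([(0, 600, c)])),
        ScenarioSpec("c_two_pulses",
                     "600-min pulse then a 10x-stronger 840-min pulse",
                     spheroid_radius, horizon, pulses([(0, 600, c), (600, 840, 10 * c)])),
        ScenarioSpec("d_continuous", "continuous exposure for 1440 min",
                     spheroid_radius, horizon, pulses([(0, 1440, c)])),
        ScenarioSpec("e_pulses_150", "10-min pulses at 150-min intervals",
                     spheroid_radius, horizon,
                     pulses([(start, 10, c) for start in np.arange(0, horizon, 150.0)])),
        ScenarioSpec("f_pulses_600", "10-min pulses at 600-min intervals",
                     spheroid_radius, horizon,
                     pulses([(start, 10, c) for start in np.arange(0, horizon, 600.0)])),
    ]


def _fate_intracellular(theta: float = 0.5) -> IntracellularConfig:
    conf = IntracellularConfig(
        bnd_filename="<builtin:fate>", cfg_filename="<builtin:fate>",
        input_mappings=[InputMapping("bound_receptor_fraction", "tnf", "TNF",
                                     theta=theta)],
        output_mappings=[OutputMapping("Apoptosis", "trigger_apoptosis"),
                         OutputMapping("NonACD", "trigger_necrosis")])
    conf.network, conf.initial_condition = parse_network(FATE_BND, FATE_CFG)
    return conf


def _fate_cell_type(contact_inhibition_pressure: float = 0.0) -> CellTypeConfig:
    return CellTypeConfig(
        name="default", cell_radius=8.4, division_rate=5e-4,
        apoptosis_shrink_rate=0.005, apoptosis_duration=480.0,
        contact_inhibition_pressure=contact_inhibition_pressure,
        receptors=[ReceptorConfig(substrate="tnf", receptors_per_cell=200.0,
                                  k_on=5.0, k_off=0.05, k_endo=0.05,
                                  k_recycle=0.01)],
        intracellular=_fate_intracellular())


def scenario_config(scenario: ScenarioSpec, seed: int = 0) -> SimulationConfig:
    """Full simulation configuration for one TNF-pulse regime.

    Desk-scale study conditions: 240-µm box at 20-µm voxels, ~270-cell
    spheroid (radius 60 µm, cell radius 8.4 µm), TNF diffusing fast
    (6000 µm²/min) with a 0.05/min wash-out decay, receptor-mediated input
    at half-occupancy threshold, snapshots every 240 min.
    """
    return SimulationConfig(
        bounds=(-120, 120, -120, 120, -120, 120), dx=20.0,
        max_time=scenario.horizon, dt_diffusion=0.5, dt_mechanics=3.0,
        dt_cells=6.0, snapshot_interval=240.0,
        substrates=[SubstrateSpec("tnf", diffusion_coefficient=6000.0,
                                  decay_rate=0.05)],
        cell_types=[_fate_cell_type()],
        pulses=list(scenario.pulses),
        spheroid_radius=scenario.spheroid_radius,
        seed=seed)


def drug_screen_config(icx_level: float = 90.0, spheroid_radius: float = 60.0,
                       horizon: float = 1440.0, seed: int = 0,
                       with_drug: bool = True) -> SimulationConfig:
    """Drug screen layout: a synthetic sigmoid drug (ec50 = 1, slope = 2)
    targeting the anti-apoptotic IAP node, supplied at the chosen ICx
    concentration from all six box walls; slow diffusion (100 µm²/min) and
    first-order cellular uptake (0.3/min) confine it to the outer spheroid
    layers.  Contact inhibition is enabled so space freed by dying boundary
    cells feeds back into inner-layer proliferation."""
    curve = DoseResponseCurve(ec50=1.0, hill_slope=2.0)
    conc = curve.icx(icx_level) if with_drug else 0.0
    # threshold calibrated to the measured overlap-pressure scale of a packed
    # spheroid (interior ~0.026, rim ~0.004): interior division roughly
    # halved by compression, rim cells nearly uninhibited
    ct = _fate_cell_type(contact_inhibition_pressure=0.05)
    # uptake sets the penetration depth delta = sqrt(D / (V_c/V_vox * U * n));
    # 0.7/min gives delta ~ 14 µm, i.e. <1% central transmission for a
    # 100-µm spheroid (spherical screening (R/delta)/sinh(R/delta))
    ct.uptake_rate["drug"] = 0.7
    return SimulationConfig(
        bounds=(-120, 120, -120, 120, -120, 120), dx=20.0,
        max_time=horizon, dt_diffusion=0.5, dt_mechanics=3.0, dt_cells=6.0,
        snapshot_interval=240.0,
        substrates=[
            SubstrateSpec("tnf", diffusion_coefficient=6000.0, decay_rate=0.05),
            SubstrateSpec("drug", diffusion_coefficient=100.0, decay_rate=0.0,
                          dirichlet_value=(conc if with_drug else None)),
        ],
        cell_types=[ct],
        drugs=[DrugSpec(name="drug", target_node="IAP", curve=curve)],
        spheroid_radius=spheroid_radius,
        seed=seed)


def list_fixture_names() -> list[str]:
    return [s.name for s in make_tnf_scenarios()] + ["drug_screen"]


def emit_scenario(name: str, out_dir) -> "Path":
    """Write a ready-to-run config (XML + BND/CFG model files) for a named
    scenario; returns the config path."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fate.bnd").write_text(FATE_BND)
    (out / "fate.cfg").write_text(FATE_CFG)
    (out / "drug_targets.csv").write_text(
        "drug,target_node\n" +
        "".join(f"{drug},{node}\n" for drug, node in DRUG_TARGET_PAIRS))

    if name == "drug_screen":
        config = drug_screen_config()
        pulses_xml = ""
        drug_substrate = ('    <substrate name="drug" diffusion_coefficient="100"'
                          ' decay_rate="0">\n'
                          f'      <dirichlet value="{config.substrates[1].dirichlet_value:g}"/>\n'
                          '    </substrate>\n')
        drugs_xml = ('  <drugs>\n    <drug name="drug" target_node="IAP" '
                     'ec50="1.0" hill_slope="2.0"/>\n  </drugs>\n')
        uptake_xml = ('        <substrate name="drug" uptake_rate="0.3"/>\n')
        ci = 'contact_inhibition_pressure="0.05"'
        horizon = config.max_time
        radius = config.spheroid_radius
    else:
        matches = [s for s in make_tnf_scenarios() if s.name == name]
        if not matches:
            raise KeyError(f"unknown fixture scenario {name!r}; "
                           f"choose from {list_fixture_names()}")
        scenario = matches[0]
        entries = "".join(
            f'    <pulse substrate="tnf" start="{p.start:g}" '
            f'duration="{p.duration:g}" value="{p.value:g}"/>\n'
            for p in scenario.pulses)
        pulses_xml = f"  <pulses>\n{entries}  </pulses>\n" if entries else ""
        drug_substrate = ""
        drugs_xml = ""
        uptake_xml = ""
        ci = ""
        horizon = scenario.horizon
        radius = scenario.spheroid_radius

    xml = f"""<simulation>
  <domain x_min="-120" x_max="120" y_min="-120" y_max="120" z_min="-120" z_max="120" dx="20"/>
  <overall max_time="{horizon:g}" dt_diffusion="0.5" dt_mechanics="3" dt_cells="6" snapshot_interval="240"/>
  <substrates>
    <substrate name="tnf" diffusion_coefficient="6000" decay_rate="0.05"/>
{drug_substrate}  </substrates>
  <cell_definitions>
    <cell_definition name="default">
      <phenotype>
        <cycle division_rate="0.0005" {ci}/>
        <death shrink_rate="0.005" duration="480"/>
        <mechanics cell_radius="8.4"/>
        <secretion>
{uptake_xml}        </secretion>
        <receptor substrate="tnf" receptors_per_cell="200" k_on="5" k_off="0.05" k_endo="0.05" k_recycle="0.01"/>
      </phenotype>
      <intracellular>
        <bnd_filename>fate.bnd</bnd_filename>
        <cfg_filename>fate.cfg</cfg_filename>
        <mappings>
          <input source="bound_receptor_fraction" substrate="tnf" node="TNF" threshold="0.5"/>
          <output node="Apoptosis" action="trigger_apoptosis"/>
          <output node="NonACD" action="trigger_necrosis"/>
        </mappings>
      </intracellular>
    </cell_definition>
  </cell_definitions>
  <initial_conditions>
    <spheroid radius="{radius:g}" cell_type="default"/>
  </initial_conditions>
{drugs_xml}{pulses_xml}</simulation>
"""
    config_path = out / f"{name}.xml"
    config_path.write_text(xml)
    return config_path


def make_synthetic_doseresponse(ec50: float = 1.0, hill_slope: float = 2.0,
                                n_points: int = 9, noise_sd: float = 0.0,
                                seed: int = 0):
    """Log-spaced (concentration, viability) points from a Hill curve with
    optional clipped Gaussian noise; returns (points, true_curve)."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    curve = DoseResponseCurve(ec50=ec50, hill_slope=hill_slope)
    conc = ec50 * np.logspace(-2, 2, n_points)
    rng = np.random.default_rng(seed)
    viab = np.array([curve.viability(c) for c in conc])
    if noise_sd > 0:
        viab = np.clip(viab + rng.normal(0.0, noise_sd, n_points), 0.0, 1.0)
    return list(zip(conc.tolist(), viab.tolist())), curve
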