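# Methods

`hybridboss` simulates multicellular systems in which every cell agent
carries its own stochastic Boolean signalling network, the population lives
in a diffusive chemical microenvironment, and the two worlds exchange
signals through explicit transfer rules. This note describes the models,
their assumptions, the defaults and the numerical choices, and what the
packaged synthetic scenarios do and do not demonstrate.

## The intracellular model: continuous-time stochastic Boolean networks

A Boolean network assigns every node a logic expression over other nodes
plus two nonnegative rate expressions: `rate_up` (the 0→1 flip rate) and
`rate_down` (1→0), both in units of 1/Boolean-time. The network state is a
bit vector evolving as a continuous-time Markov chain: in a given state,
each node whose current value disagrees with where its rate expression
pushes it is "unstable" and flips after an exponential waiting time;
trajectories are sampled with the Gillespie algorithm (total propensity R,
dwell −ln(u)/R, one node chosen proportionally to its rate). Exactly one
node flips per event; simultaneous flips are excluded by construction.
States with R = 0 are absorbing. Ensemble node-activation probabilities are
estimated over many trajectories, optionally mixing sub-populations with
different forced-node ("mutant") sets, allocated by largest-remainder
rounding of the mixture weights.

Networks are read from a restricted text dialect (`node N { logic = …;
rate_up = …; rate_down = …; }` plus a configuration file with `$param`
constants, `N.istate` initial probabilities and `N.is_internal` flags).
The rate grammar supports the ternary `cond ? a : b`, the `@logic` alias
for the node's own logic value, parameters, and +, −, ×, /. Nodes whose
two rates are the literal 0 are treated as input nodes (they only move when
the coupling layer pins them); nodes declared `is_internal = FALSE` are the
outputs. Unlisted initial probabilities default to 0.5.

Timing relative to the agent-based clock: each cell's engine is advanced
every `time_step` minutes (default 12) by `time_step / scaling` Boolean-time
units, i.e. `scaling` > 1 slows the intracellular clock relative to
simulation minutes. With `time_stochasticity` σ > 0 the wall interval is
jittered lognormally, `time_step · exp(σZ − σ²/2)`, which preserves the mean
interval; σ = 0 recovers the strict schedule. Each cell's first update time
is drawn uniformly in [0, time_step) to avoid population-wide
synchronisation artefacts.

## The microenvironment

The domain is a 3D box of cubic voxels (edge `dx`). Per substrate the field
obeys diffusion + first-order decay with either no-flux walls or Dirichlet
walls held at a supply concentration. One step applies, in fixed x, y, z
order, an implicit (unconditionally stable) locally-one-dimensional solve —
a constant-coefficient tridiagonal (Thomas) sweep per axis, vectorised over
the orthogonal columns — then the implicit decay update ρ ← ρ/(1 + λΔt).
Dirichlet values are re-imposed after every sweep; this affects the boundary
layer at O(Δt) and is the documented convention. The implicit decay update
makes total mass decay exactly as M₀/(1+λΔt)ⁿ, which the tests use as a
closed form.

Cells interact with the field only at the voxel nearest their centre (ties
break to the lower index; positions outside the box are clamped with a
warning). Secretion toward a target concentration ρ\* and first-order
uptake are applied per cell with the implicit update
ρ ← (ρ + Δt·(V_c/V_vox)·S·ρ\*) / (1 + Δt·(V_c/V_vox)·(U+S)); the mass
removed by uptake, Δt·V_c·U·ρ_new, is booked into the cell's internalised
pool, making the voxel + pool budget exact by construction. Cells sharing a
voxel are processed sequentially in population order; the simulation's
vectorised fast path reproduces the sequential bookkeeping exactly via a
segmented cumulative product (it is only taken when no substrate is
secreted). Dying and removed cells stop exchanging by default.

## Cell agents

Cells are spheres with phase ∈ {cycling, apoptotic, necrotic, removed}.
Mechanics is the standard overdamped pairwise-potential picture: repulsion
c_r(1 − d/R_sum)² inside the radii sum, adhesion −c_a(1 − d/R_max)² out to
`max_interaction_factor` times the radii sum, forces summed symmetrically
(Newton's third law) and integrated with forward Euler; neighbour search
uses a k-d tree. The summed squared-overlap per cell is recorded as a
scalar "pressure".

The cycle is a single-rate stochastic division model: probability
rate·Δt_cell per step (clamped at 1); on division mother and daughter take
half the mother's volume and the daughter is displaced one radius in a
uniform random direction, inheriting the exchange rates, receptor pools and
the mother's current Boolean state (with an independent RNG stream). This
is deliberately simpler than multi-phase cycle models; versions of this
architecture are known to differ in exactly this component, and ours is
documented as its own variant. Optional contact inhibition multiplies the
division rate by max(0, 1 − pressure/p_max); it is off (p_max = 0) unless a
scenario enables it. Dying cells shrink exponentially
(V(t) = V₀e^(−k·t), default k = 0.005/min) and are removed after a fixed
residence (default 480 min). Spheroids are initialised on a hexagonal
close packing with spacing 2·cell radius (default radius 8.4 µm).

## Receptor kinetics

Ligand binding uses a three-pool surface-trafficking model per cell —
free, bound, internalised — with mass-action binding k_on·L·R_f, release
k_off·R_b, internalisation k_endo·R_b and recycling k_recycle·R_i, 1:1
ligand:receptor stoichiometry (receptor pools are expressed directly in
ligand mass units). The net bound ligand is withdrawn from the cell's
voxel; ligand on recycled receptors is degraded. Setting
k_endo = k_recycle = 0 recovers plain reversible surface binding.
Integration is explicit Euler with automatic sub-stepping (sub-step chosen
so the fastest rate × h ≤ 0.2), which keeps pools nonnegative and conserves
receptor number to 1e−9 relative. The bound fraction R_b/R_total is the
quantity exposed to the Boolean input mapping.

## Pharmacodynamic coupling

Viability is the two-parameter Hill sigmoid f(c) = 1/(1 + (c/ec50)^h),
normalised (f(0) = 1, monotone to 0); ICx inverts it in closed form.
`fit_curve` is a deterministic multi-start least-squares fit in log
parameters (starts at each observed concentration × slope grid
{0.5, 1, 2, 4}); it replaces multi-level plate-effect fitting, which needs
raw screening data, while preserving the curve contract. Drug action on
the signalling model is stochastic: at each regulatory update, each drug
pins its target node OFF with probability 1 − f([X]) at the cell's
nearest-voxel concentration, independently across drugs, cells and updates
(a config switch freezes the draw per cell lifetime instead). Thus a
population held at the IC90 shows the target inhibited in 90% of cells.
Concentrations and ICx are in the same arbitrary units as the substrate
field; instantaneous (not time-averaged) concentrations are used.

## Signal mappings

Inputs: a mapping takes a source — nearest-voxel concentration,
internalised pool, or bound receptor fraction — and pins the target input
node to H(x) = 1 iff x ≥ θ (boundary inclusive); a Hill-smoothed variant
pins stochastically with probability x^n/(x^n + θ^n). Pins hold between
updates. Outputs: a node can trigger apoptosis (idempotent), trigger
necrosis, scale the division rate while ON, or set a custom flag;
simultaneous death triggers resolve in favour of apoptosis.

## The main loop and reproducibility

Time advances in diffusion ticks; per tick: boundary pulses → diffusion +
decay (Dirichlet re-imposed) → secretion/uptake and receptor kinetics →
mechanics (every Δt_mec) → cycle/death (every Δt_cell) → per-cell Boolean
updates at each cell's own schedule. The hierarchy Δt_diff ≤ Δt_mec ≤
Δt_cell is enforced at configuration time; snapshot times must align with
Δt_cell. Substrates with a pulse schedule have their walls held at the
pulse value during a pulse and at zero outside it (wash-out); without the
wash-out convention, pulse regimes would be indistinguishable from
continuous exposure once the box filled. A master seed spawns one world
stream and one stream per cell (daughters branch off their mother), so runs
are byte-reproducible from (config, seed); replicate k uses the
deterministic child seed (seed, k). Snapshots are plain CSV (cells and
fields) beside an XML manifest carrying a canonical config hash.

## Packaged scenarios: what they emulate

The fixture models are repo-authored, hand-solvable stand-ins — the
published 31-node cell-fate and 133-node prostate networks are not shipped,
though they load through the dialect. The 3-node cascade
(Input→Mediator→Death) has a two-stage Erlang closed form under a pinned
input and is the engine's quantitative oracle. The 9-node fate network has
a TNF input, a caspase cascade, a mitochondrial branch that takes over when
caspase signalling is blocked, and three mutually exclusive absorbing
outputs (Survival, Apoptosis, NonACD); an anti-apoptotic node (IAP) gates a
low-level stress pathway and serves as the drug target in the screening
scenarios.

Scenario defaults (chosen from timescale arguments, not fitted to any
published curve): 240-µm box at 20-µm voxels; spheroid radius 60 µm
(~270 cells) for cytokine-pulse studies and 100 µm (~1230 cells) for the
drug screen; division rate 5e−4/min (~23 h doubling — faster than typical
prostate lines so that growth differences are visible within desk-scale
horizons); TNF diffusivity 6000 µm²/min with 0.05/min decay (pulses
equilibrate across the box in minutes and wash out in tens of minutes);
receptor kinetics k_on = 5 /(conc·min), k_off = 0.05, k_endo = 0.05,
k_recycle = 0.01 /min with θ = 0.5 on the bound fraction, giving ~minutes
binding, ~15-min surface desensitisation under sustained ligand and
~100-min resensitisation — the mechanism by which frequent short pulses
kill more than continuous exposure; Boolean cascade rates
(k_sig = 0.015/min etc.) set so a single 10-min pulse commits a few percent
of cells to apoptosis. The drug substrate diffuses at 100 µm²/min with
cellular uptake 0.7/min, giving a penetration depth √(D/λ_eff) ≈ 14 µm —
under spherical screening, <1% of the boundary concentration reaches the
centre of a 100-µm spheroid, which is the boundary-confined exposure the
screening scenario studies (an earlier 0.3/min default, derived with a
planar instead of spherical attenuation estimate, let ~25% through and was
corrected to meet the stated design goal). Contact inhibition is enabled
only in the drug screen, with p_max = 0.05 calibrated against the measured
overlap-pressure scale of a packed spheroid (interior median ≈ 0.026, rim
≈ 0.004), i.e. interior division roughly halved and the rim nearly free —
the proliferating-rim structure that lets space freed by dying boundary
cells feed back into interior proliferation.

Problem sizes in the test suite follow the same desk-scale choices:
pulse-regime comparisons use medians over 10 replicates of ~270-cell
spheroids over 1440 min; the layer-shielding analysis uses 10 replicates
per arm of the 100-µm screen over 2160 min (growth comparisons through
replicate medians throughout).

What the synthetic scenarios do **not** show: the fixtures' Boolean models
are small idealisations, the cycle model is single-rate, there is no ECM,
motility, or oxygen limitation, receptor parameters are not fitted to
measured TNF-receptor kinetics, and dose-response curves are synthetic.
Passing tests demonstrate that the engine, couplings and analyses implement
their contracts and reproduce the qualitative regime structure — not that
any specific biological system is quantitatively reproduced.

## Known limitations and open choices

* Secretion draws from an implicit source: only uptake is booked into the
  internalised pool, so the global mass budget is exact only for λ = 0
  without secretion or Dirichlet supply (the conditions of the conservation
  suite).
* The inhibition effect E entering the synergy analysis is defined as
  1 − AUC_treated/AUC_untreated (clamped to [0, 1]); other inhibition
  metrics (final counts, viability fractions) are possible and the choice
  is configurable in principle.
* Layer membership in the spatial decomposition is re-evaluated per
  snapshot; cells therefore migrate between layers, which introduces a
  small cross-layer spillover into per-layer growth indices at short
  horizons.
* Apoptotic cells remain mechanical obstacles until removed (480 min),
  delaying the space-freeing feedback.
* Drug inhibition uses the instantaneous nearest-voxel concentration, not
  a time-averaged exposure.
* TNF trimer stoichiometry is ignored (1:1 assumed).
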