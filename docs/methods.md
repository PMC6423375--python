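# Methods

`boolcell` simulates populations of cell agents on a rectangular slot lattice.
Each cell carries its own copy of a logical (Boolean) signaling network;
fate-decision nodes of that network trigger cellular actions, and diffusible
substances couple the network to the microenvironment and to other cells.
This note records the model, its conventions, the choices made where the
design was genuinely open, and what the built-in fixtures do and do not show.

## Logical networks and node taxonomy

A network distinguishes four node kinds: *genes* (rules, incoming and
outgoing links), *receptors* (environment inputs; no rule, no incoming
links), *output* nodes (drive substance production; sinks) and
*fate-decision* nodes (trigger actions; sinks). Every non-receptor node has a
Boolean rule over its parents; rules are normalised internally to truth
tables (parent *i* contributes bit *i*, least-significant first). The
expression grammar is identifiers, `&`, `|`, `!`, parentheses and the
constants `0`/`1`.

Files are accepted in three XML dialects. GraphML and GXL carry explicit
`kind`/`action`/`rule` (and edge `sign`) attributes. GINsim's GINML carries
neither a node taxonomy nor expressions, so on import:

* only Boolean models are accepted (`maxvalue` 1 everywhere); multivalued
  nodes raise an unsupported-model error;
* logical parameters become truth tables: a row is active iff some
  parameter with target value 1 matches the row's set of active incoming
  interactions exactly;
* kinds are inferred — declared inputs or edge-free nodes become receptors,
  sinks whose id names a cellular action (`Proliferation`, `Apoptosis`,
  `Necrosis`, `Growth_Arrest`) become fate nodes, other sinks outputs;
* a ruleless non-receptor defaults to the self-maintaining rule (identity
  on itself) so inputs-without-logic are stable rather than undefined.

Edge signs are display/provenance metadata only; the dynamics are entirely
rule-driven. The canonical serialization is a plain-text, one-record-per-line
format that round-trips all of the above losslessly (truth tables without an
authored expression are rendered as disjunctive normal form).

## Mutations

A clone's mutation profile either locks nodes (`force_active`,
`force_inactive`) or replaces their rules. Locks overwrite the random
initialization and exclude the node from updates; rule replacements are
applied to a copy of the network (the original is never modified). Applying
a force-constraint profile twice equals applying it once.

## Asynchronous dynamics

Updates follow the Thomas asynchronous scheme: one step picks uniformly at
random among the *unstable* nodes (rule output ≠ current value, excluding
locked nodes and receptors) and flips exactly that node. Fixed points of
this scheme coincide with the logical stable states, which
`find_stable_states` enumerates exhaustively (guarded at 22 free nodes;
beyond that the state space is too large and sampling should be used).
A variant that picks any node — possibly already stable — differs only in
time scaling, not in fixed points; the unstable-node form is used throughout.

Fate semantics during a decision window:

* **Immediate fates** (apoptosis, necrosis) fire as soon as the fate node is
  active *and its rule currently confirms the activation*, checked at
  initialization and after every step. The rule-confirmation guard is
  deliberate: states are initialized uniformly at random, so roughly half of
  all cells start with any given fate bit set. A raw level trigger would
  kill half of every clone at birth; a raw edge trigger would miss cells
  whose fate node is active *and already stable* from initialization.
  Rule-confirmed activation makes randomly seeded populations converge to
  the stable-state analysis, which is the behavior the replicated-profile
  experiments require.
* **Deferred fates** (proliferation, growth arrest) are read as plain levels
  at the window boundary, proliferation taking priority over growth arrest.
  Ties between immediate fates resolve to apoptosis unless necrosis was
  forced by the environment precondition.
* Cyclic attractors are not detected specially; a cell cycling without fate
  activation reports "no decision" and keeps accumulating steps across
  windows.

`fate_probability_profile` initializes each free node independently with
P(active) = 0.5 (no stated bias), applies the clone's locks, simulates each
cell to the window and reports decision fractions (mean ± SE over repeats,
summing to 1 including "none") plus the cumulative immediate-decision time
series and a cells × nodes state heatmap.

## Cells, lattice, and the tick

Cells occupy one slot each. A tick performs, in order: (1) receptor
synchronisation from local voxel concentrations, and the necrosis
precondition (local oxygen strictly below 0.02 mM forces necrosis regardless
of network state); (2) `network_update_rate` asynchronous steps per living,
non-arrested cell (vectorized across cells of a clone — exact, because cells
interact only through fields synchronised once per tick); (3) immediate
fates as they occur; (4) at decision-window boundaries, deferred fates in a
fresh random order; (5) one diffusion advance per substance using the
current sinks and sources.

Actions: apoptosis removes the cell and frees the slot; necrosis freezes the
cell in place forever (no consumption, no updates); proliferation copies the
cell into a uniformly random free neighbor slot (Moore neighborhood by
default — 26 in 3D, 8 in 2D; von Neumann available) and resets the
proliferation node in parent and daughter; a fully enclosed cell enters
growth arrest instead. Growth arrest pauses the network for 3 decision
windows (same counter whether network-decided or blockage-induced), halves
environmental interaction, and resumes from the paused state. Daughters
inherit a copy of the parent's current network state by default
(`randomize` available), encoding inheritance of signaling state.

## Microenvironment

Each substance obeys du/dt = D∇²u + S on a voxel grid (sparsity 1 or 3 cell
slots per voxel edge), integrated with explicit FTCS under Dirichlet
boundaries. Steps are auto-subdivided to respect the stability bound
α = D·dt/h² ≤ 1/(2·dims); when the required substep count exceeds a
configurable cap the advance is truncated to the capped number of stable
steps, which makes the field track its quasi-steady state (diffusion is
orders of magnitude faster than the cellular timescale, so the capped field
is the physically relevant limit). Negative concentrations from strong
sinks are clamped to zero with a logged warning.

Oxygen is consumed at S = m·R₀·(C − C_Nf)/(C_opt − C_Nf), floored at zero
below C_Nf, with C_opt = 0.28 mM and C_Nf at 80% of the activation
threshold; the activation threshold is identified with the 0.02 mM necrosis
trigger, so C_Nf = 0.016 mM. The status multiplier m is 1 for living cells,
0.5 in growth arrest, 0 for necrotic cells; cells with no decision consume
at full rate. Other diffusibles use S = P₀·I_output − R₀·I_receptor per
cell — production and consumption gated by the cell's output/receptor node
bits. Consumption enters the PDE with a minus sign (it is a sink). A
voxel's source term is the plain sum of its cells' terms, so a sparsity-3
voxel aggregates the sinks of up to 27 cells.

Receptor coupling is a step function: `active_above` uses ≥ (threshold
included), `active_below` and the necrosis precondition use strict <. These
boundary conventions are fixed for reproducibility.

Units and scales: diffusion coefficients are m²/s (oxygen default 1.0e-9),
oxygen rates mM/s (default consumption 5.0e-3), the slot edge defaults to
2.0e-5 m (≈ one cell diameter) and one simulation step to 1 s — the PDE
literature gives D and R but neither a voxel size nor a step duration, so
these defaults were chosen to make the standard parameter values numerically
stable. Growth-factor substances (EGF) are handled in *production units*:
P₀ = 1 unit/s and the consumption rate and activation threshold are
expressed as fractions of P₀ (both 5.0e-4 in the signaling scenario).

## Measures

Sphericity is ψ = π^(1/3)(6V)^(2/3)/A with V counted in slots (V = n·h³)
and A in exposed voxel faces (A = faces·h²) — not a smoothed surface, so
absolute values are discretization-dependent (a single voxel gives
ψ ≈ 0.806, a digitized ball approaches its digitization limit from below);
comparisons between spheroids on the same lattice are meaningful, which is
the use the package makes of them. Spheroid radius is the mean Euclidean
distance from the initial center to the surface cells (those with an empty
face neighbor). Doubling time is the first time the living count reaches
twice the initial value, linearly interpolated and expressed in decision
rounds (steps/window). Clonal fractions are over living cells only;
isolation-mode fractions normalise each clone's final count over the summed
finals of the separate monoclonal runs. Group comparisons use the
Kruskal–Wallis H with tie correction (via scipy) with an all-identical
convention of (H, p) = (0, 1), starred at 0.05/0.01/0.001/0.0001.

## Replicates and seeding

Replicate *i* of an experiment with master seed *s* draws its generator from
`SeedSequence(s)` spawn stream *i*: streams are independent, reproducible,
and results are invariant to execution order. Aggregation (mean ± SE, with
SE = sd/√R, absent for R = 1) is a pure function of the per-replicate
results. Runs stop early on extinction.

## Fixtures and what they show

The built-in `minifate` network is an 8-node caricature of growth-factor
signaling (EGF receptor → EGFR → AKT against the self-maintaining PTEN
brake; P53 opposes AKT; proliferation, apoptosis and growth-arrest fate
nodes read the pathway out). Its mutation panel — all combinations of
EGFR activation and p53/PTEN loss — reproduces the *qualitative* structure
of the published experiments: only EGFR-activated clones grow under
starvation, the double mutant proliferates deterministically, and the EGFR+
single mutant splits 50/50 on PTEN's random initial value.
`minifate_hypoxia` adds a hypoxia-sensing receptor driving an EGF-producing
output node, closing the autocrine/paracrine loop.

The hypoxia sensor activates below 0.03 mM O₂ — deliberately *above* the
0.02 mM necrosis trigger. With both thresholds equal, a cell would necrose
in the same tick its sensor first fired and could never mount an EGF
response; a hypoxia response must precede anoxic death to exist at all.

These fixtures are stand-ins, not the published 53-node MAPK model: their
fate probabilities and doubling times are properties of the toy wiring, so
passing fixture tests demonstrates the correctness of the machinery
(dynamics, constraints, diffusion, fate timing, measures), not quantitative
agreement with MAPK-network results. The published MAPK GINML can be
imported (`import_mapk_network`, with a node-count check) to run the
quantitative scenarios; it is not redistributed with the package.

Desk-scale problem sizes used by the test suite and `scripts/acceptance.py`
(10 replicates, 20–200 initial cells, 300–800 steps, lattices 21³–33³) were
chosen so the full battery runs in minutes; scenario defaults keep the
published scales (100 replicates, 2,000–4,000 steps, 100–500 cells).

## Known limitations

* No migration, invasion, adhesion mechanics, matrix porosity/stiffness or
  off-lattice positions.
* Synchronous or generalized update schemes, multivalued logic, SBML-qual
  import and symbolic (BDD) attractor analysis are out of scope.
* Absolute sphericity values depend on the voxel-face surface estimate.
* The FTCS solver is explicit only; very fine grids at sparsity 1 rely on
  the capped quasi-steady-state advance rather than fully resolved
  transients.
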