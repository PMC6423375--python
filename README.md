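# boolcell

Multiscale agent-based simulation of cell populations whose behavior emerges
from intracellular Boolean networks coupled to a diffusive microenvironment.

Studying how a genotype turns into cellular behavior requires more than a
pathway diagram: the same signaling network produces different fates
depending on nutrients, oxygen and neighboring cells. `boolcell` is for
systems/computational biologists who want to run that experiment *in
silico*: populations of cell agents grow on a 2D/3D lattice, each cell
executing its own copy of a logical signaling network under mutation
constraints, while oxygen and growth factors diffuse around them and feed
back into the networks. Typical uses are tumor-spheroid growth under
starvation or hypoxia, clonal competition between mutation profiles, and
paracrine growth-factor signaling.

## The model

* **Networks.** Boolean networks with four node kinds — genes, receptors
  (inputs), outputs, and fate-decision nodes — updated with the Thomas
  asynchronous scheme: each step flips one uniformly chosen *unstable* node
  (rule output ≠ current value). Fixed points are exactly the logical
  stable states; `find_stable_states` enumerates them exhaustively.
  Networks load from GINML (GINsim, Boolean models), GraphML or GXL, or
  from a plain-text canonical format.
* **Mutations.** A clone's profile locks nodes constitutively
  active/inactive or replaces rules; there is no limit on profiles or
  mutated genes per cell.
* **Fates.** An active apoptosis/necrosis node acts immediately (the cell
  is removed / dies in place); proliferation and growth arrest are executed
  at the end of a user-defined *decision window* (daughter into a random
  free neighbor slot; a blocked or arrested cell pauses for three windows
  at half environmental interaction).
* **Microenvironment.** Each substance obeys du/dt = D∇²u + S, solved with
  explicit FTCS under Dirichlet boundaries on a voxel grid. Cells consume
  oxygen at S = R₀(C − C_Nf)/(C_opt − C_Nf) (C_opt = 0.28 mM; necrosis is
  forced below 0.02 mM), and produce/consume user-defined diffusibles
  gated by output/receptor nodes; step functions on local concentrations
  set receptor bits.
* **Measures.** Growth curves, doubling time in decision rounds,
  voxel-face sphericity ψ = π^(1/3)(6V)^(2/3)/A, spheroid radius, clonal
  fractions, necrotic-core size, Kruskal–Wallis group comparisons.

See `docs/methods.md` for conventions, parameter defaults and limitations.

## Worked example

The built-in `minifate` fixture is an 8-node growth-factor pathway (EGF →
EGFR → AKT against the self-maintaining PTEN brake, P53 opposing AKT, with
proliferation/apoptosis/growth-arrest fate nodes):

```python
import boolcell as bc

net = bc.make_toy_network("minifate")
panel = {p.clone_label: p for p in bc.minifate_clone_panel()}

states = bc.find_stable_states(net, pinned_receptors={"EGF": 0})
print(f"wild-type stable states (EGF = 0): {len(states)}")
for s in states:
    print("  active:", ", ".join(n for n, v in s.items() if v))

res = bc.fate_probability_profile(
    net, panel["EGFR+"], n_cells=1000, n_repeats=10, window=100, seed=1
)
for decision in ("proliferation", "growth_arrest", "apoptosis", "none"):
    print(f"EGFR+ {decision}: {res.fractions[decision]:.3f} "
          f"+- {res.se[decision]:.3f}")
```

prints

```
wild-type stable states (EGF = 0): 2
  active: P53, Apoptosis
  active: PTEN, P53, Apoptosis
EGFR+ proliferation: 0.490 +- 0.007
EGFR+ growth_arrest: 0.510 +- 0.007
EGFR+ apoptosis: 0.000 +- 0.000
EGFR+ none: 0.000 +- 0.000
```

Starved wild-type cells always end in apoptosis (two stable states differing
only in PTEN). Constitutively activating EGFR rescues half the population:
PTEN is self-maintaining, so its random initial value decides between
proliferation (PTEN off) and growth arrest (PTEN on) — the fractions above
are 0.5 within sampling error of 10,000 simulated cells.

The same models run from the shell:

```sh
boolcell fixtures minifate --out fixtures/
boolcell stable-states fixtures/minifate.txt --constraints EGFR=1,PTEN=0 --pin EGF=0
boolcell run experiment.yaml --out results/
boolcell measure results/
```

Ready-made scenario configurations (`make_scenario`) cover starvation
growth of the eight-clone mutation panel, timed mutation-order experiments,
clonal competition, hypoxia with necrotic-core formation, and
hypoxia-driven EGF signaling. The published 53-node MAPK logical network
can be imported from its GINML file with
`bc.import_mapk_network("mapk53.ginml")` to run the same scenarios on
the full signaling model (the file is not redistributed; the quantitative
test in `tests/test_acceptance.py` looks for it at
`data/external/mapk53.ginml`).

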