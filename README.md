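# asyndyn

Kinetic modeling of intracellular alpha-synuclein (ASYN) dynamics: constant
("source") expression, dopamine (DA) modification, stepwise oligomerization
with a high-molecular-weight (HMW) aggregate pool, and degradation through
three routes — chaperone-mediated autophagy via the Lamp2a receptor,
macroautophagy via an autophagosome compartment, and the proteasome.

The canonical network has **90 species, 136 elementary mass-action
reactions, 3 compartments**, and **20 grouped rate constants**. DA-modified
monomers bind Lamp2a irreversibly and progressively suppress the receptor,
which couples ASYN overexpression to the collapse of its own proteolysis.

What the package provides:

- `asyndyn.network` — canonical model builder, structural validation, JSON /
  reaction-list serialization (`asyndyn.sbml_io` adds SBML L3V1 export/import)
- `asyndyn.simulate` — deterministic simulation (LSODA) and exact stochastic
  simulation (Gibson–Bruck next-reaction method with an indexed priority
  queue; direct-method fallback), ensembles with daily summaries
- `asyndyn.quantify` — Western-blot densitometry to scaled per-cell particle
  numbers (three recombinant standards, smear-ratio oligomer estimate), plus
  the packaged daily calibration table
- `asyndyn.calibrate` — weighted-SSE objective with constraint caps
  (HMW ≤ 15, proteasome-bound ≤ 20, proteasome mass fraction ≤ 0.5%), scaled
  finite-difference sensitivities, particle-swarm estimation (GA/GASR/SRES
  comparators), and the five qualitative tuning criteria
- `asyndyn.scenarios` — the three intervention scenarios (half production,
  Lamp2a 200→600, DA production off) and outcome comparison
- `asyndyn.synth` — synthetic datasets with known ground truth, inverse
  "blotify" mapping to intensity space, and parameter-recovery experiments
- `asyndyn.fitted` — the shipped calibrated parameter set
  (`data/calibrated.yaml`) and the pre-calibration starting table

## CLI

```sh
asyndyn build --out model.xml                 # SBML (or .json / .txt)
asyndyn validate model.json
asyndyn simulate --algorithm ssa --runs 10 --seed 42 --out traj.csv
asyndyn quantify --in blots.csv --out table.csv
asyndyn sensitivity --out sens.csv
asyndyn calibrate --algorithm ps --seed 1 --iters 2000 --out fitted.yaml
asyndyn scenario --name s2_triple_lamp2a --runs 10 --seed 7 --out outcome.json
asyndyn synth --sigma 0.1 --seed 3 --space intensities --out synth.csv
```

## Shipped fit

The packaged calibrated set reproduces the daily dimer and oligomer series
within 20% of each series mean, passes the five qualitative trend criteria
on a 10-run stochastic ensemble, and respects all three constraint caps.
Of the three intervention scenarios, tripling Lamp2a and shutting off DA
production reproduce the expected outcomes in full; halving ASYN production
reduces oligomers but does not preserve free Lamp2a at day 7 under this
reconstruction of the parameter grouping (see the acceptance test suite,
where that assertion is intentionally left failing).

## Conventions

- Counts are in the 1000×-scaled per-cell particle units used throughout;
  7 "lab days" = 600,000 s, day k sampled at k·600000/7 s.
- Blot observables are free cytosolic species, modified + unmodified summed:
  monomers = WT1+DM1, dimers = WT2+DM2, oligomers = Σ orders 3–9.
- Stochastic runs are bitwise reproducible given (model, parameters, initial
  state, seed); ensembles seed runs `base_seed + i`.
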