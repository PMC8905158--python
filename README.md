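# kindisp

Kin selection and the evolution of altruism under density-dependent
dispersal in island-structured populations.

The package has two layers that check each other:

- **Closed forms** (`kindisp.analytics`): whole-group relatedness `r`, the
  "scale of competition" `a`, the dispersal-mortality load `chi`, the
  Hamilton's-rule margin, the potential for altruism `A` (the threshold
  cost-to-benefit ratio `C/B` below which indiscriminate altruism is
  favoured), the ESS density-dependent dispersal schedule `x*_P` and its
  population mean `x̄*`. Two classic limits are built in as tested
  identities: with density-independent dispersal `A = 1/n` exactly (the
  rate of dispersal has no net effect), while at the dispersal ESS kin
  competition is abolished (`a = 0`) and `A = (r - c²)/(1 - c²) > 1/n` —
  viscosity then promotes altruism.
- **Individual-based simulation** (`kindisp.simulator`,
  `kindisp.experiments`): an agent-based island model in which an altruism
  locus and a two-locus linear dispersal reaction norm co-evolve under
  mutation, selection and drift. The experiment layer evolves dispersal
  per `(n, c)` grid cell, estimates each population's potential for
  altruism by bisecting on `C/B`, and tests the negative association
  between evolved dispersal and the potential for altruism with a Monte
  Carlo randomization test.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion. Criteria 1–3 (closed-form identities, monotonicities, and the
independent invasion-fitness / exhaustive-permutation oracles) run in
seconds; criteria 4–6 run scaled-down simulations and together take
roughly 15–20 minutes on one CPU.

## Command line

```sh
# every closed-form quantity at one parameter point (JSON)
kindisp analytic --n 2 --c 0.2
# ... or at an explicit dispersal regime, or for a CSV batch
kindisp analytic --n 2 --c 0.2 --xbar 0.5 --mu 0.3
kindisp analytic --n 1 --c 0 --batch params.csv --out derived.csv

# one simulation run from a YAML config -> per-generation CSV + manifest
kindisp simulate --config examples/sim.yaml --out run.csv --seed 1

# the experiments
kindisp sweep    --out sweep.csv --seed 1
kindisp potential --n 2 --c 0.2 --out pot.csv --seed 1
kindisp permtest --data xy.csv --out test.csv
kindisp figure1d --out figure1d.csv --seed 1       # sweep + randomization test
```

A minimal simulation config needs only the patch size and dispersal cost;
everything else has documented defaults (see `kindisp.config.CONFIG_DEFAULTS`):

```yaml
n: 2
c: 0.2
num_patches: 500
generations: 5000
seed: 7
```

Every results CSV is paired with a `*.manifest.json` holding the resolved
settings and seeds; re-running from a manifest reproduces the CSV byte for
byte. `--full` on the experiment subcommands switches to published-scale
populations (5×10⁴ breeders, 2×10⁴ generations — hours of CPU; the default
scaled-down settings are the tested surface).

## Layout

```
src/kindisp/
  analytics.py     closed-form quantities and their domain types
  simulator.py     vectorized agent-based life cycle
  experiments.py   threshold bisection, parameter sweep, randomization test
  config.py        YAML config schema, CSV + manifest serialization
  cli.py           click command group
tests/             pytest suite (unit, property, acceptance) + oracles
scripts/acceptance.py
```
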