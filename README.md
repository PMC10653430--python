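# optenvelope

Growth-coupled strain design by target-point guided knockout search for
constraint-based metabolic models.

Given a stoichiometric model, a biomass reaction and a product exchange, the
pipeline:

1. computes the **production envelope** (min/max product secretion over a
   growth-rate grid) and picks a primary target point on the upper edge at a
   small fraction (default 3 %) of the maximal growth rate;
2. solves a MILP for the **minimal active reactions (MAR)** that can carry the
   network exactly at that target, and removes everything else — yielding a
   strongly coupled envelope whenever one exists;
3. **reinserts** the removed reactions one at a time, keeping every reaction
   whose return preserves the guaranteed minimum secretion at zero growth, so
   that only a minimal knockout set remains.

Interior target points between the primary target and the envelope's
maximal-growth (MP) point are then scanned to collect alternative designs
into a comparison table, and a duality-reformulated MILP variant answers
"what is the best guaranteed minimum with at most K knockouts?".

## CLI

```sh
# end-to-end design run (toy example)
python -c "from optenvelope.toys import make_coupling_toy; \
           from optenvelope import save_json; save_json(make_coupling_toy(), 'toy.json')"
optenvelope run --model toy.json --biomass R3 --product EX_P --out out/

# with a config file (medium, roles, molecular weights, scan settings)
optenvelope run --config src/optenvelope/data/iJR904_acetate.yaml --out out/

# knockout budget series (Fig-5 style envelope expansion)
optenvelope cap --config cfg.yaml --max-knockouts 3 --max-knockouts 7

# rank hosts for one product (one config per host)
optenvelope compare host_a.yaml host_b.yaml --out comparison.json
```

Outputs are TSV/JSON tables (wild-type envelope, primary design, comparison
table, capped designs) plus an optional envelope overlay plot (`--plot`).

## Published models

The benchmark/acceptance computations use the public BiGG models iJR904
(*E. coli*) and iMM904 (*S. cerevisiae*), which are not redistributed here.
With network access:

```sh
python scripts/fetch_models.py     # downloads into src/optenvelope/data/
```

or drop `iJR904.json` / `iMM904.json` into `$OPTENVELOPE_MODEL_DIR` or
`./data/bigg/`.

## Layout

| module | purpose |
|---|---|
| `optenvelope.model_io` | model reading/writing, irreversible split, medium, reaction roles |
| `optenvelope.envelope` | FBA, production envelopes, coupling class, MP point, yields |
| `optenvelope.mar_milp` | minimal-active-reactions MILP and model reduction |
| `optenvelope.reinsertion` | sequential reinsertion to a minimal knockout set |
| `optenvelope.target_scan` | interior target points and the comparison table |
| `optenvelope.knockout_cap` | duality-based bounded-knockout MILP |
| `optenvelope.toys` | synthetic test models and brute-force oracles |
| `optenvelope.benchmarks` | published-model benchmark recomputations |
| `optenvelope.cli` | `optenvelope run/cap/compare`, pipeline orchestration |
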