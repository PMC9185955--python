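# nhecon

Health-economic evaluation toolkit for nurse-led nursing-home care models,
assessed from the facility's perspective. It covers the full pipeline:

* **Synthetic ledger generation** (`nhecon.synth`) — stepped-wedge rollout of
  seven analytic units (six single facilities plus one pooled multi-site
  group), monthly census with Poisson hospitalisation counts, nurse salary
  spells, a TDABC process map, price schedules and hospitalisation episodes.
  Fully deterministic given one seed (named substreams per table).
* **TDABC implementation costing** (`nhecon.tdabc`) — time-driven
  activity-based costing of eight implementation action categories plus
  travel/material, reported per bed with exact cost/time conservation.
* **Intervention costing** (`nhecon.intervention`) — the expanded-role nurse
  salary as yearly cost per bed, head-count and FTE density per 100 beds,
  and mean employment fraction (with a below-minimum staffing warning).
* **Hospitalisation economics** (`nhecon.hospital`) — revenue lost per
  absence day under three billing regimes (reservation fee / hotel fee
  continues / resident nursing share for four days then refunds), with
  conservation of lost + retained revenue and the zero-savings assumption.
* **Cost-effectiveness analysis** (`nhecon.cea`) — hospitalisation and
  salary rates per facility-month, unweighted summary statistics, the ICER
  against zero-cost usual care (0% discount), and cost-effectiveness-plane
  quadrant classification including explicit dominated/infinite signalling.
* **One-way sensitivity analysis** (`nhecon.tornado`) — ±20% perturbations
  of nursing days and hospitalisation counts, sample-range perturbations of
  the three rates, ISPOR-style tornado ordering and a rendered diagram.

## CLI

```sh
nhecon --seed 1 --out-dir out simulate            # write a synthetic ledger
nhecon validate            --ledger out
nhecon cost-implementation --ledger out --out impl.csv
nhecon cost-intervention   --ledger out --out interv.csv
nhecon revenue-loss        --ledger out --out loss.csv
nhecon cea                 --ledger out --out cea.json
nhecon sensitivity         --ledger out --out tornado.svg --table tornado.csv
nhecon --seed 1 --out-dir out report              # everything at once
```

A ledger directory holds `units.csv`, `census.csv`, `process_map.csv`,
`salaries.csv`, `prices.csv` and (optionally) `episodes.csv`; months are ISO
`YYYY-MM` tokens. Generator knobs can be supplied as YAML via `--config`
(see `nhecon.synth.GeneratorConfig` for the full list).

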