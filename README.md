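# sunrule

Interpretable interval-rule mining for labelled numeric sensor tables,
driven by a parallel sunflower optimisation metaheuristic.

The miner searches, per class, for conjunctive rules of the form

```
if((266 ≤ MQ3 ≤ 637) and (516 ≤ NH3 ≤ 847)) Then L
```

scoring candidates by confusion-matrix accuracy on the training split and
reporting per-class rule tables plus best/worst/mean/median/std statistics
over repeated independent experiments.

## How it works

- **datamodel** — CSV feature tables (raw sensor units, heterogeneous
  scales), label canonicalization, exact invertible min-max normalization,
  and packaged 19-row fixture tables with their printed reference rules.
- **rule_engine** — inclusive-bound antecedent evaluation, TP/TN/FP/FN
  counting, accuracy, and the textual/JSON rule forms.
- **sfoa** — a generic continuous sunflower optimiser over a bounded box:
  candidates orient toward the incumbent best ("sun") with steps capped at
  `(upper − lower) / (2N)` per dimension, recombine locally (pollination)
  and are periodically replaced by fresh uniform samples (elimination).
  The sun never moves, so the best-so-far fitness is monotone.
- **miner** — the bridge to rule mining: a `3d` encoding (per-attribute
  activation score, candidate lower bound, candidate upper bound), strict
  threshold `delta` for attribute activation, swap-on-decode bound repair,
  independent optimisation islands whose final populations are decoded,
  deduplicated and ranked, and the repeated-experiment protocol with a
  stratified 80/20 split.
- **synth** — planted-rule benchmark generator: uniform marginals on
  raw-unit channel scales, optional shared-factor correlation, background
  leakage, label noise, class-ratio tuning, and a label-independent null
  generator.
- **cli** — `sunrule generate | mine | eval | benchmark`.

## CLI usage

A config file carries a `generator` and/or a `miner` section:

```yaml
generator:
  n: 400
  d: 6
  planted: {1: [0.3, 0.6], 4: [0.2, 0.7]}
  label_noise: 0.0
  seed: 1
miner:
  population: 30
  pollination_rate: 0.025
  elimination_rate: 0.20
  iterations: 300
  islands: 2
  experiments: 10
  seed: 1
```

```bash
# synthesize a planted-rule table (and its ground-truth rule)
sunrule generate --config config.yaml --out data.csv --truth truth.json

# mine per-class rules over repeated independent experiments
sunrule mine --data data.csv --config config.yaml --out run/ --seed 1

# score a JSON rule file against a labelled table
sunrule eval --rules run/rules.json --data data.csv
sunrule eval --rules src/sunrule/fixtures/rules_cl.json \
             --data src/sunrule/fixtures/cl_19rows.csv --label-map "V=P,Y=A"

# compare against ZeroR (and scikit-learn baselines when available)
sunrule benchmark --data data.csv --config config.yaml
```

`mine` writes `rules.json` (rules + per-class statistics + provenance),
`rules.txt` (a plain-text rule table) and `runstats.csv`. Reports are
byte-identical across runs with the same seeds.

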