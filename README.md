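# replaylab

Analysis pipeline for place-cell recordings on a lattice maze with a
checkpoint-switching spatial learning task, paired with a synthetic session
generator that embeds known ground truth at every level — so each analysis
stage can be validated by recovery rather than by eyeballing.

The pipeline covers:

- **synthetic sessions** (`replaylab.synth`): maze geometry with start box,
  open lattice field, goal box and return alleyway; three learning phases
  (pre / learning / post) with a behavioral switch; theta-modulated,
  phase-precessing Poisson place cells (stable, context-dependent,
  appearing, disappearing, untuned); pink-noise LFP with running theta and
  ripple bursts; time-compressed forward/reverse replay sequences injected
  at immobility pauses.
- **behavior** (`replaylab.behavior`): lattice-cell path strings, path
  labeling between landmarks, moving-average learning curves and learning
  point, Levenshtein trajectory distances, behavior-change probability.
- **spatial tuning** (`replaylab.tuning`): linearized occupancy-normalized
  rate maps, place-field detection, stable / context-dependent / on / off
  joint classification, population-vector correlation matrices.
- **decoding** (`replaylab.decoding`): memoryless Poisson Bayesian decoder
  over (path, position-bin) states, leave-one-out position-error validation
  with an identity-shuffle control.
- **theta sequences** (`replaylab.theta`): theta-cycle segmentation and
  quadrant scores of decoded two-cycle posteriors.
- **replay events** (`replaylab.events`): SWR and synchronous-event
  detection, per-event fine-bin decoding, representation rates (reprate /
  repZ), weighted time-position correlation r, sequence score rZ,
  forward/reverse classification, trajectory events, participation and
  per-cell contribution, ensemble correlations.
- **population statistics** (`replaylab.stats`): hierarchical Bayesian
  Poisson rate and multinomial proportion models (in-package adaptive MCMC,
  split-R-hat/ESS gated), percent-change posteriors, credible intervals,
  and posterior-overlap estimates.
- **pipeline** (`replaylab.pipeline` / CLI): one-command generate → analyze
  → report runs, reproducible from the config and seed alone.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end recovery criteria (decoder
error, replay direction/content recovery, oracle identities, model
calibration); the rest are per-module unit and property tests.

## CLI

```sh
replaylab demo --seed 0 --out demo_run          # small end-to-end run
replaylab run --seed 0 --out run                # full pipeline
replaylab simulate --seed 0 --out sess          # write a synthetic session
replaylab behavior sess                         # trial summaries + learning point
replaylab tuning sess --out classes.tsv
replaylab decode sess --bin-ms 200
replaylab theta sess
replaylab replay sess --n-shuffles 200 --seed 0
replaylab stats run/event_rates.tsv --chains 4
```

All outputs are plain text (TSV/JSON) under the chosen run directory with a
manifest; sessions round-trip through `replaylab.io`.

## Benchmark report

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes every recovery benchmark from scratch (fresh synthetic sessions
from the seed, full analysis, measured metrics) and writes them as JSON.
Runtime is a few minutes on one CPU.
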