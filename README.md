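# rtwalk

First-passage-time random-walk models of response times in
multi-alternative decisions.

The package implements two generative models of a single decision:

* **obstacles** — an unbiased walker on a 2-D square lattice scattered
  with reflecting obstacles (density `q`), absorbed at a circular
  boundary of radius `R`; each iteration costs `dt_ms` milliseconds.
  Obstacles create dead ends the walker must back out of, which fattens
  the first-passage-time tail.
* **ddm** — a discrete drift-diffusion analogue: the same lattice walker
  with an outward bias. A proposed step at angle θ to the radial
  direction costs `C = (1 − cos θ)/2` and is accepted with probability
  `exp(−C/ε)`; rejected proposals still consume an iteration.

On top of the simulators:

* exact references (`rtwalk.analytic`): the Lévy–Smirnov 1-D
  first-passage density (power-law tail), the bounded
  absorbing/reflecting solution (exponential tail), the exact
  absorption-time pmf of any fixed grid via its absorbing Markov chain,
  and tail-slope diagnostics;
* distribution tools (`rtwalk.dist`): fixed-width RT histograms
  (default 0.1 s bins over a 300 s budget), KL and Jensen–Shannon
  divergence in nats, and a two-sample Kolmogorov–Smirnov test;
* fitting (`rtwalk.fitting`): fit either model to an RT histogram by
  minimizing the JSD between the data and 75,000-walk simulated
  histograms — exhaustive search over the integer radius, Nelder–Mead
  over the continuous shape parameter with an exhaustive profile over
  `dt_ms`, made deterministic by common random numbers; plus repeated
  80/20 cross-validation for model comparison;
* population analyses (`rtwalk.cohort`): middle-game filtering
  (remaining-time fraction in [0.1, 0.9]), per-instant fits, per-player
  fits, similarity rank-correlation between real and fitted
  distributions, and equal-count rating-group analysis with
  parameter–rating correlations;
* a synthetic-corpus generator (`rtwalk.synth`) producing move tables
  with known per-player ground truth for end-to-end recovery tests.

## CLI

One entry point with five subcommands (data to files, logs to stderr,
seeds recorded in every output):

```bash
# simulate 75,000 decisions from the obstacles model
rtwalk simulate --model obstacles --radius 4 --density 0.45 --dt 90 \
    --n 75000 --seed 1 --out rt.csv

# fit a model to a response-time sample (CSV with rt_s or rt_ms column)
rtwalk fit --target rt.csv --model obstacles --seed 1 --out fit.json

# cross-validated model comparison (80/20 split)
rtwalk compare --target rt.csv --models obstacles,ddm \
    --cv-repeats 1000 --split 0.8 --out cv.json

# synthetic cohort with known ground truth, then rating-group analysis
rtwalk synth --seed 5 --out moves.csv --truth truth.json
rtwalk cohort --data moves.csv --groups 5 --out cohort.json \
    --players-out players.json --min-games 100
```

`--space space.yaml` overrides any `FitSpace` field (search ranges,
simulation budgets, optimizer settings); command-line flags win over the
file.

## Conventions

* `q` (`obstacle_density_q`) is always the *fraction of obstacle nodes*.
  Where a smoothness parameterization is needed it is `1 − q`.
* Divergences are natural-log (nats); JSD is bounded by ln 2 ≈ 0.693.
* All first-passage times are at least `R` steps (unit-step walker).
* Annealed disorder (fresh grid per walk) is the default; quenched mode
  (one grid per batch) backs the exact Markov-chain oracle.
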