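# anfisctl

Dual-timescale adaptive neuro-fuzzy (first-order Sugeno ANFIS) stimulation
control for insect bio-bots, together with a habituating virtual-insect
plant so the whole closed loop can be trained, exercised, and benchmarked
on a desk.

## What is in the box

| module | contents |
| --- | --- |
| `anfisctl.anfis` | Five-layer Sugeno inference: generalized-bell / two-sided Gaussian membership functions, product firing strengths, normalization, affine consequents, weighted-average aggregation; lossless YAML (de)serialization. |
| `anfisctl.learning` | Hybrid estimation: per-sample recursive least squares with forgetting for consequents, damped Gauss-Newton (LMA) or momentum gradient descent for membership parameters, the dual-timescale driver, offline training, and k-fold validation. |
| `anfisctl.habituation` | Coupled short/long-term habituation dynamics with velocity-dependent charging and Wiener-increment noise (Euler-Maruyama); doubles, noise-free, as the controller's observer. |
| `anfisctl.scheduler` | Stimulus shaping: linear-chirp amplitude modulation driven by the habituation level, adaptive inter-burst intervals, safe-range clipping. |
| `anfisctl.plant` | Virtual insect: threshold + Wiener-cascade (low-pass -> saturating) turning response attenuated by latent habituation, stimulus-specific habituation drive, log-normal inter-specimen variability, Ornstein-Uhlenbeck natural walk, ray-cast proximity sensing in a 2-D arena. |
| `anfisctl.controllers` | The assembled 8-input / 3-output adaptive controller (observer, chirp/IBI scheduling, per-rule local RLS, online rule grow/prune) plus the frozen PID-fuzzy and no-stimulation baselines. |
| `anfisctl.experiments` | Closed-loop trial runner, navigation and habituation-resistance metrics, rolling performance score / effective control duration, paired multi-seed comparisons. |
| `anfisctl.benchmarks` | Desk-scale benchmark protocols (accelerated habituation timescales) used by the acceptance tests. |
| `anfisctl.config` / `anfisctl.cli` | YAML configuration with strict key checking, and the `anfisctl` command-line interface. |

## CLI

```bash
anfisctl demo --seed 0 --out out/                 # small end-to-end run
anfisctl train --seed 0 --epochs 25 --out out/    # offline hybrid training
anfisctl simulate --seed 1 --duration 120 --controller anfis --out tel.csv
anfisctl evaluate tel.csv                          # metrics from telemetry CSV
anfisctl compare --seed 0 --n-seeds 10 --out out/  # paired adaptive-vs-baseline study
```

All commands accept `--config path.yaml`; the file is deep-merged over the
documented defaults (`anfisctl.config.default_config()`) with unknown keys
rejected. Sections: `plant`, `habituation`, `controller`, `scheduler`,
`arena`, `experiment`.

## Reproducibility

Every stochastic component takes an explicit `numpy.random.Generator` or
integer seed; identical seeds produce byte-identical telemetry CSVs.
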