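# brokenduet

Simulations of mutual (mis)understanding between a speaker and a listener,
built on a bistable "broken" Lorenz system and inverted by generalized
filtering.

## The problem

When two people interpret the same ambiguous utterance differently — say, a
non-native rendering of "sheep" heard as "ship" — each interpretation can be
self-consistent and stable, and the disagreement can persist no matter how
much more speech arrives.  This package models that situation with a minimal
dynamical dyad:

* A **speaker** whose internal state follows the Lorenz system in a broken
  parameter regime (σ = 0.12, r = 0, b = −0.6) where the attractor splits
  into two disconnected lobes — two stable "interpretations".  The speaker
  emits a scalar percept

      v0 = 0.5 · v1 · y + z,     v1 ∈ {−1, +1},

  which deliberately omits the x coordinate that separates the lobes: the
  percept is ambiguous between them.

* A **listener** who inverts a two-level generative model of the percept by
  generalized filtering — a variational gradient flow on the model's free
  energy in generalized coordinates of motion.  Level 1 holds broken-Lorenz
  beliefs (x̃, ỹ, z̃) with observation ṽ0 = 0.5·tanh(ṽ1)·ỹ + z̃;
  level 2 holds a static lobe belief ṽ1 with Gaussian prior (mean 1,
  log-precision −1).  Free-energy gradients are precision-weighted
  prediction errors, so the listener's confidence enters through two
  log-precisions: **internal** (trust in its dynamics model) and
  **external** (trust in its percept predictions).

Crossing these over {0, 4} gives four regimes — A = (0, 0), B = (4, 0),
C = (0, 4), D = (4, 4) — which reproduce qualitatively distinct outcomes:
the low-confidence listener (A) migrates to the speaker's lobe; the
listener with overconfident percept expectations (C) explains the percept
without ever finding the right lobe; full overconfidence (D) tracks the
percept closely while its state estimates stay dispersed.  Precision-
weighted prediction errors double as in silico local field potentials, from
which peristimulus-averaged evoked responses around lobe switches are
extracted.

Audience: computational neuroscientists and dynamical-systems modellers
interested in predictive coding, hierarchical inference and multistable
perception.

## Worked example

```python
from brokenduet import SimulationProtocol, run_simulation, percept_tracking_error

proto = SimulationProtocol(n_samples=4096)      # constant +1 lobe schedule
for label in "ACD":
    r = run_simulation(label, proto, seed=1)
    print(label, round(r.log_mse, 2), r.lobe_recovered,
          round(r.lobe_occupancy, 2), round(percept_tracking_error(r), 3))
```

prints

```
A 2.18 True 0.84 0.031
C 2.95 False 0.57 0.004
D 3.21 False 0.52 0.028
```

Reading: the baseline listener (A) ends with the lowest state-space error
(log-MSE 2.18), occupies the speaker's lobe 84% of the trailing half of the
run, and is scored as having recovered the lobe.  The overconfident-percept
listener (C) predicts the percept almost perfectly (residual 0.4% of
percept variance) yet its state error is higher and its trajectory is
dispersed across both lobes (occupancy 0.57) — linguistic synchrony without
semantic synchrony.  D likewise tracks the percept (2.8% residual) but
never settles in the right lobe.

The same machinery exposes a CLI:

```bash
brokenduet run --sim A --n-samples 4096 --seed 1 --out-dir runs/
brokenduet sweep --internal 0:4:5 --external 0:4:5 --n-samples 1024 --out sweep.csv
brokenduet erp --label A --period 128 --n-samples 4096 --out erp.csv
```

Each run writes CSV artifacts plus a manifest with content hashes; identical
configs and seeds reproduce bit-identical outputs.

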