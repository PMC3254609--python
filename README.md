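# mgc — ratio coding in the antennal-lobe macroglomerular complex

`mgc` is a simulation and analysis toolkit for a firing-rate model of the
insect macroglomerular complex (MGC), the pheromone-processing part of the
antennal lobe. Male moths must identify the *ratio* of two pheromone blend
components from the rapidly fluctuating filaments of an odour plume. The
package implements a 60-neuron network model of this computation — 30
excitatory projection neurons (PNs) split into two glomeruli, each driven by
one receptor channel, and 30 inhibitory multiglomerular local neurons (LNs) —
together with the complete analysis suite for asking how well the PN
population code reports the blend ratio under static and plume-like pulsed
stimulation.

## The model

Each neuron follows a first-order rate equation

```
tau_i  da_i/dt  =  -a_i  +  f( sum_j w_ij a_j  +  A_i . G(t) )
```

with activation `a_i in [0, 1]`, time constants `tau = 10 ms` (PNs) and
`20 ms` (LNs), a rectified sigmoid `f(x) = tanh(g x)` for `x > 0` (else 0,
gain `g = 2` by default), random sign-constrained weights `w`, afferent
weights `A`, and a two-channel input `G(t) = (rho, 1 - rho) * amplitude`
parameterized by the blend ratio `rho`. Integration is fixed-step RK4 at
1 ms with per-step Gaussian state noise (sd `5e-4`).

Two wiring regimes differ only in the LN–LN inhibitory block:

* **FPA** (fixed-point attractor): all-to-all symmetric LN inhibition.
  One LN wins, the PN spatial pattern freezes — a spatial code.
* **LCA** (limit-cycle attractor): sparse (p = 0.25) asymmetric LN
  inhibition. LN coalitions keep switching, the PN pattern evolves in
  time — a spatiotemporal code.

The analyses quantify the trade-off between the two codes: time-binned
response matrices (10 ms bins), pattern cross-correlation maps, bin-wise and
spatiotemporal PCA(90% variance)+LDA decoding of five ratio classes
(0, 0.25, 0.5, 0.75, 1 ± 0.125), the bell-curve specificity width W(rho)
(RMS second moment of the correlation-vs-ratio curve about its peak), and
the time at which ratio-specific PCA trajectories diverge maximally.

## Worked example

```python
import numpy as np
from mgc import (NetworkSpec, SimulationConfig, build_network, make_pulse,
                 simulate)
from mgc import experiments as ex

# one FPA and one LCA realization sharing every non-LN-LN block
fpa = build_network(NetworkSpec(regime="fpa", seed=7))
lca = build_network(NetworkSpec(regime="lca", seed=7))

cfg = SimulationConfig(duration_ms=700.0, seed=1)
stim = make_pulse(0.5)          # balanced blend, 500 ms pulse at t = 100 ms
for name, net in [("FPA", fpa), ("LCA", lca)]:
    tr = simulate(net, stim, cfg)
    late = tr.ln[:, 500:600].mean(axis=1)
    print(f"{name}: active LNs late in the pulse: {(late > 0.05).sum()}")

# small decoding ensemble (2 networks per regime)
for regime in ("fpa", "lca"):
    specs = ex.make_network_specs(regime, 2, 42)
    acc = ex.accuracy_experiment(specs, [100.0, 500.0], 42,
                                 n_train=60, n_test=100)
    print(f"{regime} decoding accuracy at 100/500 ms:",
          np.round(acc.accuracy, 3))
```

prints

```
FPA: active LNs late in the pulse: 1
LCA: active LNs late in the pulse: 7
fpa decoding accuracy at 100/500 ms: [0.79 0.79]
lca decoding accuracy at 100/500 ms: [0.88  0.815]
```

The FPA network settles on a single winning LN while the LCA network keeps
several LNs active; five-class ratio decoding from the flattened
spatiotemporal PN code is far above the 20% chance level for both regimes
even with this miniature ensemble.

## Command line

```
mgc build --regime lca --seed 3 --out net.npz
mgc inspect --net net.npz
mgc stim pulse --ratio 0.5 --out pulse.json
mgc simulate --net net.npz --stim pulse.json --duration 700 --seed 1 \
    --out trace.npz --csv trace.csv
mgc analyze accuracy --config cfg.yaml --outdir results/
```

`mgc analyze {corrmap,classmap,specificity,accuracy,timing}` runs the
ensemble experiments from a YAML/JSON config (seed, regimes, ensemble
sizes) and writes CSV results plus a manifest.

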