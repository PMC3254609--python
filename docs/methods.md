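# Methods

## Model

The network is a firing-rate model of the moth macroglomerular complex with
two glomeruli. Each of the 60 units (30 projection neurons, PNs; 30 local
neurons, LNs) obeys

    tau_i da_i/dt = -a_i + f( sum_j w_ij a_j + A_i . G(t) ),

integrated with classical fixed-step fourth-order Runge–Kutta at
dt = 1 ms. `G(t)` is the two-channel receptor drive: during a pulse it
equals `(rho, 1 - rho) * amplitude` with total concentration held at 1, so
the blend ratio `rho` is the only stimulus identity variable. Receptor
transduction dynamics are deliberately omitted; pulses are square at the
integration resolution.

Gaussian noise (mean 0, sd 5e-4) is added to the activation state once per
1 ms step (Euler–Maruyama placement) and the state is clipped to [0, 1];
initial activations are drawn from N(0.01, 0.0025). Construction, initial
conditions and per-step noise use three independently seeded streams so one
network can be reused across noise realizations. Stimulation begins 100 ms
into every run so that the initial transient has died out (without input
the network relaxes to the zero state; there is no spontaneous activity).

### Connectivity

| block | probability | weight (mean ± sd) | sign |
|---|---|---|---|
| ORN → PN (own glomerulus only) | 1 | 1 ± 1 | ≥ 0 |
| ORN → LN (both channels) | 1 | 1 ± 1 | ≥ 0 |
| PN → PN (within glomerulus) | 0.8 | 0.0125 ± 0.1 | ≥ 0 |
| LN → PN | 0.2 | −2.5 ± 0.1 | ≤ 0 |
| PN → LN | 0.5 | 0.033 ± 0.1 | ≥ 0 |
| LN → LN, FPA regime | 1 (all-to-all) | −15 ± 0.1 | ≤ 0 |
| LN → LN, LCA regime | 0.25 per ordered pair | −15 ± 0.1 | ≤ 0 |

Weights are normal draws rectified to their block's sign (excitatory draws
below 0 become 0, and symmetrically for inhibitory blocks). Recurrent
diagonals are zero: "all-to-all" excludes self-connections, because
self-inhibition at strength −15 would destroy the winner-take-all mechanism
the FPA regime is defined by. Blocks are drawn in a fixed order with the
LN–LN block last, so FPA and LCA networks built from the same seed share
every other block exactly — the two regimes differ only in LN–LN wiring.
PNs 1–15 read channel 1 and PNs 16–30 channel 2 (an arbitrary labelling,
fixed for reproducibility). LN→PN connections are sampled independently
per (LN, PN) pair.

### Squashing function

The literature behind this architecture specifies only "a rectified
sigmoid". We use

    f(x) = 0 for x <= 0,   tanh(g * x) for x > 0,

which is bounded in [0, 1), linear-like at small drive, and exactly zero at
rest. The gain is exposed in `SimulationConfig`; the package default is
**g = 2**. The gain is the one genuinely free scalar of the model and it
was fixed by model identification against the published ensemble
statistics: at g = 1 the fixed-point regime retains too much analogue ratio
information in its saturation levels and out-decodes the limit-cycle
regime, inverting the published ordering of the two codes (and pushing the
FPA plateau accuracy ≈ 7 points above its published value); at g ≳ 5
saturation destroys FPA ratio information entirely. g = 2 reproduces the
published plateau accuracies (≈ 85% FPA, ≈ 90% LCA), their ordering, the
single-winner FPA LN, the multi-LN late LCA state, and divergence timings
inside the published ±1 sd bands. All tests and the acceptance script run
at the default gain.

## Dynamical regimes

With LN–LN inhibition at −15, an active LN silences any LN it projects to;
LN dynamics are effectively combinatorial. In the FPA regime the all-to-all
competition leaves exactly one winner and a frozen PN spatial pattern
within ~100 ms. In the LCA regime the sparse asymmetric graph supports
switching coalitions; runs end either in a multi-LN fixed point (a
dominating independent set of the LN graph, often reached early) or in
persistent cyclic switching. A consequence worth stating plainly: the
coalition turnover of this implementation is gradual (successive active-LN
sets overlap strongly), so the LCA PN pattern decorrelates over hundreds of
milliseconds, not within one 50 ms band, and the specificity gain from
longer codes is correspondingly weak. The decoder-level contrasts between
the regimes (diagonal-band decodability, interference with 50 ms gaps,
earlier trajectory divergence) are reproduced; the raw-correlation
signature of fast switching is not. We were unable to locate a sigmoid
shape or gain within the stated architecture that produces full pattern
turnover at the 50 ms scale; this is the main known limitation of the
model as implemented.

Integration accuracy deserves one more caveat: during lateral-inhibition
competition the dynamics are transiently chaotic, so *pointwise* trajectory
agreement under step-size refinement is ill-posed — any integrator's local
error is amplified to O(1), exactly as a 5e-4 noise kick is. Convergence is
therefore verified on the relaxation dynamics (where halving dt changes
activations by far less than 1e-3) and at the attractor level under
stimulation (the selected winner and late PN pattern are invariant to dt).

## Analyses

* **Response matrices.** PN activity averaged in 10 ms bins from stimulus
  onset (5 ms bins for trajectory analyses). Flattened spatiotemporal
  vectors are PN-major and invertible given the bin count.
* **Pattern correlation.** Pearson correlation between spatial (or
  flattened) vectors; zero-variance patterns (silent pre-stimulus bins)
  yield 0 with a degeneracy flag rather than an exception. Maps over
  (reference bin, test bin) pairs are averaged arithmetically across
  stimuli and networks (no Fisher-z transform).
* **Ratio classes.** Five classes centred on 0, 0.25, 0.5, 0.75, 1 with
  half-width 0.125; boundary ties round half up. Chance is 20% for
  balanced classes.
* **Decoders.** PCA retaining ≥ 90% variance (fit on training data only;
  test patterns are projected with the training loadings) followed by LDA.
  If the within-class covariance is singular after reduction the model
  degrades to a shrinkage-regularized discriminant with a warning.
  All-zero training bins are flagged uninformative and predict at chance.
* **Protocols.** Code-length accuracy curves use uniform random ratios
  (100 training / 400 test stimuli per network): the task is to *classify*
  a continuum into five groups. Bin-wise classification maps and the
  pulse-train interference experiment use the five centre ratios with
  repeated noisy trials (20 training / 80 test per class): a single 10 ms
  bin cannot resolve the within-class ratio spread, so uniform sampling
  would measure class geometry rather than code stability, which is what
  the map is for.
* **Interference.** Per-pulse accuracy of a 5 × 50 ms pulse train scores
  the bins of each pulse with the training bins at the same latency within
  the first 50 ms of the single-pulse response — i.e. it asks whether each
  pulse restarts the code from scratch.
* **Specificity width.** W(rho) is the square root of the normalized second
  moment, about rho, of the positively rectified correlation between the
  code for rho and the codes on a 41-point ratio grid, within a ±0.25
  window (one-sided toward the interior for rho < 0.25 or > 0.75, to stay
  inside [0, 1]). The window half-width is a parameter.
* **Trajectory timing.** Per network: one PCA (3 components) on all
  ratios/repeats/bins pooled; repeat-averaged per-ratio trajectories;
  mean pairwise Euclidean distance per 5 ms bin; the statistic is the
  argmax time after onset. Ensembles are compared with a Welch t-test.
* **Attractor detection.** A long run is classified as fixed point if its
  20 ms-binned pattern stays within 0.05 (max-abs) of the final pattern
  from some onset on, else as periodic if the late trajectory matches
  itself at the smallest lag with autocorrelation > 0.95 (the smallest
  qualifying lag, since the global maximum can land on a harmonic), else
  as neither. The 0.05 tolerance absorbs state noise and slow amplitude
  drift.

## Problem sizes

Ensemble statistics use 20 network realizations per regime, 20 noise
repeats per ratio for trajectory timing, 100/400 train/test stimuli for
decoders, and a 41-point ratio grid for specificity. Property-level tests
that only need a direction (specificity flatness, interference) use 4–6
networks. These are the sizes at which the published statistics were
defined; all runs complete in minutes on one CPU.

## What the generated data do and do not emulate

All inputs are generated by the package itself: there is no external data.
The stimulus generator covers square single pulses, periodic trains and a
renewal-process "plume" with a 40 ms minimum pulse length — realistic
pulse durations, but no turbulence statistics, concentration fluctuations
within a pulse, or receptor adaptation. Passing tests therefore show that
the *network* and *decoding* machinery behave as described under idealized
inputs; they do not certify performance on measured plume time series.

## Known limitations

* LCA temporal richness is muted (see above): slow pattern decorrelation,
  weak code-length specificity gain, and multi-LN fixed points that are
  often reached well before 0.5 s.
* FPA decoding accuracy declines with code length only beyond ~100 ms; the
  very-short-code advantage (20 ms vs 100 ms) is within noise here.
* The model has exactly two glomeruli throughout the analyses; the network
  type supports other counts, the analyses assume two.
* No spiking, conductances, synaptic delays, plasticity, or
  cell-intrinsic adaptation.
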