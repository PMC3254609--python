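"""Ensemble experiment drivers.

These functions reproduce the study's standard protocols end to end:
build an ensemble of network realizations, stimulate, bin, and feed the
analyses.  Every driver takes a single master seed and derives all
network, stimulus and noise streams from it deterministically, so any
result can be regenerated from (code, seed, sizes).

Protocol notes
--------------
* Response banks for classification use a single 500 ms pulse starting
  100 ms into the run, binned at 10 ms from stimulus onset.
* Code-length accuracy curves use uniform random blend ratios
  (100 training / 400 test stimuli per network by default), labelled by
  their ratio class.
* Bin-wise classification maps use the five class-centre ratios with
  repeated noisy trials (20 training / 80 test per class by default):
  with uniform ratios the within-class ratio spread, not decoder
  quality, limits single-bin accuracy.
* The pulse-train interference protocol scores each pulse with the
  training bins at the same latency within the first 50 ms of the
  single-pulse response ("does each pulse restart the code?").
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .analysis import (
    RATIO_CENTERS,
    BinwiseClassifier,
    CodeLengthAccuracy,
    TimingResult,
    accuracy_vs_code_length,
    cross_classification_map,
    ratio_class,
    specificity_widths,
    train_binwise,
    trajectory_distance_timing,
)
from .coding import CorrelationMap, bin_responses, cross_correlation_map, flatten_code
from .network import Network, NetworkSpec, build_network
from .simulate import SimulationConfig, simulate, simulate_batch, simulate_many
from .stimuli import StimulusProgram, make_pulse, sample_ratios

__all__ = [
    "make_network_specs",
    "uniform_ratio_bank",
    "center_ratio_bank",
    "accuracy_experiment",
    "binwise_map_experiment",
    "mean_correlation_map",
    "correlation_map_experiment",
    "interval_interference_experiment",
    "specificity_experiment",
    "trajectory_timing_experiment",
]

ONSET_MS = 100.0
PULSE_MS = 500.0
BIN_MS = 10.0


def _sub_seed(master_seed: int, *key: int) -> int:
    """Deterministic 31-bit child seed for a labelled sub-stream."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] >> 1)


def make_network_specs(
    regime: str, n_networks: int, master_seed: int, **overrides
) -> list[NetworkSpec]:
    """Distinct-seed network specs for one ensemble."""
    return [
        NetworkSpec(regime=regime, seed=_sub_seed(master_seed, 0, i), **overrides)
        for i in range(n_networks)
    ]


def _bin_window(onset: float, stim_end: float, tail_ms: float, bin_ms: float):
    n_bins = int(np.ceil((stim_end - onset + tail_ms) / bin_ms))
    return onset, onset + n_bins * bin_ms


def uniform_ratio_bank(
    net: Network,
    n_stimuli: int,
    seed: int,
    duration_ms: float = ONSET_MS + PULSE_MS,
    pulse_ms: float = PULSE_MS,
    bin_ms: float = BIN_MS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned responses to ``n_stimuli`` uniform-ratio 500 ms pulses.

    Returns (X, y, ratios): X is (n_stimuli, n_pn, n_bins), y the ratio
    classes.
    """
    ratios = sample_ratios(n_stimuli, seed)
    stims = [make_pulse(r, ONSET_MS, pulse_ms) for r in ratios]
    cfg = SimulationConfig(duration_ms=duration_ms, seed=_sub_seed(seed, 1))
    traces = simulate_many(net, stims, cfg)
    window = (ONSET_MS, ONSET_MS + pulse_ms)
    X = np.stack([bin_responses(tr, bin_ms, window).R for tr in traces])
    y = np.array([ratio_class(r) for r in ratios])
    return X, y, ratios


def center_ratio_bank(
    net: Network,
    n_per_class: int,
    seed: int,
    duration_ms: float = ONSET_MS + PULSE_MS,
    pulse_ms: float = PULSE_MS,
    bin_ms: float = BIN_MS,
    stim: StimulusProgram | None = None,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned responses to repeated trials of the five centre ratios.

    ``stim`` overrides the default single pulse (the ratio field of the
    override is replaced per class); ``window`` overrides the binning
    window.  Returns (X, y).
    """
    X_parts, y_parts = [], []
    for ci, rho in enumerate(RATIO_CENTERS):
        if stim is None:
            program = make_pulse(rho, ONSET_MS, pulse_ms)
        else:
            program = StimulusProgram(rho, stim.pulses, stim.amplitude)
        cfg = SimulationConfig(duration_ms=duration_ms, seed=_sub_seed(seed, 2, ci))
        traces = simulate_batch(net, program, cfg, n_per_class)
        win = window if window is not None else (ONSET_MS, ONSET_MS + pulse_ms)
        X_parts.extend(bin_responses(tr, bin_ms, win).R for tr in traces)
        y_parts.append(np.full(n_per_class, ci))
    return np.stack(X_parts), np.concatenate(y_parts)


# ---------------------------------------------------------------------------
# Fig-style experiments


def accuracy_experiment(
    specs: Sequence[NetworkSpec],
    code_lengths_ms: Sequence[float],
    master_seed: int,
    n_train: int = 100,
    n_test: int = 400,
) -> CodeLengthAccuracy:
    """Decoding accuracy of flattened codes vs code length.

    One 100-train / 400-test uniform-ratio bank per network; PCA (90%
    variance) + LDA on codes truncated to each length; mean and
    standard error across networks.
    """
    banks = []
    for i, spec in enumerate(specs):
        net = build_network(spec)
        Xtr, ytr, _ = uniform_ratio_bank(net, n_train, _sub_seed(master_seed, 3, i, 0))
        Xte, yte, _ = uniform_ratio_bank(net, n_test, _sub_seed(master_seed, 3, i, 1))
        banks.append((Xtr, ytr, Xte, yte))
    return accuracy_vs_code_length(
        banks, np.asarray(code_lengths_ms, dtype=float), BIN_MS,
        seed=_sub_seed(master_seed, 3, 999),
    )


def binwise_map_experiment(
    specs: Sequence[NetworkSpec],
    master_seed: int,
    n_train_per_class: int = 20,
    n_test_per_class: int = 80,
    test_stim: StimulusProgram | None = None,
    tail_ms: float = 0.0,
) -> tuple[np.ndarray, BinwiseClassifier]:
    """Mean cross-classification map over an ensemble of networks.

    Training responses are always to the single 500 ms pulse; test
    responses default to the same stimulus but can be any pulse program
    (``test_stim``; its ratio is replaced per class).  Returns the mean
    (train bin, test bin) accuracy map and the last network's
    classifier (for bin metadata).
    """
    maps = []
    clf = None
    for i, spec in enumerate(specs):
        net = build_network(spec)
        Xtr, ytr = center_ratio_bank(
            net, n_train_per_class, _sub_seed(master_seed, 4, i, 0)
        )
        if test_stim is None:
            Xte, yte = center_ratio_bank(
                net, n_test_per_class, _sub_seed(master_seed, 4, i, 1)
            )
        else:
            t0, t1 = _bin_window(test_stim.onset, test_stim.end, tail_ms, BIN_MS)
            Xte, yte = center_ratio_bank(
                net,
                n_test_per_class,
                _sub_seed(master_seed, 4, i, 1),
                duration_ms=t1 + BIN_MS,
                stim=test_stim,
                window=(t0, t1),
            )
        clf = train_binwise(Xtr, ytr, BIN_MS, seed=_sub_seed(master_seed, 4, i, 2))
        maps.append(cross_classification_map(clf, Xte, yte))
    return np.mean(maps, axis=0), clf


def mean_correlation_map(maps: Sequence[CorrelationMap]) -> np.ndarray:
    """Arithmetic mean of correlation coefficients across maps."""
    return np.mean([m.values for m in maps], axis=0)


def correlation_map_experiment(
    specs: Sequence[NetworkSpec],
    master_seed: int,
    n_ratios: int = 20,
    test_stim: StimulusProgram | None = None,
    tail_ms: float = 0.0,
) -> np.ndarray:
    """Mean cross-correlation map between single-pulse and test responses.

    For each network and each of ``n_ratios`` uniform random ratios the
    reference response (500 ms pulse) is correlated bin-by-bin with an
    independently noisy test response (same ratio; ``test_stim``
    schedule, defaulting to the same single pulse).  Coefficients are
    averaged arithmetically over ratios and networks.
    """
    maps = []
    for i, spec in enumerate(specs):
        net = build_network(spec)
        ratios = sample_ratios(n_ratios, _sub_seed(master_seed, 5, i, 0))
        for j, rho in enumerate(ratios):
            ref_stim = make_pulse(rho, ONSET_MS, PULSE_MS)
            cfg = SimulationConfig(
                duration_ms=ONSET_MS + PULSE_MS,
                seed=_sub_seed(master_seed, 5, i, j, 1),
            )
            ref = bin_responses(
                simulate(net, ref_stim, cfg), BIN_MS, (ONSET_MS, ONSET_MS + PULSE_MS)
            )
            tstim = ref_stim if test_stim is None else StimulusProgram(
                rho, test_stim.pulses, test_stim.amplitude
            )
            t0, t1 = _bin_window(tstim.onset, tstim.end, tail_ms, BIN_MS)
            cfg_t = replace(
                cfg,
                duration_ms=t1 + BIN_MS,
                seed=_sub_seed(master_seed, 5, i, j, 2),
            )
            test = bin_responses(simulate(net, tstim, cfg_t), BIN_MS, (t0, t1))
            maps.append(cross_correlation_map(ref, test))
    return mean_correlation_map(maps)


def interval_interference_experiment(
    specs: Sequence[NetworkSpec],
    gap_ms: float,
    master_seed: int,
    n_train_per_class: int = 20,
    n_test_per_class: int = 20,
    n_pulses: int = 5,
    pulse_ms: float = 50.0,
) -> dict:
    """Per-pulse decodability of a pulse train after single-pulse training.

    Trains bin-wise decoders on the 500 ms single-pulse responses, then
    scores the bins of each 50 ms pulse of a pulse train (gap
    ``gap_ms``) with the training bins at the same within-pulse latency
    (bins 0..4 of the single-pulse response).  Returns per-pulse mean
    accuracies per network plus ensemble mean and standard error.
    """
    from .stimuli import make_pulse_train

    train_stim = make_pulse_train(0.5, ONSET_MS, n_pulses, pulse_ms, gap_ms)
    n_latency_bins = int(pulse_ms / BIN_MS)
    per_network = []
    for i, spec in enumerate(specs):
        net = build_network(spec)
        Xtr, ytr = center_ratio_bank(
            net, n_train_per_class, _sub_seed(master_seed, 6, i, 0)
        )
        clf = train_binwise(Xtr, ytr, BIN_MS, seed=_sub_seed(master_seed, 6, i, 2))
        t0, t1 = _bin_window(train_stim.onset, train_stim.end, 0.0, BIN_MS)
        Xte, yte = center_ratio_bank(
            net,
            n_test_per_class,
            _sub_seed(master_seed, 6, i, 1),
            duration_ms=t1 + BIN_MS,
            stim=train_stim,
            window=(t0, t1),
        )
        pulse_acc = []
        for k in range(n_pulses):
            onset_bin = int(round(k * (pulse_ms + gap_ms) / BIN_MS))
            accs = [
                clf.models[j].score(Xte[:, :, onset_bin + j], yte)
                for j in range(n_latency_bins)
            ]
            pulse_acc.append(np.mean(accs))
        per_network.append(pulse_acc)
    per_network = np.array(per_network)
    mean = per_network.mean(axis=0)
    se = (
        per_network.std(axis=0, ddof=1) / np.sqrt(len(specs))
        if len(specs) > 1
        else np.zeros_like(mean)
    )
    return {
        "gap_ms": gap_ms,
        "per_network": per_network,
        "mean": mean,
        "se": se,
        "mean_pulses_2_to_end": float(mean[1:].mean()),
    }


def specificity_experiment(
    specs: Sequence[NetworkSpec],
    code_lengths_ms: Sequence[float],
    master_seed: int,
    n_grid: int = 41,
    half_window: float = 0.25,
) -> dict:
    """Mean bell-curve width vs code length across networks.

    Each network is stimulated once per ratio on an even grid of
    ``n_grid`` ratios (500 ms pulses); widths are averaged over the
    grid, then over networks.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    code_lengths_ms = np.asarray(code_lengths_ms, dtype=float)
    per = np.empty((len(specs), len(code_lengths_ms)))
    for i, spec in enumerate(specs):
        net = build_network(spec)
        stims = [make_pulse(r, ONSET_MS, PULSE_MS) for r in grid]
        cfg = SimulationConfig(
            duration_ms=ONSET_MS + PULSE_MS, seed=_sub_seed(master_seed, 7, i)
        )
        traces = simulate_many(net, stims, cfg)
        rms = [
            bin_responses(tr, BIN_MS, (ONSET_MS, ONSET_MS + PULSE_MS))
            for tr in traces
        ]
        for l, L in enumerate(code_lengths_ms):
            vecs = np.stack([flatten_code(rm, L) for rm in rms])
            per[i, l] = specificity_widths(vecs, grid, half_window).mean()
    mean = per.mean(axis=0)
    se = (
        per.std(axis=0, ddof=1) / np.sqrt(len(specs))
        if len(specs) > 1
        else np.zeros_like(mean)
    )
    return {
        "code_lengths_ms": code_lengths_ms,
        "per_network": per,
        "mean": mean,
        "se": se,
    }


def trajectory_timing_experiment(
    specs: Sequence[NetworkSpec],
    master_seed: int,
    n_repeats: int = 20,
    duration_ms: float = 700.0,
    bin_ms: float = 5.0,
) -> tuple[np.ndarray, list[TimingResult]]:
    """Per-network trajectory-divergence timing over the five ratios.

    500 ms pulses at the five class-centre ratios, ``n_repeats`` noise
    repeats each; returns the per-network argmax times (ms after
    onset) and the full results.
    """
    times = []
    results = []
    n_bins = int(duration_ms / bin_ms)
    for i, spec in enumerate(specs):
        net = build_network(spec)
        per_ratio = []
        for ci, rho in enumerate(RATIO_CENTERS):
            stim = make_pulse(rho, ONSET_MS, PULSE_MS)
            cfg = SimulationConfig(
                duration_ms=duration_ms, seed=_sub_seed(master_seed, 8, i, ci)
            )
            traces = simulate_batch(net, stim, cfg, n_repeats)
            per_bin = int(bin_ms / traces[0].dt)
            arr = np.stack(
                [
                    tr.pn[:, : n_bins * per_bin]
                    .reshape(tr.pn.shape[0], n_bins, per_bin)
                    .mean(axis=2)
                    .T
                    for tr in traces
                ],
                axis=2,
            )  # (n_bins, n_pn, n_repeats)
            per_ratio.append(arr)
        res = trajectory_distance_timing(per_ratio, bin_ms, ONSET_MS)
        results.append(res)
        times.append(res.time_ms)
    return np.array(times), results

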