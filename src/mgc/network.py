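"""Random connectivity of the macroglomerular-complex (MGC) network.

The model network contains 30 projection neurons (PNs, excitatory, split
into two glomeruli of 15) and 30 multiglomerular local neurons (LNs,
inhibitory).  Each of the two olfactory receptor channels drives the PNs
of one glomerulus and all LNs.  Two wiring regimes differ only in the
LN-to-LN inhibitory block:

``fpa``
    fixed-point attractor: all-to-all LN mutual inhibition, producing
    winner-take-all competition and a stationary PN spatial pattern.
``lca``
    limit-cycle attractor: each ordered LN pair is connected
    independently with probability 0.25, producing asymmetric
    competition and switching LN coalitions.

Weights noted "mean ± sd" are drawn from a normal distribution and
sign-rectified: excitatory draws below zero are set to 0, inhibitory
draws above zero are set to 0.  Blocks are drawn in a fixed order
(afferents, PN->PN, LN->PN, PN->LN, LN->LN last) so that the two regimes
built from the same seed share every non-LN-LN block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "NetworkSpec",
    "Network",
    "ConnectivitySummary",
    "build_network",
    "summarize_connectivity",
]

Regime = Literal["fpa", "lca"]


class ConfigurationError(ValueError):
    """Raised for invalid network parameters."""


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of one network realization.

    Connection probabilities and weight distributions follow moth MGC
    morphology; ``seed`` makes construction fully deterministic.
    """

    regime: Regime = "fpa"
    seed: int = 0
    n_pn_per_glomerulus: int = 15
    n_glomeruli: int = 2
    n_ln: int = 30
    p_pn_pn: float = 0.8
    w_pn_pn: tuple[float, float] = (0.0125, 0.1)
    p_ln_pn: float = 0.2
    w_ln_pn: tuple[float, float] = (-2.5, 0.1)
    p_pn_ln: float = 0.5
    w_pn_ln: tuple[float, float] = (0.033, 0.1)
    p_ln_ln: float | None = None  # resolved by regime when None
    w_ln_ln: tuple[float, float] = (-15.0, 0.1)
    w_orn: tuple[float, float] = (1.0, 1.0)
    tau_pn: float = 10.0  # ms
    tau_ln: float = 20.0  # ms

    def __post_init__(self) -> None:
        if self.regime not in ("fpa", "lca"):
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        for name in ("n_pn_per_glomerulus", "n_glomeruli", "n_ln"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("p_pn_pn", "p_ln_pn", "p_pn_ln"):
            _check_prob(name, getattr(self, name))
        if self.p_ln_ln is not None:
            _check_prob("p_ln_ln", self.p_ln_ln)
        for name in ("tau_pn", "tau_ln"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("w_pn_pn", "w_ln_pn", "w_pn_ln", "w_ln_ln", "w_orn"):
            if getattr(self, name)[1] < 0:
                raise ConfigurationError(f"{name} sd must be non-negative")

    @property
    def n_pn(self) -> int:
        return self.n_pn_per_glomerulus * self.n_glomeruli

    @property
    def ln_ln_probability(self) -> float:
        if self.p_ln_ln is not None:
            return self.p_ln_ln
        return 1.0 if self.regime == "fpa" else 0.25

    @property
    def glomerulus_of_pn(self) -> np.ndarray:
        """Channel index of each PN (PNs are grouped by glomerulus)."""
        return np.repeat(np.arange(self.n_glomeruli), self.n_pn_per_glomerulus)


@dataclass
class Network:
    """A realized MGC network: weight blocks plus afferent maps.

    Block shapes are (n_targets, n_sources); block names keep the
    source->target order of the connection they describe (``w_ln_pn`` is
    the LN-onto-PN block, shape (n_pn, n_ln)).  PN- and ORN-sourced
    weights are >= 0, LN-sourced weights are <= 0, diagonals of the
    recurrent blocks are zero.
    """

    spec: NetworkSpec
    w_pn_pn: np.ndarray
    w_ln_pn: np.ndarray
    w_pn_ln: np.ndarray
    w_ln_ln: np.ndarray
    a_orn_pn: np.ndarray
    a_orn_ln: np.ndarray

    @property
    def regime(self) -> Regime:
        return self.spec.regime

    @property
    def n_pn(self) -> int:
        return self.a_orn_pn.shape[0]

    @property
    def n_ln(self) -> int:
        return self.a_orn_ln.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.n_pn + self.n_ln

    def weight_matrix(self) -> np.ndarray:
        """Full (n_neurons, n_neurons) recurrent matrix, PNs first."""
        top = np.hstack([self.w_pn_pn, self.w_ln_pn])
        bottom = np.hstack([self.w_pn_ln, self.w_ln_ln])
        return np.vstack([top, bottom])

    def afferent_matrix(self) -> np.ndarray:
        """Full (n_neurons, n_channels) afferent weight matrix."""
        return np.vstack([self.a_orn_pn, self.a_orn_ln])

    def tau(self) -> np.ndarray:
        """Per-neuron time constants in ms, PNs first."""
        return np.r_[
            np.full(self.n_pn, self.spec.tau_pn),
            np.full(self.n_ln, self.spec.tau_ln),
        ]


def _masked_normal(
    rng: np.random.Generator,
    shape: tuple[int, int],
    prob: float,
    mean_sd: tuple[float, float],
    sign: int,
) -> np.ndarray:
    """Bernoulli(prob) mask times rectified normal draws.

    Mask uniforms and weight normals are always drawn for the full
    block, so the consumed random stream does not depend on ``prob``.
    """
    mask = rng.random(shape) < prob
    w = rng.normal(mean_sd[0], mean_sd[1], shape)
    w = np.maximum(w, 0.0) if sign > 0 else np.minimum(w, 0.0)
    return np.where(mask, w, 0.0)


def build_network(spec: NetworkSpec) -> Network:
    """Draw one network realization from ``spec``.

    Pure function of the spec (including its seed).  Draw order is
    fixed — ORN->PN, ORN->LN, PN->PN, LN->PN, PN->LN, LN->LN — so
    FPA and LCA networks from the same seed differ only in the final
    LN->LN block.
    """
    rng = np.random.default_rng(spec.seed)
    n_pn, n_ln, n_ch = spec.n_pn, spec.n_ln, spec.n_glomeruli

    # Afferents: each PN reads exactly one channel, every LN reads all.
    a_orn_pn = np.zeros((n_pn, n_ch))
    w = np.maximum(rng.normal(*spec.w_orn, n_pn), 0.0)
    a_orn_pn[np.arange(n_pn), spec.glomerulus_of_pn] = w
    a_orn_ln = np.maximum(rng.normal(*spec.w_orn, (n_ln, n_ch)), 0.0)

    # PN->PN: uniglomerular excitation, no autapses.
    w_pn_pn = _masked_normal(rng, (n_pn, n_pn), spec.p_pn_pn, spec.w_pn_pn, +1)
    same_glom = spec.glomerulus_of_pn[:, None] == spec.glomerulus_of_pn[None, :]
    w_pn_pn[~same_glom] = 0.0
    np.fill_diagonal(w_pn_pn, 0.0)

    w_ln_pn = _masked_normal(rng, (n_pn, n_ln), spec.p_ln_pn, spec.w_ln_pn, -1)
    w_pn_ln = _masked_normal(rng, (n_ln, n_pn), spec.p_pn_ln, spec.w_pn_ln, +1)

    # LN->LN drawn last; all-to-all (fpa) vs sparse asymmetric (lca).
    w_ln_ln = _masked_normal(
        rng, (n_ln, n_ln), spec.ln_ln_probability, spec.w_ln_ln, -1
    )
    np.fill_diagonal(w_ln_ln, 0.0)

    return Network(spec, w_pn_pn, w_ln_pn, w_pn_ln, w_ln_ln, a_orn_pn, a_orn_ln)


@dataclass(frozen=True)
class BlockSummary:
    n_nonzero: int
    density: float
    mean_weight: float
    sign_ok: bool


@dataclass(frozen=True)
class ConnectivitySummary:
    """Per-block connection counts, densities and sign checks."""

    blocks: dict[str, BlockSummary] = field(default_factory=dict)

    def all_signs_ok(self) -> bool:
        return all(b.sign_ok for b in self.blocks.values())


def _summ(block: np.ndarray, sign: int, off_diagonal: bool) -> BlockSummary:
    b = block.copy()
    n_possible = b.size
    if off_diagonal:
        np.fill_diagonal(b, np.nan)
        n_possible -= min(b.shape)
    vals = b[~np.isnan(b)]
    nz = vals[vals != 0]
    sign_ok = bool(np.all(vals >= 0) if sign > 0 else np.all(vals <= 0))
    mean = float(nz.mean()) if nz.size else 0.0
    return BlockSummary(int(nz.size), nz.size / n_possible, mean, sign_ok)


def summarize_connectivity(net: Network) -> ConnectivitySummary:
    """Connection counts, off-diagonal densities and sign discipline."""
    return ConnectivitySummary(
        {
            "pn_pn": _summ(net.w_pn_pn, +1, off_diagonal=True),
            "ln_pn": _summ(net.w_ln_pn, -1, off_diagonal=False),
            "pn_ln": _summ(net.w_pn_ln, +1, off_diagonal=False),
            "ln_ln": _summ(net.w_ln_ln, -1, off_diagonal=True),
            "orn_pn": _summ(net.a_orn_pn, +1, off_diagonal=False),
            "orn_ln": _summ(net.a_orn_ln, +1, off_diagonal=False),
        }
    )
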