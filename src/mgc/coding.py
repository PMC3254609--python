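"""Response representations of PN population activity.

The unit of every analysis is the time-binned response matrix R: mean
PN activity in consecutive windows of ``bin_ms`` (10 ms by default).
Columns of R are instantaneous spatial patterns; the flattened matrix
truncated to a code length is the spatiotemporal code vector.  Pattern
similarity is the Pearson correlation coefficient between spatial (or
flattened spatiotemporal) vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import ActivityTrace

__all__ = [
    "ResponseMatrix",
    "CorrelationMap",
    "bin_responses",
    "flatten_code",
    "unflatten_code",
    "correlate_patterns",
    "cross_correlation_map",
]


@dataclass
class ResponseMatrix:
    """Bin-averaged PN activity, shape (n_pn, n_bins).

    ``t_start`` is the trace time of the left edge of the first bin and
    ``onset`` the stimulus onset, so stimulus-locked bin times are
    ``t_start - onset + bin_ms * (j + 0.5)``.
    """

    R: np.ndarray
    bin_ms: float
    t_start: float
    onset: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_pn(self) -> int:
        return self.R.shape[0]

    @property
    def n_bins(self) -> int:
        return self.R.shape[1]

    def bin_times(self) -> np.ndarray:
        """Bin centres relative to stimulus onset (or t_start if none)."""
        ref = self.onset if self.onset is not None else self.t_start
        return self.t_start - ref + self.bin_ms * (np.arange(self.n_bins) + 0.5)

    def column(self, j: int) -> np.ndarray:
        return self.R[:, j]


def bin_responses(
    trace: ActivityTrace,
    bin_ms: float = 10.0,
    window: tuple[float, float] | None = None,
) -> ResponseMatrix:
    """Average PN activity over consecutive ``bin_ms`` windows.

    ``window`` is (start, stop) in trace time; it defaults to stimulus
    onset through the end of the trace.  ``bin_ms`` must tile the
    window exactly and be a multiple of the integration step.
    """
    if window is None:
        start = trace.onset if trace.onset is not None else 0.0
        window = (start, trace.duration_ms)
    t0, t1 = window
    dt = trace.dt
    if t0 < 0 or t1 > trace.duration_ms + 1e-9 or t1 <= t0:
        raise ValueError(f"window {window} outside trace [0, {trace.duration_ms}]")
    per_bin = bin_ms / dt
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError("bin_ms must be a multiple of the trace step")
    per_bin = int(round(per_bin))
    n_bins = (t1 - t0) / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_ms must tile the window exactly")
    n_bins = int(round(n_bins))
    i0 = int(round(t0 / dt))
    seg = trace.pn[:, i0 : i0 + n_bins * per_bin]
    R = seg.reshape(trace.pn.shape[0], n_bins, per_bin).mean(axis=2)
    return ResponseMatrix(R, bin_ms, t0, trace.onset, dict(trace.meta))


def flatten_code(rm: ResponseMatrix, code_ms: float | None = None) -> np.ndarray:
    """Spatiotemporal vector: all elements of R up to ``code_ms``.

    Flattening is PN-major (all bins of PN 1, then PN 2, ...), fixed so
    vectors are comparable across runs; invertible via
    :func:`unflatten_code`.
    """
    if code_ms is None:
        return rm.R.ravel()
    nb = code_ms / rm.bin_ms
    if abs(nb - round(nb)) > 1e-9:
        raise ValueError("code_ms must be a multiple of bin_ms")
    nb = int(round(nb))
    if nb > rm.n_bins:
        raise ValueError("code_ms exceeds the binned window")
    return rm.R[:, :nb].ravel()


def unflatten_code(vec: np.ndarray, n_pn: int) -> np.ndarray:
    """Inverse of :func:`flatten_code`: (n_pn, n_bins) matrix."""
    if vec.size % n_pn:
        raise ValueError("vector length is not a multiple of n_pn")
    return vec.reshape(n_pn, vec.size // n_pn)


def correlate_patterns(r: np.ndarray, r2: np.ndarray) -> float:
    """Pearson correlation between two response vectors.

    Zero-variance vectors (e.g. all-silent pre-stimulus bins) yield 0.0
    rather than an exception; :func:`cross_correlation_map` flags such
    bin pairs separately.
    """
    r = np.asarray(r, dtype=float).ravel()
    r2 = np.asarray(r2, dtype=float).ravel()
    if r.shape != r2.shape:
        raise ValueError("vectors must have equal length")
    x = r - r.mean()
    y = r2 - r2.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


@dataclass
class CorrelationMap:
    """Correlation over (reference bin, test bin) pairs.

    ``values[i, j]`` is the correlation between reference bin ``i`` and
    test bin ``j``; ``degenerate[i, j]`` marks pairs where at least one
    pattern had zero variance (value reported as 0).
    """

    values: np.ndarray
    degenerate: np.ndarray
    ref_times: np.ndarray
    test_times: np.ndarray


def cross_correlation_map(
    r_ref: ResponseMatrix, r_test: ResponseMatrix
) -> CorrelationMap:
    """Correlate every reference spatial pattern with every test pattern.

    When maps from several stimuli or networks are combined, the
    arithmetic mean of coefficients is used (see
    :func:`mgc.experiments.mean_correlation_map`).
    """
    if r_ref.n_pn != r_test.n_pn:
        raise ValueError("PN dimensions differ")
    A = r_ref.R - r_ref.R.mean(axis=0, keepdims=True)
    B = r_test.R - r_test.R.mean(axis=0, keepdims=True)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    degen = (na[:, None] == 0.0) | (nb[None, :] == 0.0)
    denom = np.where(degen, 1.0, na[:, None] * nb[None, :])
    vals = np.clip((A.T @ B) / denom, -1.0, 1.0)
    vals[degen] = 0.0
    return CorrelationMap(vals, degen, r_ref.bin_times(), r_test.bin_times())
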