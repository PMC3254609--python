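"""Decoding and geometry analyses of PN population responses.

Covers the ratio-class decoders (per-time-bin and spatiotemporal
PCA+LDA pipelines), the bell-curve specificity width of the ratio
tuning of the population code, and the timing of maximal divergence
between ratio-specific PCA trajectories.

Ratio classes
-------------
Blend ratios are grouped into five classes centred on
0, 0.25, 0.5, 0.75 and 1 with half-width 0.125; boundaries round half
up toward the larger centre.  Chance level for balanced classes is 20%.

Decoders
--------
Every classifier is PCA (retaining >= 90% variance, fit on training
data only) followed by linear discriminant analysis.  PCA is required
because the within-class covariance of raw patterns is typically rank
deficient.  Training bins whose patterns carry no variance at all
(e.g. all-silent pre-stimulus bins) are flagged uninformative and
predict at chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "RATIO_CENTERS",
    "CLASS_HALF_WIDTH",
    "ratio_class",
    "BinwiseClassifier",
    "train_binwise",
    "cross_classification_map",
    "CodeLengthAccuracy",
    "accuracy_vs_code_length",
    "bell_curve_width",
    "specificity_widths",
    "TimingResult",
    "trajectory_distance_timing",
    "compare_timing",
    "AttractorReport",
    "detect_attractor",
]

RATIO_CENTERS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
CLASS_HALF_WIDTH = 0.125


class DegenerateTrajectories(ValueError):
    """Raised when trajectory distances carry no signal."""


def ratio_class(rho: float) -> int:
    """Class label (0..4) of the centre within 0.125 of ``rho``.

    Boundary ties (e.g. rho = 0.125) round half up toward the larger
    centre — a fixed, measure-zero convention.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"ratio must lie in [0, 1], got {rho}")
    return int(np.floor(rho / 0.25 + 0.5))


# ---------------------------------------------------------------------------
# PCA + LDA building block


class _PcaLda:
    """PCA to >= ``var`` explained variance, then LDA, on one feature set."""

    def __init__(self, var: float = 0.9, seed: int = 0):
        self.var = var
        self.seed = seed
        self.uninformative = False
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PcaLda":
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training requires at least two classes")
        if np.allclose(X.var(axis=0), 0.0):
            self.uninformative = True
            return self
        self.pca = PCA(n_components=self.var, svd_solver="full").fit(X)
        Z = self.pca.transform(X)
        try:
            self.lda = LinearDiscriminantAnalysis().fit(Z, y)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular within-class covariance; falling back to a "
                "shrinkage-regularized discriminant",
                RuntimeWarning,
                stacklevel=2,
            )
            self.lda = LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage="auto"
            ).fit(Z, y)
        return self

    @property
    def n_components(self) -> int:
        return 0 if self.uninformative else int(self.pca.n_components_)

    @property
    def explained_variance(self) -> float:
        if self.uninformative:
            return 0.0
        return float(self.pca.explained_variance_ratio_.sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.uninformative:
            rng = np.random.default_rng(self.seed)
            return rng.choice(self.classes_, size=X.shape[0])
        return self.lda.predict(self.pca.transform(X))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == y))


# ---------------------------------------------------------------------------
# Bin-wise classification (classification maps)


@dataclass
class BinwiseClassifier:
    """One reduced-space linear discriminant per training time-bin."""

    models: list[_PcaLda]
    bin_ms: float
    bin_times: np.ndarray
    n_train: int

    @property
    def n_bins(self) -> int:
        return len(self.models)

    def uninformative_bins(self) -> np.ndarray:
        return np.array([m.uninformative for m in self.models])

    def retained_variance(self) -> np.ndarray:
        return np.array([m.explained_variance for m in self.models])


def _stack_patterns(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 3:
        raise ValueError("expected (n_samples, n_pn, n_bins) response array")
    return X


def train_binwise(
    X: np.ndarray,
    y: np.ndarray,
    bin_ms: float = 10.0,
    var: float = 0.9,
    seed: int = 0,
    bin_times: np.ndarray | None = None,
) -> BinwiseClassifier:
    """Fit one PCA+LDA decoder on the spatial patterns of each time-bin.

    ``X`` is (n_samples, n_pn, n_bins); ``y`` the class labels.  Needs
    at least two classes with two samples each.
    """
    X = _stack_patterns(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least two samples")
    models = [
        _PcaLda(var, seed=seed + j).fit(X[:, :, j], y) for j in range(X.shape[2])
    ]
    if bin_times is None:
        bin_times = bin_ms * (np.arange(X.shape[2]) + 0.5)
    return BinwiseClassifier(models, bin_ms, np.asarray(bin_times), len(y))


def cross_classification_map(
    clf: BinwiseClassifier, X_test: np.ndarray, y_test: np.ndarray
) -> np.ndarray:
    """Accuracy of each training-bin model on each test bin.

    ``map[i, j]`` is the fraction of test stimuli whose bin-``j``
    pattern the bin-``i`` model assigns to its true class.
    """
    X_test = _stack_patterns(X_test)
    y_test = np.asarray(y_test)
    n_test_bins = X_test.shape[2]
    out = np.empty((clf.n_bins, n_test_bins))
    for i, m in enumerate(clf.models):
        for j in range(n_test_bins):
            out[i, j] = m.score(X_test[:, :, j], y_test)
    return out


# ---------------------------------------------------------------------------
# Spatiotemporal code: accuracy vs code length


@dataclass
class CodeLengthAccuracy:
    """Mean test accuracy (with se across networks) per code length."""

    code_lengths_ms: np.ndarray
    accuracy: np.ndarray  # (n_lengths,)
    se: np.ndarray
    per_network: np.ndarray  # (n_networks, n_lengths)

    def plateau(self, from_ms: float = 100.0) -> float:
        """Mean accuracy over code lengths >= ``from_ms``."""
        sel = self.code_lengths_ms >= from_ms
        return float(self.accuracy[sel].mean())


def _flatten_bank(X: np.ndarray, n_bins: int) -> np.ndarray:
    return X[:, :, :n_bins].reshape(X.shape[0], -1)


def accuracy_vs_code_length(
    banks: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    code_lengths_ms: np.ndarray,
    bin_ms: float = 10.0,
    var: float = 0.9,
    seed: int = 0,
) -> CodeLengthAccuracy:
    """PCA+LDA accuracy on flattened codes truncated to each length.

    ``banks`` holds one (X_train, y_train, X_test, y_test) tuple per
    network, X arrays shaped (n_samples, n_pn, n_bins).  Code length 0
    carries no information and scores at chance.
    """
    code_lengths_ms = np.asarray(code_lengths_ms, dtype=float)
    per = np.empty((len(banks), len(code_lengths_ms)))
    for b, (Xtr, ytr, Xte, yte) in enumerate(banks):
        for l, L in enumerate(code_lengths_ms):
            nb = int(round(L / bin_ms))
            if nb == 0:
                m = _PcaLda(var, seed=seed + 17 * b)
                m.fit(np.zeros((len(ytr), 1)), np.asarray(ytr))
                per[b, l] = m.score(np.zeros((len(yte), 1)), np.asarray(yte))
                continue
            m = _PcaLda(var, seed=seed + 17 * b + l)
            m.fit(_flatten_bank(np.asarray(Xtr), nb), np.asarray(ytr))
            per[b, l] = m.score(_flatten_bank(np.asarray(Xte), nb), np.asarray(yte))
    acc = per.mean(axis=0)
    se = per.std(axis=0, ddof=1) / np.sqrt(len(banks)) if len(banks) > 1 else np.zeros_like(acc)
    return CodeLengthAccuracy(code_lengths_ms, acc, se, per)


# ---------------------------------------------------------------------------
# Ratio specificity: bell-curve width


def bell_curve_width(
    grid: np.ndarray,
    correlations: np.ndarray,
    rho: float,
    half_window: float = 0.25,
) -> float:
    """RMS width of the correlation-vs-ratio curve about its peak.

    ``correlations[j]`` is the correlation between the response to
    ``rho`` and the response to ``grid[j]``.  The width is the square
    root of the normalized second moment of the positively rectified
    curve over a window of ``half_window`` around ``rho``; near the
    boundaries (rho < 0.25 or rho > 0.75) the window is one-sided
    (towards the interior) to avoid running off [0, 1].
    """
    grid = np.asarray(grid, dtype=float)
    correlations = np.asarray(correlations, dtype=float)
    if grid.shape != correlations.shape:
        raise ValueError("grid and correlations must align")
    if rho < 0.25:
        lo, hi = rho, rho + half_window
    elif rho > 0.75:
        lo, hi = rho - half_window, rho
    else:
        lo, hi = rho - half_window, rho + half_window
    eps = 1e-9
    if grid.min() > lo + eps or grid.max() < hi - eps:
        raise ValueError("ratio grid does not cover the integration window")
    sel = (grid >= lo - eps) & (grid <= hi + eps)
    c = np.clip(correlations[sel], 0.0, None)
    mass = c.sum()
    if mass == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((grid[sel] - rho) ** 2 * c) / mass))


def specificity_widths(
    vectors: np.ndarray,
    grid: np.ndarray,
    half_window: float = 0.25,
) -> np.ndarray:
    """Bell-curve width at every grid ratio from a bank of code vectors.

    ``vectors[j]`` is the flattened spatiotemporal response to ratio
    ``grid[j]`` (already truncated to the code length under study).
    """
    from .coding import correlate_patterns

    vectors = np.asarray(vectors, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n = len(grid)
    C = np.empty((n, n))
    for i in range(n):
        C[i, i] = 1.0
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = correlate_patterns(vectors[i], vectors[j])
    return np.array(
        [bell_curve_width(grid, C[i], grid[i], half_window) for i in range(n)]
    )


# ---------------------------------------------------------------------------
# Trajectory divergence timing


@dataclass
class TimingResult:
    """Time of maximal mean pairwise trajectory distance, one network."""

    time_ms: float  # relative to stimulus onset
    distance: np.ndarray  # mean pairwise distance at each bin
    bin_times: np.ndarray  # bin centres relative to onset
    pca_components: np.ndarray = field(repr=False, default=None)


def trajectory_distance_timing(
    ratio_trajectories: list[np.ndarray],
    bin_ms: float = 5.0,
    onset_ms: float = 100.0,
    n_components: int = 3,
) -> TimingResult:
    """Divergence timing of ratio-specific PN trajectories.

    ``ratio_trajectories[r]`` is the binned PN activity for ratio ``r``,
    shape (n_bins, n_pn, n_repeats), all ratios sharing the bin grid
    (bins of ``bin_ms`` from trace time 0).  A single PCA (fit on all
    ratios, repeats and bins pooled) projects activity to
    ``n_components`` dimensions; repeat-averaged trajectories are
    compared by Euclidean distance, averaged over all ratio pairs, and
    the time of the maximum at or after stimulus onset is returned
    (relative to onset).
    """
    if len(ratio_trajectories) < 2:
        raise DegenerateTrajectories("need at least two ratios")
    n_bins, n_pn, _ = ratio_trajectories[0].shape
    pooled = np.concatenate(
        [tr.transpose(0, 2, 1).reshape(-1, n_pn) for tr in ratio_trajectories]
    )
    pca = PCA(n_components=n_components).fit(pooled)
    means = [pca.transform(tr.mean(axis=2)) for tr in ratio_trajectories]

    n_r = len(means)
    dist = np.zeros(n_bins)
    n_pairs = 0
    for i in range(n_r):
        for j in range(i + 1, n_r):
            dist += np.linalg.norm(means[i] - means[j], axis=1)
            n_pairs += 1
    dist /= n_pairs

    bin_centres = bin_ms * (np.arange(n_bins) + 0.5)
    sel = bin_centres >= onset_ms
    if not sel.any():
        raise ValueError("no bins at or after stimulus onset")
    if dist[sel].max() < 1e-12:
        raise DegenerateTrajectories("trajectories are identical")
    k = int(np.argmax(dist[sel]))
    t_max = bin_centres[sel][k] - onset_ms
    return TimingResult(float(t_max), dist, bin_centres - onset_ms, pca.components_)


# ---------------------------------------------------------------------------
# Long-run attractor detection


@dataclass
class AttractorReport:
    """Outcome of the stationarity/periodicity check on a long run."""

    kind: str  # "fixed_point", "periodic" or "none"
    onset_ms: float | None  # time the attractor is reached (trace time)
    period_ms: float | None
    n_active: int  # units above ``active_level`` in the final state


def detect_attractor(
    activity: np.ndarray,
    dt: float = 1.0,
    search_start_ms: float = 100.0,
    bin_ms: float = 20.0,
    tol: float = 0.05,
    active_level: float = 0.05,
    max_period_ms: float = 1000.0,
) -> AttractorReport:
    """Classify the late dynamics of a (n_units, T) activity array.

    Fixed point: the ``bin_ms``-binned pattern stays within ``tol``
    (max-abs) of the final pattern from some onset on.  Periodic orbit:
    the late trajectory matches itself shifted by a period (best
    normalized autocorrelation > 0.95 over lags up to
    ``max_period_ms``), with the onset found the same way against the
    shifted trace.  ``tol`` absorbs the firing-rate noise.
    """
    act = np.asarray(activity, dtype=float).T  # (T, n)
    per = int(round(bin_ms / dt))
    nb = act.shape[0] // per
    B = act[: nb * per].reshape(nb, per, -1).mean(axis=1)
    start_bin = int(search_start_ms / bin_ms)

    final = B[-max(5, nb // 10) :].mean(axis=0)
    dev = np.abs(B - final).max(axis=1)
    bad = np.where(dev[start_bin:] > tol)[0]
    n_active = int((final > active_level).sum())
    if bad.size == 0:
        return AttractorReport("fixed_point", start_bin * bin_ms, None, n_active)
    if bad[-1] + 1 + start_bin < nb:
        onset = (bad[-1] + 1 + start_bin) * bin_ms
        return AttractorReport("fixed_point", float(onset), None, n_active)

    # Periodicity: autocorrelation of the mean-subtracted late half.
    late = B[nb // 2 :]
    x = late - late.mean(axis=0)
    if np.linalg.norm(x) < 1e-9:
        return AttractorReport("none", None, None, n_active)
    max_lag = int(max_period_ms / bin_ms)
    lags = range(2, min(max_lag, len(x) - 2) + 1)  # >= 2 bins to skip smoothness
    cs = {}
    for lag in lags:
        a, b = x[:-lag].ravel(), x[lag:].ravel()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        if denom > 0:
            cs[lag] = float(a @ b / denom)
    # the fundamental period is the smallest strongly matching lag
    # (the global max can land on a harmonic)
    best_lag = next((lag for lag in lags if cs.get(lag, -1.0) > 0.95), None)
    best_c = cs.get(best_lag, -1.0)
    if best_lag is not None and best_c > 0.95 and best_lag * bin_ms >= 2 * bin_ms:
        shift = best_lag
        dev_p = np.abs(B[:-shift] - B[shift:]).max(axis=1)
        bad_p = np.where(dev_p[start_bin:] > tol)[0]
        if bad_p.size == 0:
            onset = start_bin * bin_ms
        elif bad_p[-1] + 1 + start_bin < len(dev_p):
            onset = (bad_p[-1] + 1 + start_bin) * bin_ms
        else:
            return AttractorReport("none", None, None, n_active)
        return AttractorReport(
            "periodic", float(onset), best_lag * bin_ms, n_active
        )
    return AttractorReport("none", None, None, n_active)


def compare_timing(times_a: np.ndarray, times_b: np.ndarray) -> dict:
    """Welch t-test between two samples of per-network divergence times."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    t, p = stats.ttest_ind(times_a, times_b, equal_var=False)
    return {
        "mean_a": float(times_a.mean()),
        "sd_a": float(times_a.std(ddof=1)),
        "mean_b": float(times_b.mean()),
        "sd_b": float(times_b.std(ddof=1)),
        "t": float(t),
        "p": float(p),
    }
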