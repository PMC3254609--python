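"""Decoders, specificity widths, trajectory timing, attractor detector."""

import numpy as np
import pytest

from mgc import (
    accuracy_vs_code_length,
    bell_curve_width,
    compare_timing,
    cross_classification_map,
    detect_attractor,
    ratio_class,
    specificity_widths,
    train_binwise,
    trajectory_distance_timing,
)
from mgc.analysis import DegenerateTrajectories, _PcaLda


class TestRatioClass:
    @pytest.mark.parametrize(
        "rho,label",
        [
            (0.0, 0),
            (0.30, 1),
            (0.5, 2),
            (0.874, 3),
            (1.0, 4),
            (0.125, 1),  # boundary rounds half up toward the larger centre
            (0.375, 2),
            (0.625, 3),
            (0.875, 4),
        ],
    )
    def test_examples(self, rho, label):
        assert ratio_class(rho) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ratio_class(1.1)
        with pytest.raises(ValueError):
            ratio_class(-0.01)


def cluster_bank(rng, n_per=20, n_bins=4, sep=10.0, spread=1.0):
    """Five well-separated Gaussian clusters per bin: (X, y)."""
    centers = rng.normal(size=(5, 30)) * sep
    X = np.empty((5 * n_per, 30, n_bins))
    y = np.repeat(np.arange(5), n_per)
    for j in range(n_bins):
        for c in range(5):
            X[y == c, :, j] = centers[c] + spread * rng.normal(size=(n_per, 30))
    return X, y


class TestBinwiseClassifier:
    def test_separated_clusters_classify_perfectly(self, rng):
        X, y = cluster_bank(rng)
        clf = train_binwise(X, y)
        m = cross_classification_map(clf, X, y)
        np.testing.assert_array_equal(np.diag(m), 1.0)
        assert np.all(clf.retained_variance() >= 0.9)

    def test_all_zero_bins_flagged_uninformative_and_score_chance(self, rng):
        X, y = cluster_bank(rng, n_per=40, n_bins=2)
        X[:, :, 0] = 0.0  # silent pre-stimulus bin
        clf = train_binwise(X, y)
        assert clf.uninformative_bins().tolist() == [True, False]
        m = cross_classification_map(clf, X, y)
        chance_sd = np.sqrt(0.2 * 0.8 / len(y))
        assert m[0, 0] == pytest.approx(0.2, abs=3 * chance_sd)

    def test_shuffled_labels_score_at_chance(self, rng):
        """Chance-level calibration: ~20% for 5 balanced classes."""
        X, y = cluster_bank(rng, n_per=60, n_bins=3)
        y_shuf = rng.permutation(y)
        clf = train_binwise(X, y_shuf)
        m = cross_classification_map(clf, X, y_shuf)
        chance_sd = np.sqrt(0.2 * 0.8 / len(y))
        assert np.all(np.abs(m - 0.2) < 3 * chance_sd + 0.05)

    def test_single_class_rejected(self, rng):
        X = rng.random((10, 30, 2))
        with pytest.raises(ValueError):
            train_binwise(X, np.zeros(10))


class TestPcaLdaOracle:
    def test_matches_closed_form_two_class_discriminant(self, rng):
        """Pipeline equals the textbook pooled-covariance LDA boundary.

        2-D Gaussian classes with equal priors; the first principal
        component explains < 90% variance so PCA keeps both dimensions
        and the pipeline must reproduce the closed-form rule
        sign(w . (x - (m0+m1)/2)) with w = S_pooled^-1 (m1 - m0).
        """
        n = 200
        X0 = rng.normal(size=(n, 2)) * 1.5
        X1 = rng.normal(size=(n, 2)) * 1.5 + np.array([3.0, 0.0])
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n), np.ones(n)]
        model = _PcaLda(var=0.9).fit(X, y)
        assert model.n_components == 2

        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        S = (
            (X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)
        ) / (2 * n - 2)
        w = np.linalg.solve(S, m1 - m0)
        Xt = rng.normal(size=(500, 2)) * 2 + np.array([1.5, 0.0])
        oracle = (Xt - (m0 + m1) / 2) @ w > 0
        np.testing.assert_array_equal(model.predict(Xt), oracle.astype(float))


class TestCodeLength:
    def test_zero_code_length_scores_chance(self, rng):
        X, y = cluster_bank(rng, n_per=60, n_bins=2)
        res = accuracy_vs_code_length([(X, y, X, y)], [0.0, 20.0], bin_ms=10.0)
        chance_sd = np.sqrt(0.2 * 0.8 / len(y))
        assert res.accuracy[0] == pytest.approx(0.2, abs=3 * chance_sd)
        assert res.accuracy[1] == 1.0


class TestBellCurveWidth:
    def test_delta_curve_has_zero_width(self):
        grid = np.linspace(0, 1, 41)
        c = np.zeros(41)
        c[20] = 1.0
        assert bell_curve_width(grid, c, 0.5) == 0.0

    def test_flat_curve_equals_window_second_moment(self):
        """c == 1: width is the RMS second moment of the window itself."""
        grid = np.linspace(0, 1, 41)
        c = np.ones(41)
        w = bell_curve_width(grid, c, 0.5)
        sel = np.abs(grid - 0.5) <= 0.25 + 1e-9
        expected = np.sqrt(np.mean((grid[sel] - 0.5) ** 2))
        assert w == pytest.approx(expected, abs=1e-12)

    def test_one_sided_windows_near_boundaries(self):
        grid = np.linspace(0, 1, 41)
        c = np.ones(41)
        w0 = bell_curve_width(grid, c, 0.0)
        sel = (grid >= 0) & (grid <= 0.25 + 1e-9)
        assert w0 == pytest.approx(np.sqrt(np.mean(grid[sel] ** 2)), abs=1e-12)
        w1 = bell_curve_width(grid, c, 1.0)
        assert w1 == pytest.approx(w0, abs=1e-12)

    def test_insufficient_grid_coverage_raises(self):
        grid = np.linspace(0.4, 0.6, 9)
        with pytest.raises(ValueError):
            bell_curve_width(grid, np.ones(9), 0.5)

    def test_specificity_widths_sharp_bank_narrower_than_flat(self, rng):
        grid = np.linspace(0, 1, 21)
        sharp = np.eye(21) + 0.01 * rng.random((21, 21))  # dissimilar ratios
        smooth = np.outer(np.ones(21), np.arange(21.0)) + rng.random((21, 21))
        ws = specificity_widths(sharp, grid)
        wf = specificity_widths(smooth, grid)
        assert ws.mean() < wf.mean()


class TestTrajectoryTiming:
    def synthetic(self, peak_bin, n_bins=140, n_pn=30, n_rep=4, rng=None):
        """Two ratio trajectories whose separation peaks at a known bin."""
        rng = rng or np.random.default_rng(0)
        sep = np.exp(-0.5 * ((np.arange(n_bins) - peak_bin) / 10.0) ** 2)
        base = rng.random(n_pn)
        d = rng.normal(size=n_pn)
        d /= np.linalg.norm(d)
        out = []
        for sign in (+1, -1):
            tr = base[None, :] + sign * 0.5 * sep[:, None] * d[None, :]
            out.append(
                np.repeat(tr[:, :, None], n_rep, axis=2)
                + 1e-4 * rng.normal(size=(n_bins, n_pn, n_rep))
            )
        return out

    def test_recovers_known_divergence_peak(self):
        trajs = self.synthetic(peak_bin=60)  # bin 60 -> 302.5 ms, onset 100
        res = trajectory_distance_timing(trajs, bin_ms=5.0, onset_ms=100.0)
        assert res.time_ms == pytest.approx(302.5 - 100.0, abs=10.0)

    def test_identical_trajectories_signalled(self, rng):
        tr = rng.random((40, 30, 3))
        with pytest.raises(DegenerateTrajectories):
            trajectory_distance_timing([tr, tr.copy()], 5.0, 100.0)
        with pytest.raises(DegenerateTrajectories):
            trajectory_distance_timing([tr], 5.0, 100.0)

    def test_compare_timing_detects_shift(self, rng):
        a = rng.normal(300, 30, 20)
        b = rng.normal(150, 30, 20)
        res = compare_timing(a, b)
        assert res["mean_a"] > res["mean_b"]
        assert res["p"] < 0.01


class TestAttractorDetector:
    def test_fixed_point_with_onset(self, rng):
        T, n = 3000, 10
        x = np.zeros((n, T))
        x[:, :1000] = rng.random((n, 1000))  # wandering first second
        x[:, 1000:] = 0.6 + 1e-3 * rng.normal(size=(n, 2000))
        rep = detect_attractor(x, search_start_ms=100)
        assert rep.kind == "fixed_point"
        assert 900 <= rep.onset_ms <= 1200
        assert rep.n_active == n

    def test_periodic_orbit_detected_with_period(self):
        T, n = 4000, 6
        t = np.arange(T)
        phases = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x = 0.4 + 0.3 * np.sin(2 * np.pi * t[None, :] / 200.0 + phases[:, None])
        rep = detect_attractor(x, search_start_ms=100)
        assert rep.kind == "periodic"
        assert rep.period_ms == pytest.approx(200.0, abs=20.0)

    def test_drifting_trace_is_neither(self, rng):
        x = np.cumsum(rng.normal(size=(5, 4000)), axis=1) / 50.0
        rep = detect_attractor(x, search_start_ms=100)
        assert rep.kind == "none"
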