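"""ON/OFF calling: spline velocities and the thresholded labeling rule."""

import numpy as np
import pytest

from figr.model import ExpressionDataset
from figr.onoff import (
    ClassifierOptions,
    StateLabels,
    classify_state,
    estimate_velocities,
    label_dataset,
    resolve_thresholds,
)
from figr.synthetic import SyntheticConfig, random_circuit, sample_trajectories


def _dataset(series, times=None):
    series = np.asarray(series, dtype=float)
    times = np.linspace(0, 2, series.shape[-1]) if times is None else times
    return ExpressionDataset(times=times, X=series.reshape(1, -1, 1))


class TestEstimateVelocities:
    def test_exponential_rise_derivative_at_origin(self):
        t = np.linspace(0, 2, 21)
        v = estimate_velocities(_dataset(1 - np.exp(-t), t))
        # true derivative e^{-t}; spline end-derivative within 5%
        assert v[0, 0, 0] == pytest.approx(1.0, rel=0.05)
        assert np.allclose(v[0, 5:15, 0], np.exp(-t[5:15]), rtol=0.05)

    def test_constant_series_has_zero_velocity(self):
        v = estimate_velocities(_dataset(np.full(21, 0.7)))
        np.testing.assert_allclose(v, 0.0, atol=1e-10)

    def test_linear_series_reproduced_exactly(self):
        t = np.linspace(0, 2, 21)
        v = estimate_velocities(_dataset(2 * t, t))
        np.testing.assert_allclose(v, 2.0, atol=1e-9)

    def test_too_few_timepoints_is_an_error(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            estimate_velocities(_dataset([0.0, 1.0]))

    def test_gcv_smoothing_recovers_trend_under_noise(self, rng):
        t = np.linspace(0, 2, 41)
        x = np.clip(1 - np.exp(-t) + rng.normal(0, 0.02, t.size), 0, None)
        v = estimate_velocities(_dataset(x, t),
                                ClassifierOptions(spline_smoothing=None))
        # smoothed derivative keeps the sign of the true trend
        assert np.mean(np.sign(v[0, :, 0]) == 1) > 0.9


class TestClassifyState:
    OPTS = ClassifierOptions(v_thresh=np.array([0.1]), x_thresh=np.array([0.5]))

    @pytest.mark.parametrize("x,v,expected", [
        (0.2, 0.5, 1),     # fast rise: velocity branch ON
        (0.9, 0.01, 1),    # slow, high expression: expression branch ON
        (0.1, -0.01, -1),  # slow, low expression: both branches agree OFF
        (0.2, -0.5, -1),   # fast fall: velocity branch OFF
        (0.5, 0.01, 1),    # x == x_gc tie resolves ON (sgn(0) = +1)
        (0.2, 0.1, 1),     # |v| == v_gc boundary uses the velocity branch
        (0.9, -0.1, -1),   # ... even when the expression branch disagrees
    ])
    def test_threshold_rule(self, x, v, expected):
        assert classify_state(x, v, 0, self.OPTS) == expected


class TestLabelDataset:
    def test_labels_match_hyperplane_sign_on_noiseless_circuit(self, rng,
                                                               two_gene_circuit):
        """On clean simulated data the called state equals the ground-truth
        hyperplane side sgn(T_g . x + h_g) almost everywhere."""
        cfg = SyntheticConfig(G=2, N=20, Nt=21)
        data = sample_trajectories(two_gene_circuit, cfg, rng)
        labels = label_dataset(data)
        P = data.N * data.Nt
        pts = data.X.reshape(P, 2)
        for g in range(2):
            truth = np.where(pts @ two_gene_circuit.T[g]
                             + two_gene_circuit.h[g] >= 0, 1, -1)
            agree = np.mean(labels.y[:, :, g].reshape(P) == truth)
            assert agree >= 0.95

    def test_all_zero_dataset_labels_off(self):
        data = ExpressionDataset(times=np.linspace(0, 2, 11),
                                 X=np.zeros((3, 11, 2)))
        opts = ClassifierOptions(x_thresh=np.array([0.5, 0.5]))
        labels = label_dataset(data, opts)
        assert np.all(labels.y == -1)

    def test_traveling_domain_is_tracked(self):
        """A spatial toy with one traveling ON domain: the labeled ON region
        follows the synthesis domain."""
        from figr.model import SpatialDataset
        nuc = np.arange(30)
        times = np.linspace(0, 8, 9)
        X = np.zeros((30, 9, 1))
        for j, t in enumerate(times):
            center = 8 + t  # domain drifts posteriorly
            X[:, j, 0] = np.exp(-0.5 * ((nuc - center) / 3.0) ** 2)
        ds = SpatialDataset(positions=nuc.astype(float), times=times, X=X)
        labels = label_dataset(ds)
        on_centers = [np.mean(np.nonzero(labels.y[:, j, 0] == 1)[0])
                      for j in range(1, 9)]
        assert np.all(np.diff(on_centers) > 0)  # ON region moves with domain

    def test_labels_invariant_under_time_rescaling(self, rng, two_gene_circuit):
        cfg = SyntheticConfig(G=2, N=5, Nt=21)
        data = sample_trajectories(two_gene_circuit, cfg, rng)
        a = label_dataset(data)
        scaled = ExpressionDataset(times=data.times * 10.0, X=data.X)
        b = label_dataset(scaled)  # fractional thresholds rescale with time
        np.testing.assert_array_equal(a.y, b.y)


def test_resolved_thresholds_are_scale_free_fractions(rng, two_gene_circuit):
    cfg = SyntheticConfig(G=2, N=5, Nt=21)
    data = sample_trajectories(two_gene_circuit, cfg, rng)
    v = estimate_velocities(data)
    opts = resolve_thresholds(data, v, ClassifierOptions())
    np.testing.assert_allclose(
        opts.v_thresh, 0.01 * np.max(np.abs(v), axis=(0, 1)))
    np.testing.assert_allclose(
        opts.x_thresh, 0.2 * np.max(data.X, axis=(0, 1)))


def test_state_labels_validate_shape_and_values():
    with pytest.raises(ValueError):
        StateLabels(y=np.array([1, 0]), v=np.zeros(2))
    with pytest.raises(ValueError):
        StateLabels(y=np.ones((2, 2)), v=np.zeros(3))
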