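"""Kinetic-parameter estimators: slope, analytic and kink methods."""

import numpy as np
import pytest

from figr.kinetics import (
    KinkFit,
    infer_kinetics_analytic,
    infer_kinetics_kink,
    infer_kinetics_slope,
    switch_exclusion_mask,
)
from figr.model import SpatialDataset


class TestSlopeMethod:
    def test_off_branch_exact(self):
        t = np.linspace(0, 2, 21)
        lam = 0.7
        x = 3.0 * np.exp(-lam * t)
        v = -lam * x
        y = -np.ones_like(x, dtype=int)
        with pytest.warns(RuntimeWarning, match="no ON"):
            R, lam_hat = infer_kinetics_slope(x, v, y, exclude_k=0)
        assert lam_hat == pytest.approx(0.7, abs=1e-6)
        assert np.isnan(R)

    def test_on_branch_exact(self):
        t = np.linspace(0, 2, 21)
        R_true, lam_true = 1.5, 0.5
        x = (R_true / lam_true) * (1 - np.exp(-lam_true * t))
        v = R_true - lam_true * x
        y = np.ones_like(x, dtype=int)
        with pytest.warns(RuntimeWarning, match="no OFF"):
            R, lam = infer_kinetics_slope(x, v, y, exclude_k=0)
        assert R == pytest.approx(1.5, abs=1e-6)
        assert lam == pytest.approx(0.5, abs=1e-6)

    def test_mixed_branches_exact_with_true_velocities(self):
        """With exact velocities and correct labels the overdetermined
        system is consistent, so least squares recovers (R, lam) to
        machine precision."""
        rng = np.random.default_rng(3)
        R_true, lam_true = 1.2, 0.9
        x = rng.uniform(0, R_true / lam_true, 100)
        y = rng.choice([-1, 1], 100)
        v = np.where(y == 1, R_true - lam_true * x, -lam_true * x)
        R, lam = infer_kinetics_slope(x, v, y, exclude_k=0)
        assert R == pytest.approx(R_true, abs=1e-10)
        assert lam == pytest.approx(lam_true, abs=1e-10)

    def test_switch_exclusion_improves_spline_based_recovery(self):
        """One ON->OFF switch: spline velocities are worst near the switch;
        dropping 2 points on each side gets closer to the truth."""
        from figr.model import ExpressionDataset
        from figr.onoff import estimate_velocities
        R_true, lam_true = 1.5, 1.0
        t = np.linspace(0, 2, 21)
        t_sw = 1.0
        x_on = (R_true / lam_true) * (1 - np.exp(-lam_true * t))
        x_sw = (R_true / lam_true) * (1 - np.exp(-lam_true * t_sw))
        x = np.where(t < t_sw, x_on, x_sw * np.exp(-lam_true * (t - t_sw)))
        ds = ExpressionDataset(times=t, X=x.reshape(1, -1, 1))
        v = estimate_velocities(ds)[0, :, 0]
        y = np.where(t < t_sw, 1, -1)
        err = {}
        for k in (0, 2):
            R, lam = infer_kinetics_slope(x, v, y, exclude_k=k)
            err[k] = abs(R - R_true) + abs(lam - lam_true)
        assert err[2] < err[0]

    def test_empty_after_exclusion_is_an_error(self):
        x = np.array([0.1, 0.2, 0.3, 0.2, 0.1])
        y = np.array([1, -1, 1, -1, 1])
        with pytest.raises(ValueError, match="no observations"):
            infer_kinetics_slope(x, np.zeros(5), y, exclude_k=3)

    def test_exclusion_mask_windows(self):
        y = np.array([[1, 1, 1, -1, -1, -1, -1]])
        mask = switch_exclusion_mask(y, 2)
        np.testing.assert_array_equal(
            mask[0], [True, False, False, False, False, True, True])


class TestAnalyticMethod:
    def test_noiseless_single_segment_exact(self):
        t = np.linspace(0, 2, 21)
        R_true, lam_true = 1.4, 0.6
        x = (R_true / lam_true) * (1 - np.exp(-lam_true * t))
        R, lam = infer_kinetics_analytic(x, np.ones(21, dtype=int), t)
        assert R == pytest.approx(R_true, rel=1e-6)
        assert lam == pytest.approx(lam_true, rel=1e-6)

    def test_noisy_recovery_within_ten_percent(self, rng):
        t = np.linspace(0, 2, 21)
        R_true, lam_true = 1.4, 0.8
        runs = []
        for _ in range(20):
            x0 = rng.uniform(0, 1.0)
            clean = x0 * np.exp(-lam_true * t) + \
                (R_true / lam_true) * (1 - np.exp(-lam_true * t))
            noisy = np.clip(clean + rng.normal(0, 0.02, t.size), 0, None)
            runs.append(noisy)
        x = np.vstack(runs)
        y = np.ones_like(x, dtype=int)
        R, lam = infer_kinetics_analytic(x, y, t)
        assert R == pytest.approx(R_true, rel=0.10)
        assert lam == pytest.approx(lam_true, rel=0.10)

    def test_two_segment_series(self):
        R_true, lam_true = 1.0, 1.0
        t = np.linspace(0, 2, 21)
        x = np.where(t < 1.0, 1 - np.exp(-t),
                     (1 - np.exp(-1.0)) * np.exp(-(t - 1.0)))
        y = np.where(t < 1.0, 1, -1)
        R, lam = infer_kinetics_analytic(x, y, t)
        assert R == pytest.approx(R_true, rel=0.05)
        assert lam == pytest.approx(lam_true, rel=0.05)

    def test_flat_steady_state_flagged_unidentifiable(self):
        t = np.linspace(0, 2, 11)
        x = np.full(11, 2.0)  # sitting at R/lam with no dynamics
        with pytest.warns(RuntimeWarning, match="only the ratio"):
            R, lam = infer_kinetics_analytic(x, np.ones(11, dtype=int), t)
        assert np.isnan(R) and np.isnan(lam)

    def test_no_usable_segment_is_an_error(self):
        t = np.linspace(0, 1, 3)
        y = np.array([1, -1, 1])
        with pytest.raises(ValueError, match="segment"):
            infer_kinetics_analytic(np.array([0.1, 0.2, 0.1]), y, t)


def _kink_dataset(R=1.0, lam=0.8, D=0.2, l=20, r=30, Nnuc=50, n_times=9):
    """Synthesize a profile from the kink closed form: interior plateau
    R/lam, half-maximum at the borders, exponential flanks with
    gamma = sqrt(lam/D); the temporal rise toward the pattern is
    exponential with rate lam."""
    gamma = np.sqrt(lam / D)
    n = np.arange(Nnuc)
    prof = np.empty(Nnuc)
    plateau = R / lam
    prof[(n >= l) & (n <= r)] = plateau
    left = n < l
    right = n > r
    prof[left] = 0.5 * plateau * np.exp(-gamma * (l - n[left]))
    prof[right] = 0.5 * plateau * np.exp(-gamma * (n[right] - r))
    prof[l] = prof[r] = 0.5 * plateau  # half maximum exactly at the borders
    times = np.linspace(0.0, 12.0 / lam, n_times)
    X = prof[:, None] * (1 - np.exp(-lam * times))[None, :]
    return SpatialDataset(positions=n.astype(float), times=times,
                          X=X[:, :, None])


class TestKinkMethod:
    def test_recovers_parameters_within_five_percent(self):
        R, lam, D = 1.0, 0.8, 0.2
        ds = _kink_dataset(R, lam, D)
        fit = infer_kinetics_kink(ds, 0)
        assert fit.R == pytest.approx(R, rel=0.05)
        assert fit.lam == pytest.approx(lam, rel=0.05)
        assert fit.D == pytest.approx(D, rel=0.05)

    def test_gamma_consistency_invariant(self):
        fit = infer_kinetics_kink(_kink_dataset(), 0)
        assert fit.gamma == pytest.approx(np.sqrt(fit.lam / fit.D), rel=1e-6)

    def test_borders_detected_at_half_maximum(self):
        fit = infer_kinetics_kink(_kink_dataset(l=20, r=30), 0)
        assert abs(fit.domain[0] - 20) <= 1
        assert abs(fit.domain[1] - 30) <= 1

    def test_peak_time_class_is_the_steadiest(self):
        fit = infer_kinetics_kink(_kink_dataset(n_times=9), 0)
        assert fit.peak_time_class == 8

    def test_higher_of_two_domains_is_chosen(self):
        ds = _kink_dataset(l=10, r=16)
        X = ds.X.copy()
        # add a second, lower bump posteriorly
        second = _kink_dataset(R=0.5, l=33, r=39).X
        X = np.maximum(X, second)
        ds2 = SpatialDataset(positions=ds.positions, times=ds.times, X=X)
        fit = infer_kinetics_kink(ds2, 0)
        assert 9 <= fit.domain[0] <= 11
        assert 15 <= fit.domain[1] <= 17

    def test_flat_profile_is_an_error(self):
        ds = SpatialDataset(positions=np.arange(10.0),
                            times=np.array([0.0, 1.0]),
                            X=np.full((10, 2, 1), 3.0))
        with pytest.raises(ValueError, match="flat"):
            infer_kinetics_kink(ds, 0)

    def test_domain_touching_edge_warns_one_sided(self):
        ds = _kink_dataset(l=0, r=8)
        X = ds.X.copy()
        X[0] = X[4]  # plateau runs into the anterior edge: no left border
        ds = SpatialDataset(positions=ds.positions, times=ds.times, X=X)
        with pytest.warns(RuntimeWarning, match="one-sided"):
            fit = infer_kinetics_kink(ds, 0)
        assert fit.gamma > 0

    def test_kink_fit_validates(self):
        with pytest.raises(ValueError):
            KinkFit(peak_time_class=0, domain=(5, 3), gamma=1.0,
                    R=1, lam=1, D=1)
        with pytest.raises(ValueError):
            KinkFit(peak_time_class=0, domain=(3, 5), gamma=-1.0,
                    R=1, lam=1, D=1)
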