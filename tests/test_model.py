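"""Forward-model tests: regulation functions, closed forms, integrators."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from figr.model import (
    ExpressionDataset,
    GeneCircuit,
    analytic_segment_solution,
    heaviside_regulation,
    integrate_glass,
    integrate_glass_batch,
    sigmoid_regulation,
    simulate_glass,
    simulate_spatial,
    total_input,
)


@pytest.mark.parametrize("u,expected", [(0.0, 1.0), (-1.0, 0.0), (2.5, 1.0),
                                        (-1e-12, 0.0)])
def test_heaviside_regulation_steps_at_zero_inclusive(u, expected):
    assert heaviside_regulation(u) == expected


@pytest.mark.parametrize("u,expected", [
    (0.0, 0.5),
    (1.0, 0.8535533905932737),   # (1/sqrt(2) + 1) / 2
    (-1.0, 0.14644660940672624),
])
def test_sigmoid_regulation_values(u, expected):
    assert sigmoid_regulation(u) == pytest.approx(expected, abs=1e-12)


def test_sigmoid_regulation_properties():
    u = np.linspace(-50, 50, 1001)
    s = sigmoid_regulation(u)
    assert np.all((s > 0) & (s < 1))
    assert np.all(np.diff(s) > 0)
    np.testing.assert_allclose(sigmoid_regulation(-u), 1 - s, atol=1e-14)


@pytest.mark.parametrize("func", [heaviside_regulation, sigmoid_regulation])
def test_regulation_rejects_non_finite(func):
    with pytest.raises(ValueError):
        func(np.nan)
    with pytest.raises(ValueError):
        func(np.inf)


def test_total_input_is_affine_projection():
    circ = GeneCircuit(T=np.array([[0.0, 0.0], [1.0, 0.0]]),
                       h=np.array([-3.0, 0.0]),
                       R=[1, 1], lam=[1, 1])
    assert total_input(circ, [7.5, -2.0], 0) == -3.0
    assert total_input(circ, [2.0, 5.0], 1) == 2.0
    with pytest.raises(ValueError):
        total_input(circ, [1.0, 2.0, 3.0], 0)


def test_total_input_sign_matches_velocity_along_trajectory(two_gene_circuit):
    """For a Glass network, sgn(dx_g/dt) = sgn(T_g . x + h_g) away from
    equilibria -- checked along a simulated trajectory."""
    t = np.linspace(0, 2, 201)
    X = integrate_glass(two_gene_circuit, [0.1, 0.1], t)
    v = np.gradient(X, t, axis=0)
    for g in range(2):
        u = X @ two_gene_circuit.T[g] + two_gene_circuit.h[g]
        clear = (np.abs(u) > 0.05) & (np.abs(v[:, g]) > 0.05)
        assert np.all(np.sign(v[clear, g]) == np.sign(u[clear]))


class TestAnalyticSegment:
    def test_initial_condition_exact_at_t0(self):
        for on in (True, False):
            assert analytic_segment_solution(0.37, 2.0, 1.3, on, 0.0) == 0.37

    def test_steady_states(self):
        assert analytic_segment_solution(0.0, 2.0, 1.0, True, 1e3) == pytest.approx(2.0)
        assert analytic_segment_solution(5.0, 2.0, 1.0, False, 1e3) == pytest.approx(0.0, abs=1e-12)

    def test_half_life_arithmetic(self):
        assert analytic_segment_solution(5.0, 1.0, np.log(2), False, 1.0) == \
            pytest.approx(2.5, rel=1e-14)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            analytic_segment_solution(1.0, 1.0, 1.0, True, -0.1)


class TestGlassIntegrator:
    def test_always_on_matches_closed_form(self):
        circ = GeneCircuit(T=[[0.0]], h=[10.0], R=[1.0], lam=[1.0])
        t = np.linspace(0, 2, 21)
        X = integrate_glass(circ, [0.0], t)
        np.testing.assert_allclose(X[:, 0], 1 - np.exp(-t), rtol=0, atol=1e-8)

    def test_always_off_matches_closed_form(self):
        circ = GeneCircuit(T=[[0.0]], h=[-10.0], R=[1.0], lam=[0.7])
        t = np.linspace(0, 2, 21)
        X = integrate_glass(circ, [0.9], t)
        np.testing.assert_allclose(X[:, 0], 0.9 * np.exp(-0.7 * t), rtol=0, atol=1e-8)

    def test_two_gene_matches_stiff_ode_oracle(self, two_gene_circuit):
        """Event-driven integration agrees with a high-accuracy generic ODE
        solve of the discontinuous right-hand side."""
        t = np.linspace(0, 2, 41)
        X = integrate_glass(two_gene_circuit, [0.1, 0.1], t)

        def rhs(_, x):
            u = two_gene_circuit.T @ x + two_gene_circuit.h
            return two_gene_circuit.R * (u >= 0) - two_gene_circuit.lam * x

        sol = solve_ivp(rhs, (0, 2), [0.1, 0.1], t_eval=t,
                        rtol=1e-10, atol=1e-12, max_step=1e-3)
        np.testing.assert_allclose(X, sol.y.T, atol=1e-5)

    def test_trajectories_stay_in_bounding_hypercube(self, rng):
        from figr.synthetic import SyntheticConfig, random_circuit
        for _ in range(5):
            cfg = SyntheticConfig(G=4)
            circ = random_circuit(cfg, rng)
            x0 = rng.uniform(0, 1, 4) * circ.x_max
            X = integrate_glass(circ, x0, np.linspace(0, 2, 51))
            assert np.all(X >= -1e-9)
            assert np.all(X <= circ.x_max[None, :] * (1 + 1e-9))

    def test_outside_hypercube_warns_but_runs(self):
        circ = GeneCircuit(T=[[0.0]], h=[-10.0], R=[1.0], lam=[1.0])
        with pytest.warns(RuntimeWarning, match="bounding hypercube"):
            X = integrate_glass(circ, [5.0], np.linspace(0, 1, 5))
        assert np.isfinite(X).all()

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GeneCircuit(T=[[0.0]], h=[0.0], R=[0.0], lam=[1.0])

    def test_batch_agrees_with_event_driven_on_switching_trajectory(
            self, two_gene_circuit):
        t = np.linspace(0, 2, 21)
        Xe = integrate_glass(two_gene_circuit, [0.1, 0.1], t)
        Xb = integrate_glass_batch(two_gene_circuit, np.array([[0.1, 0.1]]), t,
                                   step=1e-4)
        np.testing.assert_allclose(Xb[0], Xe, atol=2e-3)

    def test_simulate_glass_returns_dataset(self, two_gene_circuit):
        ds = simulate_glass(two_gene_circuit, [0.1, 0.1], np.linspace(0, 2, 21))
        assert isinstance(ds, ExpressionDataset)
        assert ds.X.shape == (1, 21, 2)


class TestSpatialSimulator:
    def _plain_circuit(self, D):
        return GeneCircuit(T=np.array([[0.5, -0.3], [0.2, 0.4]]),
                           h=np.array([0.1, -0.2]),
                           R=np.array([1.0, 0.8]), lam=np.array([0.9, 1.1]),
                           D=np.array(D))

    def test_diffusion_free_limit_is_cell_autonomous(self):
        circ = self._plain_circuit([0.0, 0.0])
        t = np.linspace(0, 2, 9)
        init = np.array([[0.1, 0.5], [0.7, 0.2], [0.3, 0.9]])
        ds = simulate_spatial(circ, init, t)
        for n in range(3):
            single = simulate_spatial(circ, init[n:n + 1], t)
            np.testing.assert_allclose(ds.X[n], single.X[0], atol=1e-12)

    def test_pure_decay_with_diffusion_conserves_then_decays(self):
        """With no synthesis and zero-flux ends, diffusion redistributes but
        total protein decays exactly as e^{-lam t}."""
        lam = 0.6
        # synthesis made negligible (sigmoid tails are algebraic, not exact 0)
        circ = GeneCircuit(T=[[0.0]], h=[-1e6], R=[1e-9], lam=[lam], D=[0.4])
        init = np.zeros((12, 1))
        init[4, 0] = 3.0
        t = np.linspace(0, 3, 7)
        ds = simulate_spatial(circ, init, t, max_step=1e-3)
        totals = ds.X[:, :, 0].sum(axis=0)
        np.testing.assert_allclose(totals, 3.0 * np.exp(-lam * t), rtol=1e-6)

    def test_flank_gradient_has_kink_decay_length(self):
        """A single always-ON nucleus in an OFF field builds steady flanks
        decaying as e^{-gamma n} with gamma = sqrt(lam / D)."""
        lam, D = 0.05, 0.5  # gamma = 0.316; gradient wide vs lattice spacing
        # second gene acts as a fixed spatial mask switching g ON at one
        # site; couplings are steep so the sigmoid's algebraic tail leaves
        # no synthesis background on the flank
        T = np.array([[0.0, 400.0], [0.0, 0.0]])
        circ = GeneCircuit(T=T, h=np.array([-200.0, 0.0]),
                           R=np.array([0.05, 1.0]), lam=np.array([lam, 1.0]),
                           D=np.array([D, 0.0]), upstream=frozenset({1}),
                           genes=("g", "src"))
        Nn = 81
        src = np.zeros(Nn)
        src[40] = 1.0
        times = np.linspace(0, 800, 11)
        upX = np.repeat(src[:, None], 11, axis=1)[:, :, None]
        init = np.zeros((Nn, 2))
        init[:, 1] = src
        ds = simulate_spatial(circ, init, times, upstream_times=times,
                              upstream_X=upX, max_step=0.5)
        prof = ds.X[:, -1, 0]
        # a few nuclei off the source: equilibrated, far from the boundary
        flank = prof[43:53]
        slope = np.polyfit(np.arange(flank.size), np.log(flank), 1)[0]
        assert -slope == pytest.approx(np.sqrt(lam / D), rel=0.05)

    def test_step_halving_changes_output_below_tolerance(self):
        circ = self._plain_circuit([0.2, 0.1])
        init = np.array([[0.1, 0.5], [0.7, 0.2], [0.3, 0.9]])
        t = np.linspace(0, 2, 5)
        a = simulate_spatial(circ, init, t).X
        b = simulate_spatial(circ, init, t, max_step=1e-3).X
        assert np.max(np.abs(a - b)) < 1e-6

    def test_missing_upstream_series_is_an_error(self):
        circ = GeneCircuit(T=np.zeros((2, 2)), h=np.zeros(2), R=[1, 1],
                           lam=[1, 1], D=[0.1, 0.0], upstream=frozenset({1}))
        with pytest.raises(ValueError, match="upstream"):
            simulate_spatial(circ, np.zeros((4, 2)), np.linspace(0, 1, 3))


def test_upstream_gene_requires_zero_row():
    with pytest.raises(ValueError, match="all-zero"):
        GeneCircuit(T=np.array([[0.0, 1.0], [0.5, 0.0]]), h=[0, 0],
                    R=[1, 1], lam=[1, 1], upstream=frozenset({0}))
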