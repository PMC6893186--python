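"""Local refinement of circuit parameters against the sigmoid model.

The classification and kinetic stages assume switch-like (Heaviside)
regulation; the refinement stage drops that assumption and polishes all
parameters of the non-upstream genes by unconstrained Nelder-Mead simplex
minimization of the squared-error cost

    chi2 = sum_{n,g,t} (x~_ng(t) - x_ng(t))^2

between the data and the solution of the smooth sigmoid gene-circuit model
(with diffusion for spatial data).  The sum runs over non-upstream genes
and every time slice after the initial condition.

A cell-autonomous dataset is treated as the diffusion-free limit of the
spatial model (each trajectory is one isolated "nucleus"), so both kinds of
data share one code path and one optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from figr.model import (ExpressionDataset, GeneCircuit, SpatialDataset,
                        simulate_spatial)

__all__ = ["RefinementResult", "chi2_cost", "refine"]

_PENALTY = 1e30  # cost assigned to diverged simulations, keeps the simplex usable


@dataclass(frozen=True)
class RefinementResult:
    circuit: GeneCircuit
    chi2: float
    rms: float          # sqrt(chi2 / n_obs)
    n_obs: int
    n_iter: int
    converged: bool


def _data_as_field(data) -> tuple[np.ndarray, np.ndarray]:
    """View any supported dataset as (n_series, Ntc, G) on a shared grid."""
    if isinstance(data, SpatialDataset):
        return data.X, data.times
    if isinstance(data, ExpressionDataset):
        return data.X, data.times
    raise TypeError("data must be an ExpressionDataset or SpatialDataset")


def _simulate_on_data(circuit: GeneCircuit, data, max_step=None) -> np.ndarray:
    X, times = _data_as_field(data)
    spatial = isinstance(data, SpatialDataset)
    circ = circuit
    if not spatial and circuit.D is not None and np.any(circuit.D != 0):
        circ = circuit.with_params(D=None)
    up = sorted(circ.upstream)
    kwargs = {}
    if up:
        kwargs = {"upstream_times": times, "upstream_X": X[:, :, up]}
    sim = simulate_spatial(circ, X[:, 0, :], times, max_step=max_step, **kwargs)
    return sim.X


def chi2_cost(circuit: GeneCircuit, data, max_step=None) -> float:
    """Squared-error cost of a circuit against a dataset.

    Residuals exclude upstream genes (they are inputs, not predictions) and
    the first time slice (it is the initial condition).  A simulation that
    diverges to non-finite values yields a large finite penalty so that a
    simplex search can recover from bad parameter regions.
    """
    X, _ = _data_as_field(data)
    dyn = circuit.dynamic_mask
    with np.errstate(all="ignore"):
        try:
            sim = _simulate_on_data(circuit, data, max_step=max_step)
        except (ValueError, FloatingPointError):
            warnings.warn("simulation failed; returning penalty cost",
                          RuntimeWarning, stacklevel=2)
            return _PENALTY
    resid = sim[:, 1:, :][:, :, dyn] - X[:, 1:, :][:, :, dyn]
    with np.errstate(over="ignore"):
        cost = float(np.sum(resid * resid))
    if not np.isfinite(cost):
        warnings.warn("simulation diverged; returning penalty cost",
                      RuntimeWarning, stacklevel=2)
        return _PENALTY
    return cost


def _n_obs(circuit: GeneCircuit, data) -> int:
    X, _ = _data_as_field(data)
    return X.shape[0] * (X.shape[1] - 1) * int(circuit.dynamic_mask.sum())


def _pack(circuit: GeneCircuit, fit_D: bool) -> tuple[np.ndarray, list]:
    dyn_idx = [g for g in range(circuit.G) if g not in circuit.upstream]
    theta = []
    for g in dyn_idx:
        theta.extend(circuit.T[g])
        theta.append(circuit.h[g])
        theta.append(circuit.R[g])
        theta.append(circuit.lam[g])
        if fit_D:
            theta.append(circuit.D[g])
    return np.array(theta, dtype=float), dyn_idx


def _unpack(theta: np.ndarray, circuit: GeneCircuit, dyn_idx: list,
            fit_D: bool) -> GeneCircuit:
    G = circuit.G
    stride = G + 3 + (1 if fit_D else 0)
    T = circuit.T.copy()
    h = circuit.h.copy()
    R = circuit.R.copy()
    lam = circuit.lam.copy()
    D = circuit.D.copy() if circuit.D is not None else None
    for i, g in enumerate(dyn_idx):
        row = theta[i * stride:(i + 1) * stride]
        T[g] = row[:G]
        h[g] = row[G]
        # the search itself is unconstrained; tiny floors only keep the
        # simulator's closed forms defined
        R[g] = max(row[G + 1], 1e-12)
        lam[g] = max(row[G + 2], 1e-12)
        if fit_D:
            D[g] = max(row[G + 3], 0.0)
    return circuit.with_params(T=T, h=h, R=R, lam=lam, D=D)


def refine(initial: GeneCircuit, data, max_iter: int | None = None,
           tol: float = 1e-4, max_step=None) -> RefinementResult:
    """Nelder-Mead refinement of all non-upstream parameters.

    The initial simplex steps each parameter by 10% of its magnitude (0.1
    for zero entries); convergence is declared when the cost changes by
    less than ``tol``.  The returned circuit is the best ever evaluated,
    so the final cost never exceeds the initial cost.
    """
    fit_D = isinstance(data, SpatialDataset) and initial.D is not None
    theta0, dyn_idx = _pack(initial, fit_D)
    c0 = chi2_cost(initial, data, max_step=max_step)
    if not np.isfinite(c0):
        raise ValueError("initial circuit has non-finite cost")
    best = {"theta": theta0.copy(), "cost": c0}

    def cost(theta):
        circ = _unpack(theta, initial, dyn_idx, fit_D)
        c = chi2_cost(circ, data, max_step=max_step)
        if c < best["cost"]:
            best["cost"] = c
            best["theta"] = theta.copy()
        return c

    step = np.where(theta0 == 0.0, 0.1, 0.1 * np.abs(theta0))
    simplex = np.vstack([theta0, theta0 + np.diag(step)])
    if max_iter is None:
        max_iter = 400 * theta0.size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(cost, theta0, method="Nelder-Mead",
                       options={"initial_simplex": simplex, "fatol": tol,
                                "xatol": 1e-8, "maxiter": max_iter,
                                "maxfev": 4 * max_iter})
    circ = _unpack(best["theta"], initial, dyn_idx, fit_D)
    n = _n_obs(initial, data)
    return RefinementResult(circuit=circ, chi2=best["cost"],
                            rms=float(np.sqrt(best["cost"] / n)), n_obs=n,
                            n_iter=int(res.nit), converged=bool(res.success))
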