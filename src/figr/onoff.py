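"""ON/OFF state calling from expression time series.

For a Glass network the sign of the velocity dx_g/dt equals the sign of the
total regulatory input, so a gene's (hidden) synthesis state can be read off
the data: velocities are estimated by differentiating cubic (smoothing)
splines fit to each time series, and the state is called by a thresholded
rule that falls back to an expression threshold where the velocity is too
small to be trusted::

    y_g = sgn(dx_g/dt)      if |dx_g/dt| >= v_gc
    y_g = sgn(x_g - x_gc)   otherwise

with sgn(0) = +1 throughout, matching the Theta(0) = 1 convention of the
simulator.  Near the expression bounds (x close to 0 or to R/lam) the true
velocity is close to zero and measurement noise would otherwise flip its
sign at random; the thresholds guard against such spurious switching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from figr.model import ExpressionDataset, SpatialDataset

__all__ = [
    "ClassifierOptions",
    "StateLabels",
    "estimate_velocities",
    "classify_state",
    "label_dataset",
    "resolve_thresholds",
]


@dataclass(frozen=True)
class ClassifierOptions:
    """Options of the ON/OFF calling rule.

    Parameters
    ----------
    v_thresh, x_thresh : (G,) arrays or None
        Velocity thresholds v_gc and expression thresholds x_gc per gene.
        When None they are derived from the data as
        ``v_thresh_frac * max|v_g|`` and ``x_thresh_frac * max x_g``
        (scale-free defaults; both are routinely tuned per dataset).
    spline_smoothing : float in (0, 1] or None
        Smoothing level of the cubic spline, csaps-style: 1 interpolates,
        values below 1 map to a roughness penalty lam = (1 - p) / p, and
        None selects lam per series by generalized cross-validation.  The
        default interpolates, which is the right choice for noise-free
        simulated data; use GCV or an explicit level for noisy data.
    """

    v_thresh: np.ndarray | None = None
    x_thresh: np.ndarray | None = None
    v_thresh_frac: float = 0.01
    x_thresh_frac: float = 0.2
    spline_smoothing: float | None = 1.0

    def __post_init__(self):
        for name in ("v_thresh", "x_thresh"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=float)
                if np.any(arr < 0):
                    raise ValueError(f"{name} must be nonnegative")
                object.__setattr__(self, name, arr)
        p = self.spline_smoothing
        if p is not None and not 0.0 < p <= 1.0:
            raise ValueError("spline_smoothing must lie in (0, 1] or be None (GCV)")


@dataclass(frozen=True)
class StateLabels:
    """Per-observation ON/OFF calls (+1/-1) and the velocities behind them."""

    y: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y)
        v = np.asarray(self.v, dtype=float)
        if y.shape != v.shape:
            raise ValueError("y and v must have the same shape")
        if not np.all(np.abs(y) == 1):
            raise ValueError("labels must be +1 or -1")
        object.__setattr__(self, "y", y.astype(int))
        object.__setattr__(self, "v", v)


def _series_matrix(data) -> tuple[np.ndarray, np.ndarray]:
    """Stack all (series, gene) time courses as columns of a (Nt, M) matrix."""
    X = data.X  # (n_series, Nt, G)
    n, Nt, G = X.shape
    return data.times, np.moveaxis(X, 1, 0).reshape(Nt, n * G)


def estimate_velocities(data: ExpressionDataset | SpatialDataset,
                        options: ClassifierOptions | None = None) -> np.ndarray:
    """Estimate dx/dt at every observation by spline differentiation.

    Each (trajectory-or-nucleus, gene) time series gets its own cubic
    spline; the returned array matches ``data.X`` in shape.  At least three
    timepoints per series are required for a usable derivative.
    """
    options = options or ClassifierOptions()
    times = data.times
    if times.size < 3:
        raise ValueError(
            f"need at least 3 timepoints to estimate velocities, got {times.size}")
    n, Nt, G = data.X.shape
    p = options.spline_smoothing
    if p is not None and (p == 1.0 or Nt < 5):
        if p is not None and p < 1.0 and Nt < 5:
            warnings.warn("fewer than 5 timepoints: falling back to an "
                          "interpolating spline", RuntimeWarning, stacklevel=2)
        _, Y = _series_matrix(data)
        bc = "not-a-knot" if Nt >= 4 else "natural"
        spl = CubicSpline(times, Y, bc_type=bc)
        V = spl(times, 1)
        return np.moveaxis(V.reshape(Nt, n, G), 0, 1)
    if p is not None:
        lam = (1.0 - p) / p
        _, Y = _series_matrix(data)
        spl = make_smoothing_spline(times, Y, lam=lam, axis=0)
        V = spl.derivative()(times)
        return np.moveaxis(V.reshape(Nt, n, G), 0, 1)
    # GCV: the roughness penalty is chosen per series, so loop
    V = np.empty_like(data.X)
    for i in range(n):
        for g in range(G):
            spl = make_smoothing_spline(times, data.X[i, :, g], lam=None)
            V[i, :, g] = spl.derivative()(times)
    return V


def resolve_thresholds(data, v: np.ndarray,
                       options: ClassifierOptions) -> ClassifierOptions:
    """Fill in per-gene thresholds from their scale-free fractions."""
    v_th, x_th = options.v_thresh, options.x_thresh
    if v_th is None:
        vmax = np.max(np.abs(v), axis=(0, 1))
        # a gene with no velocity signal at all must defer to the
        # expression branch, so its threshold is kept (barely) positive
        v_th = np.where(vmax > 0, options.v_thresh_frac * vmax,
                        np.finfo(float).tiny)
    if x_th is None:
        x_th = options.x_thresh_frac * np.max(data.X, axis=(0, 1))
    return replace(options, v_thresh=np.broadcast_to(v_th, (data.X.shape[2],)).copy(),
                   x_thresh=np.broadcast_to(x_th, (data.X.shape[2],)).copy())


def classify_state(x, v, g: int, options: ClassifierOptions):
    """Call the ON/OFF state of gene ``g`` from expression and velocity.

    Velocities at or above the threshold decide by their sign; smaller
    velocities defer to the expression threshold.  Ties (|v| = v_gc,
    x = x_gc, v = 0) resolve to the ON side.
    """
    if options.v_thresh is None or options.x_thresh is None:
        raise ValueError("thresholds not set; call resolve_thresholds first")
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    v_gc = float(np.asarray(options.v_thresh).ravel()[g])
    x_gc = float(np.asarray(options.x_thresh).ravel()[g])
    sign_v = np.where(v >= 0.0, 1, -1)
    sign_x = np.where(x - x_gc >= 0.0, 1, -1)
    out = np.where(np.abs(v) >= v_gc, sign_v, sign_x)
    return out if out.ndim else int(out)


def label_dataset(data: ExpressionDataset | SpatialDataset,
                  options: ClassifierOptions | None = None) -> StateLabels:
    """Estimate velocities and call the ON/OFF state of every observation."""
    options = options or ClassifierOptions()
    v = estimate_velocities(data, options)
    options = resolve_thresholds(data, v, options)
    y = np.empty(data.X.shape, dtype=int)
    for g in range(data.X.shape[2]):
        y[:, :, g] = classify_state(data.X[:, :, g], v[:, :, g], g, options)
    return StateLabels(y=y, v=v)
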