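"""Kinetic-parameter inference: synthesis, degradation and diffusion rates.

Three estimators are provided, all conditional on previously called ON/OFF
labels:

* the **slope** method regresses velocities on concentrations using the
  piecewise-linear form v = R - lam*x (ON) / v = -lam*x (OFF), excluding a
  configurable number of timepoints around each switching event where
  spline-derivative estimates are least reliable;
* the **analytic** method fits the closed-form exponential solution of the
  single-gene ODE to the concentrations themselves, segment by segment;
* the **kink** method, for spatial data with diffusion, exploits the
  steady-state exponential gradient flanking a synthesis domain,
  x_n = R/(2 lam) * exp(-gamma * distance-to-border) with
  gamma = sqrt(lam / D), to recover (R, lam, D) from the shape of the
  spatial profile plus the temporal approach to the plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from figr.model import SpatialDataset

__all__ = [
    "KinkFit",
    "infer_kinetics_slope",
    "infer_kinetics_analytic",
    "infer_kinetics_kink",
    "switch_exclusion_mask",
]


@dataclass(frozen=True)
class KinkFit:
    """Kink-method estimate for one gene of a spatial dataset."""

    peak_time_class: int
    domain: tuple  # (l, r) nucleus indices of the half-maximum borders
    gamma: float   # flank decay rate, 1 / nuclei
    R: float
    lam: float
    D: float

    def __post_init__(self):
        l, r = self.domain
        if l > r:
            raise ValueError("domain borders must satisfy l <= r")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def switch_exclusion_mask(y: np.ndarray, exclude_k: int) -> np.ndarray:
    """Mask out ``exclude_k`` timepoints on each side of every label flip.

    ``y`` is a (n_series, Nt) array of +1/-1 labels; the returned boolean
    mask is False where an observation is too close to a switching event.
    """
    y = np.atleast_2d(np.asarray(y))
    mask = np.ones(y.shape, dtype=bool)
    if exclude_k <= 0:
        return mask
    n, Nt = y.shape
    for i in range(n):
        flips = np.nonzero(np.diff(y[i]) != 0)[0]  # flip between k and k+1
        for k in flips:
            lo = max(k - exclude_k + 1, 0)
            hi = min(k + exclude_k + 1, Nt)
            mask[i, lo:hi] = False
    return mask


def infer_kinetics_slope(x, v, y, exclude_k: int = 2) -> tuple[float, float]:
    """Estimate (R, lam) for one gene by the slope method.

    Parameters
    ----------
    x, v, y : (n_series, Nt) arrays (or 1-D for a single series)
        Concentrations, velocity estimates and ON/OFF labels.
    exclude_k : int
        Timepoints dropped on each side of every detected label flip
        before the regression; spline-based velocities are least accurate
        right at switching events.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    y = np.atleast_2d(np.asarray(y))
    if not (x.shape == v.shape == y.shape):
        raise ValueError("x, v, y must have identical shapes")
    keep = switch_exclusion_mask(y, exclude_k)
    xk, vk, yk = x[keep], v[keep], y[keep]
    if xk.size == 0:
        raise ValueError("no observations left after switch-point exclusion")
    on = yk == 1
    # rows: ON  v = R - lam x  ->  [1, -x] . (R, lam)
    #       OFF v =   - lam x  ->  [0, -x] . (R, lam)
    A = np.column_stack([on.astype(float), -xk])
    if not on.any():
        warnings.warn("no ON observations: R is unidentifiable; returning "
                      "R = nan and the OFF-branch decay rate",
                      RuntimeWarning, stacklevel=2)
        lam = float(np.linalg.lstsq(A[:, 1:], vk, rcond=None)[0][0])
        return float("nan"), lam
    if on.all():
        warnings.warn("no OFF observations: (R, lam) rely on the ON branch "
                      "alone and may be poorly conditioned",
                      RuntimeWarning, stacklevel=2)
    sol = np.linalg.lstsq(A, vk, rcond=None)[0]
    return float(sol[0]), float(sol[1])


def infer_kinetics_analytic(x, y, times, exclude_k: int = 0) -> tuple[float, float]:
    """Estimate (R, lam) by fitting the exponential segment solution.

    Within every maximal run of constant label the model prediction is
    anchored at the run's first observed concentration and propagated with
    the closed-form ON/OFF solution; (R, lam) minimize the squared
    concentration residuals over all runs (trust-region least squares).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y))
    times = np.asarray(times, dtype=float).ravel()
    if x.shape != y.shape or x.shape[1] != times.size:
        raise ValueError("x, y must be (n_series, Nt) matching times")
    keep = switch_exclusion_mask(y, exclude_k)

    # collect (x0, dt, on, x_obs) tuples for every within-run observation
    anchors, dts, states, obs = [], [], [], []
    for i in range(x.shape[0]):
        runs = np.split(np.arange(times.size), np.nonzero(np.diff(y[i]))[0] + 1)
        for run in runs:
            run = run[keep[i, run]]
            if run.size < 2:
                continue
            k0 = run[0]
            anchors.append(np.full(run.size - 1, x[i, k0]))
            dts.append(times[run[1:]] - times[k0])
            states.append(np.full(run.size - 1, y[i, k0] == 1))
            obs.append(x[i, run[1:]])
    if not anchors:
        raise ValueError("no labeled segment with at least 2 points")
    x0 = np.concatenate(anchors)
    dt = np.concatenate(dts)
    on = np.concatenate(states)
    xo = np.concatenate(obs)

    if np.ptp(xo) < 1e-10 * max(np.max(np.abs(xo)), 1.0) and np.ptp(x0) < 1e-10:
        warnings.warn("flat series at steady state: only the ratio R/lam is "
                      "constrained; returning nan", RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")

    def resid(theta):
        R, lam = theta
        decay = np.exp(-lam * dt)
        target = np.where(on, R / lam, 0.0)
        return target + (x0 - target) * decay - xo

    scale = max(float(np.max(xo)), 1e-6)
    sol = least_squares(resid, x0=np.array([scale, 1.0]),
                        bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    return float(sol.x[0]), float(sol.x[1])


def _half_max_border(profile: np.ndarray, peak: int, half: float,
                     direction: int) -> float | None:
    """First half-maximum crossing from ``peak`` along ``direction`` (+/-1).

    Returns the nucleus index (float, linearly interpolated between the
    bracketing nuclei) or None if the profile never falls to half maximum
    before the edge.
    """
    n = peak
    while 0 <= n + direction < profile.size:
        nxt = n + direction
        if profile[nxt] <= half:
            # interpolate the crossing between n and nxt
            if profile[n] == profile[nxt]:
                return float(nxt)
            frac = (profile[n] - half) / (profile[n] - profile[nxt])
            return n + direction * frac
        n = nxt
    return None


def infer_kinetics_kink(data: SpatialDataset, g: int,
                        min_prominence: float = 0.1) -> KinkFit:
    """Estimate (R, lam, D) for gene ``g`` of a spatial dataset.

    Procedure: (1) pick the time class where the gene's spatial maximum is
    highest (closest to steady state); (2) locate expression domains as
    local maxima of that profile (minimum prominence ``min_prominence`` of
    the gene's global maximum, to suppress noise bumps) and keep the
    highest; (3) place the domain borders l, r where expression first
    falls to half the domain peak (linear interpolation, rounded to the
    nearest nucleus); (4) fit the exponential flanks beyond the borders
    for the decay rate gamma and amplitude R/(2 lam); (5) recover the
    absolute time scale lam from the temporal approach of the peak nucleus
    to its plateau, then R = lam * plateau and D = lam / gamma^2.
    """
    if not 0 <= g < data.G:
        raise ValueError("gene index out of range")
    Xg = data.X[:, :, g]  # (Nnuc, Ntc)
    peak_tc = int(np.argmax(Xg.max(axis=0)))
    profile = Xg[:, peak_tc]
    gmax = float(profile.max())
    if gmax <= 0 or np.ptp(profile) < 1e-12 * max(gmax, 1.0):
        raise ValueError("flat spatial profile: no expression domain to fit")
    peaks, _ = find_peaks(profile, prominence=min_prominence * gmax)
    if peaks.size == 0:
        # global maximum sits at an edge of the modeled region
        peak = int(np.argmax(profile))
        if peak not in (0, profile.size - 1):
            raise ValueError("no expression domain with sufficient prominence")
        warnings.warn("expression peak at the edge of the modeled region: "
                      "one-sided kink fit", RuntimeWarning, stacklevel=2)
    else:
        peak = int(peaks[np.argmax(profile[peaks])])
    plateau = float(profile[peak])
    half = 0.5 * plateau
    lb = _half_max_border(profile, peak, half, -1)
    rb = _half_max_border(profile, peak, half, +1)
    if lb is None and rb is None:
        raise ValueError("expression domain spans the whole region: no flank "
                         "gradient to fit")
    if lb is None or rb is None:
        warnings.warn("domain border reaches the region edge: one-sided "
                      "kink fit", RuntimeWarning, stacklevel=2)
    l = int(round(lb)) if lb is not None else 0
    r = int(round(rb)) if rb is not None else profile.size - 1

    idx = np.arange(profile.size)
    dist = np.concatenate([
        (l - idx[idx < l]) if lb is not None else np.empty(0),
        (idx[idx > r] - r) if rb is not None else np.empty(0),
    ]).astype(float)
    vals = np.concatenate([
        profile[idx < l] if lb is not None else np.empty(0),
        profile[idx > r] if rb is not None else np.empty(0),
    ])
    if dist.size < 2:
        raise ValueError("too few flank nuclei to fit the gradient")

    def flank_resid(theta):
        A, gamma = theta
        return A * np.exp(-gamma * dist) - vals

    sol = least_squares(flank_resid, x0=np.array([half, 0.3]),
                        bounds=([1e-12, 1e-9], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    A, gamma = float(sol.x[0]), float(sol.x[1])

    # absolute rate from the temporal rise of the peak nucleus; the domain
    # interior is close to cell-autonomous, x(t) -> plateau as e^{-lam t}
    series = Xg[peak, : peak_tc + 1]
    t = data.times[: peak_tc + 1]
    gap = plateau - series
    usable = gap > 1e-3 * plateau
    if usable.sum() >= 2:
        lam = -float(np.polyfit(t[usable], np.log(gap[usable]), 1)[0])
        if lam <= 0:
            lam = float("nan")
    else:
        lam = float("nan")
    if not np.isfinite(lam):
        warnings.warn("no usable transient toward the plateau: absolute "
                      "rates are unidentifiable from a steady profile; "
                      "returning lam = 1 scale", RuntimeWarning, stacklevel=2)
        lam = 1.0
    R = lam * plateau
    D = lam / gamma**2
    return KinkFit(peak_time_class=peak_tc, domain=(l, r), gamma=gamma,
                   R=R, lam=lam, D=D)
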