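"""Random gene circuits and sampled trajectories for validation studies.

The generator reproduces the protocol used to benchmark classification-based
circuit inference: synthesis and degradation rates uniform on [0.5, 2], each
switching hyperplane passing through a point drawn uniformly from the
bounding hypercube 0 < x_g < R_g/lam_g with a normal drawn uniformly from
the unit G-sphere, and N Glass-network trajectories started from uniform
random points of the hypercube, sampled at Nt equally spaced timepoints on
[0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from figr.model import (ExpressionDataset, GeneCircuit, SpatialDataset,
                        integrate_glass_batch, simulate_spatial)

__all__ = [
    "SyntheticConfig",
    "free_parameter_count",
    "random_circuit",
    "sample_trajectories",
    "add_noise",
    "gap_gene_like_circuit",
    "sample_spatial_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic parameter-recovery experiment.

    Defaults are the benchmark conditions: trajectories over [0, 2] with
    rates drawn from [0.5, 2].
    """

    G: int = 20
    N: int = 100
    Nt: int = 21
    t_end: float = 2.0
    rate_range: tuple = (0.5, 2.0)
    seed: int | None = None

    def __post_init__(self):
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.Nt < 2:
            raise ValueError("Nt must be >= 2")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        lo, hi = self.rate_range
        if lo <= 0 or hi < lo:
            raise ValueError("rate_range must be positive and ordered")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.Nt)


def free_parameter_count(G: int) -> int:
    """Number of free parameters of a G-gene circuit: G*(G+3).

    Each gene contributes G interconnectivity coefficients plus a
    threshold, a synthesis rate, and a degradation rate.
    """
    return G * (G + 3)


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def random_circuit(config: SyntheticConfig, rng=None) -> GeneCircuit:
    """Draw a random gene circuit.

    R_g and lam_g are uniform on ``config.rate_range``.  For each gene the
    hyperplane normal is uniform on the unit G-sphere (normalized standard
    Gaussians) and the threshold is set so the hyperplane passes through a
    point drawn uniformly from the bounding hypercube.
    """
    rng = _rng(rng if rng is not None else config.seed)
    G = config.G
    lo, hi = config.rate_range
    R = rng.uniform(lo, hi, size=G)
    lam = rng.uniform(lo, hi, size=G)
    x_max = R / lam
    # unit normals: normalized iid standard normals are uniform on the sphere
    T = rng.standard_normal(size=(G, G))
    T /= np.linalg.norm(T, axis=1, keepdims=True)
    x_cen = rng.uniform(0.0, 1.0, size=(G, G)) * x_max[None, :]
    h = -np.einsum("gf,gf->g", T, x_cen)
    return GeneCircuit(T=T, h=h, R=R, lam=lam)


def sample_trajectories(circuit: GeneCircuit, config: SyntheticConfig,
                        rng=None, step: float = 1e-3) -> ExpressionDataset:
    """Simulate N Glass trajectories from uniform random initial states.

    Initial states are uniform in the bounding hypercube; each trajectory
    is sampled at Nt timepoints equally subdividing [0, t_end].  All
    trajectories are integrated together by vectorized fixed-step
    exponential stepping (see ``integrate_glass_batch``); switching times
    are resolved to ``step``, far below the sampling interval.
    """
    rng = _rng(rng if rng is not None else config.seed)
    times = config.times
    x_max = circuit.x_max
    X0 = rng.uniform(0.0, 1.0, size=(config.N, circuit.G)) * x_max[None, :]
    X = integrate_glass_batch(circuit, X0, times, step=step)
    return ExpressionDataset(times=times, X=np.clip(X, 0.0, None),
                             genes=circuit.genes)


def add_noise(data: ExpressionDataset, sigma: float, rng=None) -> ExpressionDataset:
    """Additive Gaussian measurement noise, clipped at zero.

    ``sigma`` is the noise standard deviation in concentration units;
    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return data
    rng = _rng(rng)
    noisy = np.clip(data.X + rng.normal(0.0, sigma, size=data.X.shape), 0.0, None)
    return ExpressionDataset(times=data.times, X=noisy,
                             conditions=data.conditions, genes=data.genes)


# ---------------------------------------------------------------------------
# spatial fixture: a segmentation-style patterning circuit

def gap_gene_like_circuit() -> GeneCircuit:
    """A fixed 6-gene circuit emulating trunk gap-gene patterning.

    Four dynamic genes read two external maternal-style gradients (an
    anterior exponential and a posterior ramp) and repress one another, so
    that at the end of the simulated interval each is expressed in its own
    anteroposterior domain: g0 anterior, g1 and g2 interior, g3 posterior.
    Rates are in per-minute units (half-life about 10 min); diffusion
    constants are small (0.15 nucleus^2/min), giving flank gradients a few
    nuclei wide.  Used as ground truth for spatial-pipeline recovery
    studies.
    """
    #             g0    g1    g2    g3    ant   post
    T = np.array([
        [ 1.5, -1.5, -4.0, -1.5,  8.0, -2.0],
        [-7.0,  1.5, -2.0, -5.0,  5.0,  3.0],
        [-4.0, -2.0,  1.5, -7.0,  2.0,  5.0],
        [-1.5, -5.0, -2.0,  1.5, -2.0,  8.0],
        [0.0] * 6,
        [0.0] * 6,
    ])
    h = np.array([-3.2, -2.2, -2.4, -4.6, 0.0, 0.0])
    lam = np.array([0.07, 0.07, 0.07, 0.07, 1.0, 1.0])
    R = np.array([0.07, 0.07, 0.07, 0.07, 1.0, 1.0])  # plateaus R/lam = 1
    D = np.array([0.15, 0.15, 0.15, 0.15, 0.0, 0.0])
    return GeneCircuit(T=T, h=h, R=R, lam=lam, D=D, upstream=frozenset({4, 5}),
                       genes=("g0", "g1", "g2", "g3", "ant", "post"))


def sample_spatial_dataset(circuit: GeneCircuit | None = None, Nnuc: int = 50,
                           n_time_classes: int = 8,
                           class_spacing: float = 6.25,
                           sigma: float = 0.0, rng=None) -> SpatialDataset:
    """Forward-simulate a 1-D row of nuclei under a patterning circuit.

    Produces ``n_time_classes + 1`` time slices spaced ``class_spacing``
    apart (the first is the initial condition: dynamic genes at zero,
    upstream gradients in place), mirroring the staging of integrated
    blastoderm expression data.  Optional clipped Gaussian noise of scale
    ``sigma`` emulates measurement error.
    """
    circuit = circuit or gap_gene_like_circuit()
    up = sorted(circuit.upstream)
    n = np.arange(Nnuc, dtype=float)
    gradients = {
        "ant": np.exp(-n / (0.24 * Nnuc)),
        "post": n / (Nnuc - 1.0),
    }
    times = np.linspace(0.0, n_time_classes * class_spacing, n_time_classes + 1)
    if up:
        cols = []
        for k, g in enumerate(up):
            name = circuit.genes[g]
            prof = gradients.get(name)
            if prof is None:  # fall back: alternate the two shapes
                prof = list(gradients.values())[k % 2]
            cols.append(np.repeat(prof[:, None], times.size, axis=1))
        upstream_X = np.stack(cols, axis=2)
    else:
        upstream_X = None
    init = np.zeros((Nnuc, circuit.G))
    for k, g in enumerate(up):
        init[:, g] = upstream_X[:, 0, k]
    ds = simulate_spatial(circuit, init, times,
                          upstream_times=times if up else None,
                          upstream_X=upstream_X, positions=n)
    if sigma > 0:
        X = np.clip(ds.X + _rng(rng).normal(0.0, sigma, ds.X.shape), 0.0, None)
        ds = SpatialDataset(positions=ds.positions, times=ds.times, X=X,
                            genes=ds.genes)
    return ds
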