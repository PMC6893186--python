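# Methods

## Model

The package works with gene circuits: coupled ODEs in which the synthesis
rate of gene product `g` is a switch-like function of the total regulatory
input `u_g = Σ_f T_gf x_f + h_g`,

    dx_g/dt = R_g · S(u_g) − λ_g x_g .

Two regulation-expression functions are implemented. The Heaviside step
`Θ(u)` (with the convention `Θ(0) = 1`, and `sgn(0) = +1` everywhere in the
package) yields piecewise-linear *Glass* dynamics whose regulatory
parameters `(T_g, h_g)` and kinetic parameters `(R_g, λ_g)` decouple: the
former fix the switching hyperplane `u_g = 0`, the latter the closed-form
exponential segments

    x_g(t) = x_g(0) e^{−λ_g t} + (R_g/λ_g)(1 − e^{−λ_g t})   (ON)
    x_g(t) = x_g(0) e^{−λ_g t}                               (OFF).

The smooth sigmoid `σ(u) = ½(u/√(1+u²)+1)` is used wherever a
differentiable model is needed, in particular during refinement. Starting
inside the bounding hypercube `0 ≤ x_g < R_g/λ_g`, trajectories never
leave it.

For a 1-D row of nuclei (the syncytial-blastoderm setting the spatial code
targets), discretized Fickian diffusion `D_g (x_{n−1,g} + x_{n+1,g} −
2x_{n,g})` is added with zero-flux boundaries, implemented by mirroring
the boundary nucleus so that the discrete Laplacian has vanishing column
sums (diffusion redistributes but never creates or destroys protein).
Upstream regulators — external inputs such as maternal gradients — carry
all-zero `T` rows, are never integrated, and are linearly interpolated
from their data series in time.

## Inference pipeline

**ON/OFF calling.** For a Glass network, `sgn(dx_g/dt) = sgn(u_g)` away
from equilibria, so the hidden synthesis state is read from estimated
velocities. Velocities come from differentiated cubic splines fit per
(series, gene). The label rule is velocity-first with an expression
fallback: `y = sgn(v)` if `|v| ≥ v_gc`, else `y = sgn(x − x_gc)`. The
thresholds guard against noise-induced spurious switching near the
expression bounds, where the true velocity vanishes. Defaults are
scale-free fractions, `v_gc = 0.01·max|v_g|` and `x_gc = 0.2·max x_g` per
gene, and both are exposed; a gene with no velocity signal at all defers
entirely to the expression branch.

*Spline smoothing.* The default spline interpolates (`spline_smoothing =
1`), which is optimal for noise-free simulated data and lets all series on
a shared time grid be fit in one vectorized call. For noisy data, set an
explicit smoothing level (`p ∈ (0,1)`, csaps-style, mapped to a roughness
penalty `(1−p)/p`) or `None` for per-series generalized cross-validation.
GCV is the principled choice under noise but costs a per-series model
selection, which is why it is not the default for the large noiseless
recovery studies.

**Regulatory parameters.** Labeled observations make hyperplane recovery a
linear binary classification problem: minimize `λ‖T‖² + Σ_p L(y_p, x_p)`
with the binomial-deviance loss (logistic regression, default) or hinge
loss (linear SVM, `method="svm"`). Both are convex, so the fit is
deterministic. The solver is scikit-learn's `newton-cholesky` (logistic) /
liblinear (hinge) with `C = 1/(2λ)`; the default regularization weight is
`λ = 1/P` — weak, since the synthetic studies are noiseless; raise it for
noisy data. Fits are reported raw and normalized to `‖(T, h)‖ = 1`; the
classifier's own ON side orients the normal, so a discrepancy near 2
genuinely flags an inverted state assignment. If every observation of a
gene carries the same label the hyperplane is unidentifiable; the gene is
skipped and counted, with an error message pointing at the thresholds.

**Kinetic parameters.** The *slope* method solves the overdetermined
linear system `v = R − λx` (ON) / `v = −λx` (OFF) by least squares,
dropping `exclude_k` timepoints (default 2, balancing bias against data
loss at 21 timepoints) on each side of every label flip, where spline
velocities are least reliable. With exact velocities and correct labels it
is exact to machine precision. The *analytic* alternative fits the
closed-form segment solution to the concentrations themselves, anchoring
each constant-label run at its first observed value — useful when
velocities are unreliable; a flat series at steady state is flagged as
unidentifiable (only `R/λ` is constrained).

For spatial data the *kink* method estimates `(R, λ, D)` per gene from the
steady gradient flanking a synthesis domain: pick the time class with the
highest spatial maximum (closest to steady state), locate domains as local
maxima with prominence ≥ 10% of the gene's global maximum (suppressing
noise bumps), keep the highest, place borders where expression first falls
to half the domain peak (linear interpolation, rounded to the nearest
nucleus), and fit `A e^{−γ·distance}` to the flank nuclei beyond the
borders. A steady profile alone is invariant under `(R, λ, D) → (cR, cλ,
cD)`, so only the plateau `R/λ` and `γ = √(λ/D)` are identifiable from it;
the absolute timescale is recovered from the temporal approach of the peak
nucleus to its plateau (log-linear fit of `plateau − x(t)`), after which
`R = λ·plateau` and `D = λ/γ²`. When the data contain no transient this is
flagged and a unit timescale returned — refinement then sets the scale.
Domains touching the region edge are fit one-sided, with a warning.
Note that on a discrete lattice the true flank decay is
`arccosh(1 + λ/2D)` rather than `√(λ/D)`; the two agree when the decay
length spans several nuclei, the regime the estimator is meant for.

**Refinement.** Nelder–Mead simplex minimization of `χ² = Σ_{n,g,t} (x̃ −
x)²` between data and the sigmoid-model solution, excluding upstream genes
and the initial time slice. Cell-autonomous datasets run through the same
code path as spatial ones (each trajectory an isolated nucleus with `D =
0`), so both kinds of data share one cost surface. The search is
unconstrained (no sign constraint on any parameter; rates are floored at
1e−12 only to keep the simulator defined); the initial simplex steps each
parameter by 10% of its magnitude (0.1 for zeros); convergence tolerance
is 1e−4 on the cost. Diverged simulations return a large finite penalty
(1e30) so the simplex can back out. The best parameter vector ever
evaluated is returned, so the final cost never exceeds the initial one.
RMS is reported as `√(χ²/N_obs)` with `N_obs` the residual count; both
`χ²` and `N_obs` are logged so any convention can be recomputed.

## Simulators and numerics

*Event-driven Glass integrator* (`integrate_glass`): within a constant
ON/OFF configuration every coordinate follows its closed form exactly;
crossings of any switching hyperplane are detected by scanning `u(t)` (a
sum of exponentials) on a fine grid in windows and resolved by bisection
to 1e−10 in time. Attracting switching surfaces produce sliding modes
that no event sequence can cross; after several near-zero-length events
the integrator takes a short forced step (1e−3, doubling up to 2e−2 while
chattering persists) with the current regime frozen. This is the only
approximation, and it is confined to sliding segments.

*Batch Glass integrator* (`integrate_glass_batch`): fixed-step exponential
stepping with the configuration frozen per step, fully vectorized over
trajectories. Exact between events; switching times are quantized to the
step (default 1e−3, far below the 0.1 sampling interval of the benchmark
protocol). `sample_trajectories` uses this scheme so that a 100-circuit ×
100-trajectory study runs in seconds; on non-sliding trajectories it
matches the event-driven reference to ~1e−3 in concentration.

*Spatial RK4*: classical fixed-step RK4 with step `span/1000` by default,
capped at `0.2/max(D)` to stay inside the explicit-diffusion stability
limit; halving the default step changes outputs by far less than 1e−6 on
circuits in the package's usual parameter ranges.

## Synthetic data

`random_circuit`/`sample_trajectories` implement the validation protocol:
`R_g, λ_g ~ U[0.5, 2]`; unit hyperplane normals uniform on the G-sphere
(normalized Gaussians — exact and dimension-general); thresholds `h_g =
−T̂_g·x_cen` with `x_cen` uniform in the bounding hypercube, so every
hyperplane cuts the region where data live; `N` trajectories from uniform
random starting points, sampled at `Nt` equally spaced timepoints on
[0, 2]. Degenerate draws (hyperplanes barely clipping the hypercube) are
kept, not resampled. Optional measurement noise is additive Gaussian
clipped at zero; the benchmark conditions themselves are noiseless.
Each circuit of a recovery experiment gets its own RNG stream spawned from
the experiment seed, so circuit `k` is reproducible in isolation.

`gap_gene_like_circuit`/`sample_spatial_dataset` provide a fixed
segmentation-style fixture: four dynamic genes read an anterior
exponential gradient and a posterior ramp (static external inputs) and
repress one another, producing four ordered expression domains across 50
nuclei over an initial slice plus eight 6.25-min time classes. Every
coupling of the dynamic genes is nonzero, so the full sign structure is
identifiable in principle. Rates (λ = 0.07/min, plateau 1, D = 0.15
nuclei²/min) give ~10-min half-lives and flank gradients a few nuclei
wide.

What the generator does *not* emulate: immunofluorescence error structure
(spatially correlated, intensity-dependent noise), embryo-to-embryo
registration artifacts, mitotic divisions, or mRNA/protein two-stage
kinetics. Passing the synthetic benchmarks therefore demonstrates
correctness of the estimators under the model's own assumptions, not
robustness to real-data pathologies; the noise hooks and smoothing options
exist for probing the latter.

## Evaluation

`hyperplane_discrepancy` is `δT = ‖T̂_inf − T̂_true‖` between unit
normals: 0 perfect, √2 orthogonal, 2 maximal (inverted ON/OFF assignment).
An uninformed inference — normals uniform on the G-sphere — gives the null
density `P0(δT) ∝ δT^{G−2}(1 − δT²/4)^{(G−3)/2}` on [0, 2], normalized by
quadrature in `null_dT_pdf`; equivalently `δT²/4 ~ Beta((G−1)/2, (G−1)/2)`,
which `null_dT_cdf` uses and the tests cross-check by quadrature and
Monte-Carlo sphere sampling. Sign accuracy scores all entries of
non-upstream `T` rows, exact zeros matching only zeros.
`run_recovery_experiment` aggregates `δT`, `|Δh|`, `|ΔR|`, `|Δλ|` over
`n_circuits × G` hyperplanes; genes with single-class labels are excluded
and counted.

## Problem sizes

The acceptance script runs the full protocol (100 circuits per condition,
G = 20 and 50, N = 100, Nt = 21; ~2 min on one CPU). The test suite runs
the same experiments at 10–20 circuits, and the trend studies (Nt ∈ {11,
21, 41}, N ∈ {10, 25, 50, 100}, G ∈ {10, 20}) at 12 circuits each —
enough that medians over hundreds of hyperplanes are stable to a few
percent.

## Known limitations

- Sliding modes in Glass dynamics are stepped across, not solved by a
  Filippov construction; trajectories hugging an attracting switching
  surface carry O(step) wiggle.
- The kink estimator needs a transient in the data to set the absolute
  timescale, assumes the domain interior is near cell-autonomous, and
  inherits the discrete-lattice correction to `γ` for narrow gradients;
  its output is an initial guess for refinement, not a final estimate.
- Refinement is local by design; it polishes the classification-based
  estimates and will not escape a wrong basin.
- With very few trajectories the classification is under-determined; the
  inference degrades smoothly (quantified by the distance of the `δT`
  distribution from the null) but per-gene failures (single-class labels)
  become common and are reported rather than guessed at.
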