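# Methods

This note records the models, the numerical choices behind them, and
the places where the design was genuinely open.  Everything stated
here is computed by the package's tests or scripts; nothing is quoted
from elsewhere.

## Gaussian bottleneck

For jointly Gaussian past/future pairs the optimal representation is
`X~ = A X_past + ξ` with unit-variance noise.  Writing
`M = Σ_{past|future} Σ_past^{-1}`, the left eigenvectors `w_i` of M
with eigenvalues `λ_i ∈ (0, 1]` are the candidate encoding directions;
direction i activates at the critical trade-off `β_i^c = 1/(1−λ_i)`
with gain `α_i² = (β(1−λ_i) − 1)/(λ_i r_i)`, `r_i = w_iᵀ Σ_past w_i`.
We compute the spectrum through the symmetric generalized eigenproblem
`Σ_{past|future} w = λ Σ_past w` (numerically equivalent, better
conditioned), fix eigenvector signs by a positive first component, and
evaluate any linear encoder — optimal, rotated, or transferred — with
the same two log-determinant formulas, so there is a single
information-evaluation code path.  Internal logs are natural;
conversion to bits happens at the interface.  Covariances are
symmetrized after every conditioning step and validated as PSD with a
relative eigenvalue tolerance of 1e-10.

Optimality is enforced by test, not by trust in the gain formula: 200
random encoders rescaled to the optimum's compression never exceed its
predictive information by more than 1e-6 bits.

## Damped-oscillator statistics

In rescaled coordinates the state `(x, v)` has drift matrix
`[[0, 1], [−1/(4ζ²), −1]]` and stationary covariance
`diag(1, 1/(4ζ²))` — the noise intensity on v is `1/(2ζ²)`, the value
the Lyapunov equation forces for that stationary law.  The lag-Δt
cross covariance is `Σ e^{MᵀΔt}`, with the matrix exponential by
scaling-and-squaring in every damping regime.

Closed forms used as independent oracles all reduce to the 2×2 matrix
`B = Σ GᵀΣ^{-1} G` (`G = e^{MΔt}`), whose entries are elementary in
`u = cos ωΔt` and `v = sin(ωΔt)/ω` with `ω² = 1/(4ζ²) − 1/4`:

- curve slope at the origin: `1 − λ₁ = e^{−Δt}(g + √(g²−1))`,
  `g = 1 + v²/2`;
- encoder angle: `tan φ = (ν₁ − B₁₁)/B₂₁` with `ν₁ = 1 − λ₁`,
  `B₂₁ = e^{−Δt} v²/(4ζ²)`;
- total predictive information:
  `−½ log₂(1 − e^{−Δt}(2 + v²) + e^{−2Δt})`.

Overdamped parameters continue these through `ω → i|ω|` with
explicitly scaled hyperbolic functions (all intermediates bounded, no
overflow at large lags).  Small lags hit cancellation, so two series
branches take over: `tan φ = Δt/2 + O(Δt³)` below Δt = 1e-3 (the
coefficient 1/2 is exact and ζ-independent), and
`det(I−B) = Δt⁴/(12ζ²)(1−Δt)` below 3e-3.  Exact small-lag laws worth
noting, both verified against the numeric eigen-decomposition:
`λ₁ = Δt³/(24ζ²) + O(Δt⁴)`, and the total information diverges as
`−2 log₂ Δt` (conditional position variance is O(Δt³), velocity
O(Δt)).  At large lags the overdamped angle tends to π/4 with a
finite-damping offset of exactly `1/(8ζ²)`.

The Kalman baseline observes both coordinates once per prediction lag
with isotropic noise `r·I`, iterates the discrete Riccati recursion to
a relative change below 1e-12, and treats the posterior mean as the
representation.  Its joint stationary covariance with the state comes
from a four-dimensional discrete Lyapunov equation, and both
informations use the same Gaussian formulas as everything else.  The
observation model and sweep of r are configurable; the qualitative
conclusion (filter points at or below the information curve) is
insensitive to them.

Transferability Q integrates the frozen-encoder predictive information
over ζ′ ∈ (1/3, 3), Δt′ ∈ (0.1, 10) and normalizes by the integral of
the optimum at the same compression.  The integral is a linear-measure
trapezoid on log-spaced grids (the measure is configurable; rankings
reported by the package were checked to be stable between linear and
log measure, and Q is stable to ±2% under grid doubling).  Note one
deliberate asymmetry of frozen-gain transfer: an encoder tuned for a
low-variance velocity coordinate, applied to a model whose velocity
variance is larger, captures *more* past information than its source
compression level, which can push Q above 1.

## Long-memory (GLE) windows

The friction kernel is `γ/(lag + dt_sim)^α` (the one-step offset
regularizes the integrable singularity) and the noise is drawn with
the matching power-law covariance, factorized once per trajectory
length by symmetric eigendecomposition with eigenvalue flooring.
Integration is semi-implicit Euler; the history integral is a
rectangle rule over the full stored past.  Defaults α = 0.5, γ = 2,
ω₀ = 1, dt_sim = 0.1 put the position autocovariance on a clean
`τ^{−α}` scaling window over lags ≈ 2–12 while keeping trajectories
stable; these defaults define the study conditions for all
window analyses.  The trap ω₀ is required for a stationary position
process; without it the power-law tail is not observable.

The window joint is block Toeplitz in the estimated autocovariance
c(τ): past samples at `t−t₀ … t`, future at `t+Δt … t+Δt+t₀`, spacing
dt_grid, stacked covariance floored to PSD at 1e-10 of its largest
eigenvalue (c is a Monte-Carlo estimate).  Window grids should sit on
exact simulated lags: interpolating c below the simulation grid
manufactures spurious fine-scale information.  For the same reason no
claim is made that refining dt_grid converges at practical densities —
denser position windows genuinely carry more information when the
noise is correlated at all scales — while refining the *integration*
step dt_sim at fixed windows is a true convergence check and is tested
to stay within the seed-to-seed Monte-Carlo band.  Velocity samples
are excluded from the windows (densely sampled positions carry the
same content); this is configurable in principle but not exposed.

Saturation analyses share one autocovariance estimate across all t₀
values so the curve is smooth in the common noise; the curve of
maximal predictive information versus t₀ is nondecreasing with
shrinking increments.

## Wright–Fisher diffusion and discrete bottleneck

Time is in generations.  Drift `s x(1−x) + μ(1−2x)` with
`μ = Nμ/N, s = Ns/N`; the Fokker–Planck diffusion coefficient is
`D(x) = x(1−x)/N`, the value consistent with the stationary law
`[x(1−x)]^{Nμ−1} e^{Ns x}` under that drift.  (The commonly used
per-generation binomial variance `x(1−x)/N` would give stationary
exponent `2Nμ−1`; the package's binomial-chain simulator therefore
applies two half-drift resampling rounds per generation so that chain
and diffusion agree — total-variation 0.017 between the chain's
stationary histogram and the analytic cells at the default
parameters.)

The grid is the N+1 frequencies including boundaries (half cells at
the ends).  The generator is an equilibrium-preserving finite-volume
scheme: interface conductances `D ψ / dx` built from the unnormalized
stationary density ψ, fluxes proportional to differences of
mass-to-equilibrium ratios.  This gives exact discrete detailed
balance — the cell-integrated analytic law is the chain's fixed point
to machine precision — together with conservation and positivity, and
it handles the integrable boundary singularities of ψ for Nμ < 1
(cell masses by adaptive quadrature).  Propagation over the lag uses
Crank–Nicolson with substeps of at most 0.01 generations; entries
below −1e-10 raise, smaller negatives are clipped and rows
renormalized.  The stationary joint is `Ps(x) T[x→x′]` with Ps the
propagator's own leading eigenvector.

Blahut–Arimoto iterates the standard self-consistent equations with
decoder probabilities floored at 1e-300 before logs.  The IB
Lagrangian is checked nonincreasing when requested; solves stop when
it changes by less than 1e-10.  Fixed points near bifurcations depend
on initialization, so solves support seeded restarts (perturbed
uniform), warm-started upward annealing in β, and best-of-restarts
selection by predictive information.  Near the first critical β
(≈ 1.007 for the default model) convergence is critically slow and the
iteration cap matters; the package uses 2·10⁴ iterations there, at
which every restart reaches the same fixed point.

Two conventions matter for encoder *transfer* between models and were
genuinely open:

- **Effective support.** At a BA fixed point the rows of q(x̃|x) at
  states of (numerically) zero stationary mass are unconstrained by
  the objective: exact iteration hard-assigns them by amplifying
  meaningless tail preferences, yet they dominate a transfer to a
  model whose mass lives there.  The package defines an encoder's
  support as the cells a finite stationary history visits at least
  once in expectation — `Ps(x) ≥ 1/n_history`, default
  n_history = 1000 generations (≈ 10 N, a few relaxation times of the
  slowest default model) — and completes off-support rows with the
  maximum-entropy choice, the cluster marginal.  On the training model
  this changes nothing measurable; under transfer it is the difference
  between an encoder that claims knowledge of states it never saw and
  one that does not.
- **Near-saturating β.** "β large enough that the m-state channel is
  full" is implemented as the smallest β on a 28-point log grid
  [1.5, 64] whose i_past reaches 98.5% of its own large-β plateau.
  This lands at β ≈ 4.6 for the low-mutation model and β ≈ 56 for the
  high-mutation one, whose soft tails saturate much more slowly.

Effective cardinality drops clusters below a mass tolerance and merges
decoders closer than a Jensen–Shannon divergence tolerance (defaults
1e-4 and 1e-3 bits); merging is idempotent.

## Problem sizes

Default analysis sizes are chosen so the full suite runs in a few
minutes on one CPU: 10⁶-step oscillator trajectories for stationary
checks, 10⁶ chain samples for the Wright–Fisher histogram and 10⁵
replicates per transition row, 8–10 GLE trajectories of 1.5–4·10³
steps per autocovariance, and 3–4 BA restarts per solve.  All
simulation-based tests compare within explicit Monte-Carlo error
bands, so the conclusions do not depend on these sizes.

## What the synthetic data does and does not show

The simulators generate data with exactly the statistical structure
the analyses assume: stationary Gaussian oscillator paths, power-law
correlated GLE paths, binomial Wright–Fisher chains.  Passing tests
therefore demonstrate internal consistency (model construction,
solver optimality, discretization convergence) — not that any real
sensory or evolutionary system is described by these dynamics, nor
anything about measurement noise, non-stationarity, or model mismatch
in real recordings.

## Known limitations

- The Gaussian solver covers linear encoders only; no variational or
  neural approximations.
- Wright–Fisher is single-locus, biallelic, fixed N; Δt below ~0.01
  generations is limited by the substep cap.
- The GLE analysis estimates second moments from finite simulations;
  window information at fine sampling inherits their Monte-Carlo
  noise, and no closed-form spectral route is provided.
- Transfer conclusions for the discrete model depend on the effective
  support convention above; with an infinite-history support the
  high-to-low mutation transfer would instead inherit the tail
  assignments and look nearly lossless.
- The m=200, β=20 bottleneck solution is reported at its converged
  fixed point; annealing and restarts find no competing branch, and
  the converged predictive information sits within ~0.15 bits of the
  channel's total mutual information.
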