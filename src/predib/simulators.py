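"""Seeded trajectory simulators and empirical joint estimation.

These are the brute-force oracles for the model-construction modules:
exact discrete-time sampling of the damped oscillator, the binomial
resampling chain for Wright-Fisher, and direct integration of the
generalized Langevin equation with factorized power-law noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.signal import lfilter

from .gaussian_ib import JointGaussian
from .sddho import drift_matrix, stationary_covariance
from .wright_fisher import DiscreteJoint, WFParams


@dataclass
class Trajectory:
    """Sampled path: times, per-time states, provenance."""

    times: np.ndarray
    states: np.ndarray          # shape (n_times,) or (n_times, dim)
    seed: int | None
    params: dict

    def __post_init__(self):
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite values")


# ---------------------------------------------------------------------------
# damped harmonic oscillator
# ---------------------------------------------------------------------------

def simulate_sddho(zeta: float, dt_sim: float, n_steps: int,
                   seed: int | None = 0, noise: bool = True,
                   x0: np.ndarray | None = None) -> Trajectory:
    """Exact discrete-time sampling of the rescaled oscillator.

    The update over one step is the exact Gaussian transition
    ``X_{k+1} = G X_k + w_k`` with ``G = exp(M dt)`` and noise
    covariance ``Q = Sigma - G Sigma G^T`` -- no Euler discretization
    bias, so long-run statistics match the stationary law exactly.
    The coupled recursion is evaluated by diagonalizing G and running
    two scalar complex AR(1) filters.
    """
    if dt_sim > 0.01 * min(1.0, 4 * zeta ** 2):
        raise ValueError("dt_sim too coarse for the requested zeta")
    S = stationary_covariance(zeta)
    G = expm(drift_matrix(zeta) * dt_sim)
    rng = np.random.default_rng(seed)
    if noise:
        Q = S - G @ S @ G.T
        Q = (Q + Q.T) / 2
        w, V = np.linalg.eigh(Q)
        Lc = V * np.sqrt(np.clip(w, 0, None))
        innov = rng.standard_normal((n_steps, 2)) @ Lc.T
        z0 = rng.multivariate_normal(np.zeros(2), S) if x0 is None else x0
    else:
        innov = np.zeros((n_steps, 2))
        z0 = np.array([1.0, 0.0]) if x0 is None else x0
    d, P = np.linalg.eig(G)
    Pinv = np.linalg.inv(P)
    # y_{k+1} = d y_k + u_k in the eigenbasis; lfilter runs the recursion
    u = innov.astype(complex) @ Pinv.T
    y0 = Pinv @ z0.astype(complex)
    ys = np.empty((n_steps + 1, 2), complex)
    ys[0] = y0
    for i in range(2):
        zi = d[i] * y0[i]
        ys[1:, i] = lfilter([1.0], [1.0, -d[i]], u[:, i], zi=[zi])[0]
    states = (ys @ P.T).real
    times = np.arange(n_steps + 1) * dt_sim
    return Trajectory(times=times, states=states, seed=seed,
                      params={"model": "sddho", "zeta": zeta,
                              "dt_sim": dt_sim})


# ---------------------------------------------------------------------------
# Wright-Fisher binomial chain
# ---------------------------------------------------------------------------

def simulate_wf(params: WFParams, n_gen: int, n_reps: int = 1,
                seed: int | None = 0, x0: float = 0.5,
                steps_per_unit: int = 2) -> list[Trajectory]:
    """Binomial resampling chain on the N+1 frequency grid.

    Each unit of time applies ``steps_per_unit`` binomial resampling
    rounds of N offspring, each with 1/steps_per_unit of the
    deterministic drift, ``X' ~ Binomial(N, f(X))/N`` with
    ``f(X) = clip(X + [s X(1-X) + mu(1-2X)]/steps_per_unit)``.  The
    default of two rounds per unit calibrates the chain's diffusion
    limit (variance 2 x(1-x)/N per unit time) to the package's
    Fokker-Planck convention and its stationary law.
    """
    rng = np.random.default_rng(seed)
    N = params.N
    mu, s = params.mu, params.s
    k = np.full(n_reps, int(round(x0 * N)), dtype=np.int64)
    out = np.empty((n_gen + 1, n_reps), dtype=np.int64)
    out[0] = k
    for t in range(n_gen):
        for _ in range(steps_per_unit):
            x = k / N
            f = x + (s * x * (1 - x) + mu * (1 - 2 * x)) / steps_per_unit
            k = rng.binomial(N, np.clip(f, 0.0, 1.0))
        out[t + 1] = k
    times = np.arange(n_gen + 1, dtype=float)
    return [Trajectory(times=times, states=out[:, r] / N, seed=seed,
                       params={"model": "wright_fisher", "N": N,
                               "n_mu": params.n_mu, "n_s": params.n_s,
                               "rep": r})
            for r in range(n_reps)]


def wf_transition_histogram(params: WFParams, x0: float, n_reps: int,
                            seed: int | None = 0,
                            steps_per_unit: int = 2) -> np.ndarray:
    """Empirical one-lag transition row from ``n_reps`` replicates."""
    rng = np.random.default_rng(seed)
    N = params.N
    mu, s = params.mu, params.s
    n_rounds = int(round(params.dt_pred * steps_per_unit))
    k = np.full(n_reps, int(round(x0 * N)), dtype=np.int64)
    for _ in range(n_rounds):
        x = k / N
        f = x + (s * x * (1 - x) + mu * (1 - 2 * x)) / steps_per_unit
        k = rng.binomial(N, np.clip(f, 0.0, 1.0))
    return np.bincount(k, minlength=N + 1) / n_reps


# ---------------------------------------------------------------------------
# generalized Langevin equation
# ---------------------------------------------------------------------------

def gle_noise_factor(alpha: float, gamma: float, dt_sim: float,
                     n_steps: int) -> np.ndarray:
    """Factor of the power-law noise covariance over one trajectory.

    Fluctuation-dissipation fixes ``<xi(t) xi(t')> = gamma /
    (|t - t'| + dt)^alpha`` (the kernel self-interaction is offset by
    one step, regularizing the integrable singularity).  The covariance
    is factorized by symmetric eigendecomposition with eigenvalue
    flooring, reused across trajectories.
    """
    tt = np.arange(n_steps) * dt_sim
    C = gamma / (np.abs(tt[:, None] - tt[None, :]) + dt_sim) ** alpha
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-12 * w.max(), None)
    return V * np.sqrt(w)


def simulate_gle(alpha: float, gamma: float, omega0: float, dt_sim: float,
                 n_steps: int, seed: int | None = 0,
                 noise_factor: np.ndarray | None = None,
                 kernel_horizon: float | None = None) -> Trajectory:
    """Integrate the GLE with power-law friction memory.

    Semi-implicit Euler with the history integral evaluated by the
    rectangle rule over the (optionally truncated) kernel
    ``gamma / (lag + dt)^alpha``.  Raises if the trajectory diverges
    (|x| > 1e6), which signals too coarse a dt_sim.
    """
    rng = np.random.default_rng(seed)
    if noise_factor is None:
        noise_factor = gle_noise_factor(alpha, gamma, dt_sim, n_steps)
    xi = noise_factor @ rng.standard_normal(n_steps)
    lags = np.arange(n_steps) * dt_sim + dt_sim
    kern = gamma / lags ** alpha
    if kernel_horizon is not None:
        kern[lags > kernel_horizon] = 0.0
    x = np.zeros(n_steps)
    v = np.zeros(n_steps)
    for k in range(n_steps - 1):
        mem = np.dot(kern[:k + 1][::-1], v[:k + 1]) * dt_sim
        a = -mem - omega0 ** 2 * x[k] + xi[k]
        v[k + 1] = v[k] + a * dt_sim
        x[k + 1] = x[k] + v[k + 1] * dt_sim
        if abs(x[k + 1]) > 1e6:
            raise RuntimeError("GLE trajectory diverged; reduce dt_sim")
    times = np.arange(n_steps) * dt_sim
    return Trajectory(times=times, states=np.column_stack([x, v]),
                      seed=seed, params={"model": "gle", "alpha": alpha,
                                         "gamma": gamma, "omega0": omega0,
                                         "dt_sim": dt_sim})


# ---------------------------------------------------------------------------
# empirical joints
# ---------------------------------------------------------------------------

def empirical_joint(ensemble: list[Trajectory], dt_pred: float,
                    kind: str, burn_in: int = 0,
                    grid_n: int | None = None):
    """Estimate a (past, future) joint from stationary trajectories.

    ``kind='gaussian'`` returns a :class:`JointGaussian` from the
    sample covariances of lagged state pairs; ``kind='discrete'``
    returns a :class:`DiscreteJoint` from the bivariate histogram on
    the Wright-Fisher grid.  Fewer than 1e4 pairs triggers a metadata
    warning (stored on the returned object as ``meta``).
    """
    pairs_x = []
    pairs_y = []
    for tr in ensemble:
        dt_samp = tr.times[1] - tr.times[0]
        lag = int(round(dt_pred / dt_samp))
        if lag < 1:
            raise ValueError("dt_pred below the sampling interval")
        s = tr.states[burn_in:]
        pairs_x.append(s[:-lag])
        pairs_y.append(s[lag:])
    X = np.concatenate(pairs_x)
    Y = np.concatenate(pairs_y)
    meta = {"n_pairs": len(X)}
    if len(X) < 10_000:
        meta["warning"] = "fewer than 1e4 stationary pairs"
    if kind == "gaussian":
        X = np.atleast_2d(X.T).T
        Y = np.atleast_2d(Y.T).T
        Z = np.hstack([X, Y])
        Z = Z - Z.mean(axis=0)
        C = Z.T @ Z / len(Z)
        d = X.shape[1]
        out = JointGaussian(sigma_past=C[:d, :d], sigma_future=C[d:, d:],
                            sigma_cross=C[:d, d:])
        out.meta = meta
        return out
    if kind == "discrete":
        if grid_n is None:
            raise ValueError("grid_n required for discrete joints")
        a = np.rint(X * grid_n).astype(int)
        b = np.rint(Y * grid_n).astype(int)
        J = np.zeros((grid_n + 1, grid_n + 1))
        np.add.at(J, (a, b), 1.0)
        J /= J.sum()
        out = DiscreteJoint(grid=np.linspace(0, 1, grid_n + 1), p_joint=J)
        out.meta = meta
        return out
    raise ValueError(f"unknown joint kind {kind!r}")
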