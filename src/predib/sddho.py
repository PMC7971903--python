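"""Stochastically driven damped harmonic oscillator (SDDHO).

Rescaled coordinates: time in units of the relaxation time tau and
position in units of the thermal length, so the stationary law is
``<x^2> = 1``, ``<v^2> = 1/(4 zeta^2)`` and the equation of motion is

    dx/dt = v,    dv/dt = -x/(4 zeta^2) - v + noise,

with white noise of intensity ``1/(2 zeta^2)`` on v (the value forced
by the stationary law).  The only parameters are the damping
coefficient ``zeta`` and the prediction lag ``dt_pred``; the natural
frequency is ``omega = sqrt(1/(4 zeta^2) - 1/4)``, imaginary in the
overdamped regime ``zeta > 1`` where trigonometric expressions
continue to hyperbolic ones.

Closed forms used throughout derive from the 2x2 matrix
``B = Sigma G^T Sigma^{-1} G`` with propagator ``G = exp(M dt)``:
``Sigma_{past|future} Sigma_past^{-1} = I - B``, ``tr B =
exp(-dt) (2 + sin^2(omega dt)/omega^2)`` and ``det B = exp(-2 dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm, solve_discrete_lyapunov

from .gaussian_ib import (
    LOG2,
    GaussianEncoder,
    InfoPoint,
    JointGaussian,
    analytic_info,
    beta_for_past_info,
    conditional_covariances,
    encoder_at_past_info,
    evaluate_encoder,
    ib_spectrum,
)

__all__ = [
    "SDDHOParams", "TransferMap", "drift_matrix", "stationary_covariance",
    "sddho_joint", "leading_angle", "slope_at_origin",
    "total_predictive_info", "fixed_info_sweep", "transfer_gaussian",
    "q_transfer", "kalman_curve",
]


@dataclass(frozen=True)
class SDDHOParams:
    """Damping coefficient and rescaled prediction lag."""

    zeta: float
    dt_pred: float

    def __post_init__(self):
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.dt_pred <= 0:
            raise ValueError("dt_pred must be positive")

    @property
    def omega_sq(self) -> float:
        """omega^2 = 1/(4 zeta^2) - 1/4; negative when overdamped."""
        return 1.0 / (4.0 * self.zeta ** 2) - 0.25

    @property
    def regime(self) -> str:
        if self.zeta < 1.0:
            return "underdamped"
        if self.zeta == 1.0:
            return "critical"
        return "overdamped"


def drift_matrix(zeta: float) -> np.ndarray:
    return np.array([[0.0, 1.0], [-1.0 / (4.0 * zeta ** 2), -1.0]])


def stationary_covariance(zeta: float) -> np.ndarray:
    """diag(1, 1/(4 zeta^2)); solves the Lyapunov equation for the drift."""
    return np.diag([1.0, 1.0 / (4.0 * zeta ** 2)])


def sddho_joint(params: SDDHOParams) -> JointGaussian:
    """Joint Gaussian of (x, v) at times t and t + dt_pred.

    The cross block is ``Sigma exp(M dt)^T``; the propagator is
    evaluated by scaling-and-squaring uniformly across regimes.
    """
    S = stationary_covariance(params.zeta)
    G = expm(drift_matrix(params.zeta) * params.dt_pred)
    return JointGaussian(sigma_past=S, sigma_future=S, sigma_cross=S @ G.T)


# ---------------------------------------------------------------------------
# closed forms (independent of the numeric eigendecomposition path)
# ---------------------------------------------------------------------------

def _trig(params: SDDHOParams) -> tuple[float, float, float]:
    """Return (u, v, scale) with u = cos(w dt) e^{-s}, v = sin(w dt)/w e^{-s}
    and log-scale s, continued through the overdamped regime.

    Scaling by ``e^{-s}`` with ``s = |omega| dt`` (overdamped) keeps the
    hyperbolic functions bounded at large lags.
    """
    w2 = params.omega_sq
    t = params.dt_pred
    if w2 > 1e-12:
        w = np.sqrt(w2)
        return float(np.cos(w * t)), float(np.sin(w * t) / w), 0.0
    if w2 < -1e-12:
        r = np.sqrt(-w2)
        s = r * t
        # cosh, sinh scaled by e^{-s}
        u = (1.0 + np.exp(-2 * s)) / 2.0
        v = (1.0 - np.exp(-2 * s)) / (2.0 * r)
        return float(u), float(v), float(s)
    # near critical damping: series in w2 * t^2
    u = 1.0 + w2 * t * t / 2.0
    v = t * (1.0 + w2 * t * t / 6.0)
    return float(u), float(v), 0.0


def slope_at_origin(params: SDDHOParams) -> float:
    """Initial slope 1 - lambda_1 of the information curve.

    Closed form ``exp(-dt) (g + sqrt(g^2 - 1))`` with
    ``g = 1 + sin^2(omega dt) / (2 omega^2)`` (hyperbolic continuation
    in the overdamped regime).
    """
    u, v, s = _trig(params)
    t = params.dt_pred
    # g e^{-2s} and e^{-2s}, to keep arithmetic bounded
    g_sc = np.exp(-2 * s) + v * v / 2.0
    root = np.sqrt(max(g_sc * g_sc - np.exp(-4 * s), 0.0))
    return float(np.exp(2 * s - t) * (g_sc + root))


def leading_angle(params: SDDHOParams) -> float:
    """Angle of the leading encoding direction from the position axis.

    Derived from the explicit entries of ``B = Sigma G^T Sigma^{-1} G``:
    the leading left eigenvector is proportional to
    ``(B_21, nu_1 - B_11)`` where ``nu_1 = 1 - lambda_1``.  The angle
    lies in [0, pi/2) and vanishes at the removable singularities
    ``omega dt = n pi`` (position-only encoding).
    """
    t = params.dt_pred
    if t < 1e-3:
        # exact small-lag limit: tan(phi) = dt/2 + O(dt^3) for every zeta
        # (the closed form below loses the O(dt^3) numerator to rounding)
        return float(np.arctan(t / 2.0))
    u, v, s = _trig(params)
    s2 = 1.0 / (4.0 * params.zeta ** 2)      # <v^2>
    # entries share the factor exp(-dt + 2s), which cancels in the ratio:
    # B21 = s2 v^2,  B11 = (u + v/2)^2 + s2 v^2,  and the largest
    # eigenvalue of B is nu = g + sqrt(g^2 - 1) with g = e^{-2s} + v^2/2.
    b21 = s2 * v * v
    b11 = (u + v / 2.0) ** 2 + s2 * v * v
    g_sc = np.exp(-2 * s) + v * v / 2.0
    nu_sc = g_sc + np.sqrt(max(g_sc * g_sc - np.exp(-4 * s), 0.0))
    if b21 <= 1e-14 * max(b11, 1e-300):
        return 0.0   # removable singularity (omega dt = n pi): position only
    return float(np.arctan2(nu_sc - b11, b21))


def total_predictive_info(params: SDDHOParams) -> float:
    """I(X_t; X_{t+dt}) in bits.

    ``-1/2 log2 det(I - B)`` with
    ``det(I - B) = 1 - e^{-dt}(2 + sin^2(omega dt)/omega^2) + e^{-2 dt}``.
    """
    t = params.dt_pred
    if t < 3e-3:
        # det(I - B) = dt^4 (1 + 4 omega^2)/12 (1 - dt) + O(dt^6)
        #            = dt^4 / (12 zeta^2) (1 - dt); avoids cancellation
        det = t ** 4 / (12.0 * params.zeta ** 2) * (1.0 - t)
        return float(-0.5 * np.log2(det))
    u, v, s = _trig(params)
    tr = np.exp(2 * s - t) * (2.0 * np.exp(-2 * s) + v * v)
    det = 1.0 - tr + np.exp(-2.0 * t)
    det = max(det, 1e-300)
    return float(-0.5 * np.log2(det))


# ---------------------------------------------------------------------------
# fixed-information sweeps and transfer analysis
# ---------------------------------------------------------------------------

def fixed_info_sweep(zeta_grid: Sequence[float], dt_grid: Sequence[float],
                     i_past: float) -> list[dict]:
    """Optimal encoders across (zeta, dt) at a fixed compression level.

    For each cell, the tradeoff solving ``i_past(beta) = i_past`` is
    found by monotone inversion, and the conditional covariance
    ellipses of past and future given the representation are attached
    for plotting.
    """
    rows = []
    for z in zeta_grid:
        for dt in dt_grid:
            p = SDDHOParams(zeta=z, dt_pred=dt)
            joint = sddho_joint(p)
            try:
                enc = encoder_at_past_info(joint, i_past,
                                           source={"zeta": z, "dt_pred": dt})
            except RuntimeError as err:
                raise RuntimeError(
                    f"fixed_info_sweep failed at (zeta={z}, dt={dt}): {err}")
            info = evaluate_encoder(enc, joint)
            cp, cf = conditional_covariances(enc, joint)
            rows.append({"zeta": z, "dt_pred": dt, "beta": enc.beta,
                         "encoder": enc, "info": info,
                         "cond_past": cp, "cond_future": cf})
    return rows


def transfer_gaussian(source: SDDHOParams, i_past: float,
                      target: SDDHOParams) -> InfoPoint:
    """Freeze the source-optimal encoder and evaluate it on the target.

    The transferred ``i_past`` generally differs from the source
    compression level; both coordinates are recomputed under the
    target statistics.
    """
    enc = encoder_at_past_info(sddho_joint(source), i_past)
    return evaluate_encoder(enc, sddho_joint(target))


@dataclass
class TransferMap:
    """Transferred-information surface of one frozen encoder."""

    source: SDDHOParams
    i_past_level: float
    zeta_grid: np.ndarray
    dt_grid: np.ndarray
    transfer_future: np.ndarray   # shape (len(zeta_grid), len(dt_grid))
    transfer_past: np.ndarray
    optimal_future: np.ndarray
    q: float = field(default=np.nan)


def transfer_map(source: SDDHOParams, i_past: float,
                 zeta_grid: Sequence[float],
                 dt_grid: Sequence[float]) -> TransferMap:
    enc = encoder_at_past_info(sddho_joint(source), i_past)
    zg = np.asarray(zeta_grid, float)
    dg = np.asarray(dt_grid, float)
    tf = np.zeros((zg.size, dg.size))
    tp = np.zeros_like(tf)
    opt = np.zeros_like(tf)
    for i, z in enumerate(zg):
        for j, dt in enumerate(dg):
            joint = sddho_joint(SDDHOParams(zeta=z, dt_pred=dt))
            pt = evaluate_encoder(enc, joint)
            tf[i, j] = pt.i_future
            tp[i, j] = pt.i_past
            opt[i, j] = analytic_info(
                joint, beta_for_past_info(joint, i_past)).i_future
    return TransferMap(source=source, i_past_level=i_past, zeta_grid=zg,
                       dt_grid=dg, transfer_future=tf, transfer_past=tp,
                       optimal_future=opt)


def q_transfer(source: SDDHOParams, i_past: float,
               zeta_range: tuple[float, float] = (1.0 / 3.0, 3.0),
               dt_range: tuple[float, float] = (0.1, 10.0),
               n_zeta: int = 12, n_dt: int = 12) -> float:
    """Transferability metric Q.

    Ratio of the transferred predictive information integrated over
    the (zeta', dt') region to the integral of the optimal predictive
    information at the same compression level.  Integration uses the
    trapezoid rule in linear measure on log-spaced grids.
    """
    zg = np.geomspace(*zeta_range, n_zeta)
    dg = np.geomspace(*dt_range, n_dt)
    tm = transfer_map(source, i_past, zg, dg)
    if zg.size == 1 and dg.size == 1:
        return float(tm.transfer_future[0, 0] / tm.optimal_future[0, 0])

    def integrate(surface):
        inner = np.trapezoid(surface, dg, axis=1)
        return np.trapezoid(inner, zg)

    q = integrate(tm.transfer_future) / integrate(tm.optimal_future)
    tm.q = float(q)
    return float(q)


# ---------------------------------------------------------------------------
# Kalman-filter baseline
# ---------------------------------------------------------------------------

def _discrete_model(params: SDDHOParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact discrete-time transition (G, Q) over one prediction lag."""
    S = stationary_covariance(params.zeta)
    G = expm(drift_matrix(params.zeta) * params.dt_pred)
    Q = S - G @ S @ G.T
    return G, (Q + Q.T) / 2.0


def kalman_point(params: SDDHOParams, obs_noise: float,
                 tol: float = 1e-12, max_iter: int = 100_000) -> InfoPoint:
    """Information coordinates of a steady-state Kalman filter.

    Both coordinates are observed with isotropic noise ``obs_noise * I``
    once per prediction lag.  The representation is the posterior mean,
    itself a linear-Gaussian function of the state history; its joint
    stationary covariance with the state follows from an augmented
    linear system, and both informations use the Gaussian formulas.
    """
    G, Q = _discrete_model(params)
    R = obs_noise * np.eye(2)
    # steady-state Riccati iteration
    P = stationary_covariance(params.zeta)
    for it in range(max_iter):
        P_pred = G @ P @ G.T + Q
        K = np.linalg.solve((P_pred + R).T, P_pred.T).T
        P_new = (np.eye(2) - K) @ P_pred
        P_new = (P_new + P_new.T) / 2.0
        if np.abs(P_new - P).max() <= tol * max(np.abs(P_new).max(), 1e-30):
            P = P_new
            break
        P = P_new
    else:
        raise RuntimeError("Riccati iteration did not converge")
    # augmented system z = (x, xhat)
    IK = np.eye(2) - K
    A = np.block([[G, np.zeros((2, 2))], [K @ G, IK @ G]])
    noise = np.block([[Q, Q @ K.T],
                      [K @ Q, K @ Q @ K.T + obs_noise * K @ K.T]])
    Sz = solve_discrete_lyapunov(A, (noise + noise.T) / 2.0)
    Sz = (Sz + Sz.T) / 2.0
    Sx = Sz[:2, :2]
    Sh = Sz[2:, 2:]
    C = Sz[:2, 2:]              # Cov(x_t, xhat_t)
    Cf = G @ C                  # Cov(x_{t+dt}, xhat_t)

    def gauss_mi(Sa, Sb, Cab):
        M = np.block([[Sa, Cab], [Cab.T, Sb]])
        s, dj = np.linalg.slogdet(M)
        _, da = np.linalg.slogdet(Sa)
        sb, db = np.linalg.slogdet(Sb)
        if sb <= 0 or s <= 0:
            return 0.0
        return max(0.0, (da + db - dj) / (2 * LOG2))

    return InfoPoint(i_past=gauss_mi(Sx, Sh, C),
                     i_future=gauss_mi(Sx, Sh, Cf))


def kalman_curve(params: SDDHOParams,
                 obs_noise_grid: Sequence[float]) -> list[InfoPoint]:
    """Kalman information points over an observation-noise sweep."""
    grid = np.asarray(obs_noise_grid, float)
    if np.any(grid <= 0):
        raise ValueError("observation noise must be positive")
    return [kalman_point(params, r) for r in grid]
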