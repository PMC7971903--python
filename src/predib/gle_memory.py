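"""Extended-history bottleneck for power-law-memory Langevin dynamics.

The generalized Langevin equation with friction kernel
``gamma / |t - t'|^alpha`` and fluctuation-dissipation-consistent
noise has position autocorrelation decaying as ``t^-alpha``: no single
Markov state summarizes the past.  The bottleneck input is therefore a
window of positions ``X_{t-t0 : t}`` and the relevance variable the
future window ``X_{t+dt : t+dt+t0}``.  The joint covariance of the two
windows is block Toeplitz in the stationary autocovariance, which this
module estimates by simulation (the stationary law of the fractional
dynamics has no simple closed form); the Gaussian IB machinery then
applies unchanged.

Velocity samples are excluded from the windows: densely sampled
positions carry the same information (velocity is a difference of
neighbouring positions in the continuum limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaussian_ib import JointGaussian, analytic_info
from .simulators import gle_noise_factor, simulate_gle


@dataclass(frozen=True)
class GLEParams:
    """Memory exponent, trap, friction, and windowing choices.

    ``alpha`` in (0, 1) sets the power-law memory; ``omega0`` is the
    restoring frequency of the confining potential (needed for a
    stationary position process); ``gamma`` the friction amplitude;
    ``dt_sim`` the integration step; ``t0`` the history/future window
    length; ``dt_pred`` the lag between the windows; ``dt_grid`` the
    sampling interval of window points.
    """

    alpha: float = 0.5
    omega0: float = 1.0
    gamma: float = 2.0
    dt_sim: float = 0.1
    t0: float = 2.0
    dt_pred: float = 1.0
    dt_grid: float = 0.5

    def __post_init__(self):
        if not 0 < self.alpha:
            raise ValueError("alpha must be positive")
        if self.t0 > 0 and self.dt_sim >= self.t0:
            raise ValueError("dt_sim must resolve the window length t0")

    @property
    def window_points(self) -> int:
        """Number of samples per window (1 when t0 = 0)."""
        return int(round(self.t0 / self.dt_grid)) + 1


@dataclass
class Autocovariance:
    """Stationary position autocovariance with standard-error bands."""

    lags: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_traj: int

    def at(self, lag: float) -> float:
        return float(np.interp(abs(lag), self.lags, self.mean))


def _acov_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    n = len(x)
    f = np.fft.rfft(x, 2 * n)
    c = np.fft.irfft(f * np.conj(f))[:max_lag]
    return c / np.arange(n, n - max_lag, -1)


def gle_autocovariance(params: GLEParams, n_traj: int = 8,
                       traj_len: int = 3000, burn_in: int | None = None,
                       seed: int = 0) -> Autocovariance:
    """Estimate c(tau) from seeded trajectory replicates.

    Each replicate is integrated from rest, the first quarter (by
    default) is discarded as burn-in, and the replicate spread yields
    pointwise standard errors.  The lag range covers ``2 t0 + dt_pred``
    (what the extended joint needs) plus margin.
    """
    need = 2 * params.t0 + params.dt_pred
    if traj_len * params.dt_sim < 4 * max(need, params.dt_sim):
        raise ValueError("traj_len too short for the requested windows")
    if burn_in is None:
        burn_in = traj_len // 4
    elif burn_in < traj_len // 4:
        raise ValueError("burn_in must be at least a quarter of traj_len")
    max_lag = min(traj_len - burn_in - 1,
                  int(np.ceil(2 * need / params.dt_sim)) + 10)
    max_lag = max(max_lag, int(np.ceil(need / params.dt_sim)) + 2)
    factor = gle_noise_factor(params.alpha, params.gamma, params.dt_sim,
                              traj_len)
    cs = []
    for k in range(n_traj):
        tr = simulate_gle(params.alpha, params.gamma, params.omega0,
                          params.dt_sim, traj_len, seed=seed + k,
                          noise_factor=factor)
        cs.append(_acov_fft(tr.states[burn_in:, 0], max_lag))
    cs = np.asarray(cs)
    lags = np.arange(max_lag) * params.dt_sim
    return Autocovariance(lags=lags, mean=cs.mean(axis=0),
                          se=cs.std(axis=0, ddof=1) / np.sqrt(n_traj),
                          n_traj=n_traj)


def gle_extended_joint(params: GLEParams, acov: Autocovariance
                       ) -> JointGaussian:
    """Block-Toeplitz window joint from the stationary autocovariance.

    Past window samples sit at ``t - t0 ... t`` and future samples at
    ``t + dt ... t + dt + t0`` on the dt_grid spacing; every entry of
    the stacked covariance is ``c(|time difference|)``.  The stacked
    matrix is floored to the nearest PSD matrix (eigenvalue floor
    1e-10 of the largest) before splitting into blocks, since c(tau)
    is a Monte-Carlo estimate.
    """
    k = params.window_points
    t_past = -params.t0 + params.dt_grid * np.arange(k)
    t_future = params.dt_pred + params.t0 - params.dt_grid * \
        np.arange(k)[::-1]
    t_all = np.concatenate([t_past, t_future])
    need = t_all.max() - t_all.min()
    if acov.lags[-1] < need - 1e-9:
        raise ValueError(
            f"autocovariance covers lags to {acov.lags[-1]:.3g}, "
            f"need {need:.3g}")
    C = np.array([[acov.at(ti - tj) for tj in t_all] for ti in t_all])
    w, V = np.linalg.eigh((C + C.T) / 2)
    w = np.clip(w, 1e-10 * w.max(), None)
    C = (V * w) @ V.T
    C = (C + C.T) / 2
    return JointGaussian(sigma_past=C[:k, :k], sigma_future=C[k:, k:],
                         sigma_cross=C[:k, k:])


def max_predictive_info(params: GLEParams, acov: Autocovariance,
                        beta_large: float = 1e4) -> float:
    """Predictive information extractable at low compression (bits)."""
    joint = gle_extended_joint(params, acov)
    return analytic_info(joint, beta_large).i_future


def saturation_curve(params: GLEParams, t0_list, beta_large: float = 1e4,
                     acov: Autocovariance | None = None,
                     **acov_kwargs) -> np.ndarray:
    """Maximum predictive information as a function of history length.

    A single autocovariance estimate (covering the largest window) is
    shared across all t0 values so the curve is smooth in the common
    Monte-Carlo noise.  The sequence is nondecreasing with shrinking
    increments: history helps, with diminishing returns.
    """
    t0_list = list(t0_list)
    if any(np.diff(t0_list) < 0):
        raise ValueError("t0_list must be ascending")
    if acov is None:
        widest = GLEParams(alpha=params.alpha, omega0=params.omega0,
                           gamma=params.gamma, dt_sim=params.dt_sim,
                           t0=max(t0_list), dt_pred=params.dt_pred,
                           dt_grid=params.dt_grid)
        acov = gle_autocovariance(widest, **acov_kwargs)
    out = []
    for t0 in t0_list:
        p = GLEParams(alpha=params.alpha, omega0=params.omega0,
                      gamma=params.gamma, dt_sim=params.dt_sim,
                      t0=t0, dt_pred=params.dt_pred,
                      dt_grid=params.dt_grid if t0 > 0 else params.dt_grid)
        out.append(max_predictive_info(p, acov, beta_large))
    return np.array(out)
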