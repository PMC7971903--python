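"""Wright-Fisher diffusion on the allele-frequency grid.

Single biallelic locus in a population of size N, with scaled mutation
rate ``Nmu`` and scaled selection ``Ns``.  The frequency of the mutant
allele follows the diffusion

    dX/dt = s X(1-X) + mu (1-2X) + noise,

with time in generations, whose stationary law is

    Ps(X) ~ [X (1-X)]^(Nmu - 1) exp(Ns X).

The Fokker-Planck diffusion coefficient is taken as ``D(x) =
x(1-x)/N``, the value for which the drift above and the stationary law
above are mutually consistent.

Discretization: N+1 equally spaced frequencies including the
boundaries (half-width cells at 0 and 1).  The generator is an
equilibrium-preserving finite-volume scheme: interface conductances
are built from the analytic stationary density, so the discrete chain
has exactly the cell-integrated stationary law as its fixed point,
detailed balance holds, and the zero-flux boundaries keep the chain
ergodic for ``mu > 0``.  The finite-lag propagator is obtained by
Crank-Nicolson substeps of this generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.integrate import quad

from .gaussian_ib import LOG2


class DiscretizationError(RuntimeError):
    """The propagator violated positivity beyond tolerance."""


@dataclass(frozen=True)
class WFParams:
    """Population size, scaled rates, and prediction lag (generations)."""

    N: int = 100
    n_mu: float = 0.2
    n_s: float = 0.001
    dt_pred: float = 1.0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.n_mu < 0:
            raise ValueError("scaled mutation rate must be nonnegative")
        if self.dt_pred <= 0:
            raise ValueError("prediction lag must be positive")

    @property
    def mu(self) -> float:
        return self.n_mu / self.N

    @property
    def s(self) -> float:
        return self.n_s / self.N

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.N + 1)


def _stationary_cell_masses(params: WFParams) -> np.ndarray:
    """Integral of the (unnormalized) stationary density over each cell.

    The density ``[x(1-x)]^(Nmu-1) e^(Ns x)`` has integrable power-law
    singularities at the boundaries for ``Nmu < 1``; adaptive
    quadrature per cell handles them.
    """
    if params.n_mu <= 0:
        raise ValueError(
            "analytic stationary law requires Nmu > 0; use the propagator's "
            "leading eigenvector instead")
    n = params.N + 1
    dx = 1.0 / params.N
    a = params.n_mu - 1.0
    out = np.empty(n)
    for i in range(n):
        lo = max(0.0, i * dx - dx / 2)
        hi = min(1.0, i * dx + dx / 2)
        val, _ = quad(lambda y: (y * (1 - y)) ** a * np.exp(params.n_s * y),
                      lo, hi, limit=200)
        out[i] = val
    return out


def wf_steady_state(params: WFParams, normalized: bool = True) -> np.ndarray:
    """Stationary pmf on the frequency grid (cell-integrated analytic law)."""
    m = _stationary_cell_masses(params)
    return m / m.sum() if normalized else m


def wf_steady_state_spectral(params: WFParams,
                             n_substeps: int | None = None) -> np.ndarray:
    """Stationary pmf as the leading left eigenvector of the propagator.

    Cross-validates the analytic route; for ``n_mu = 0`` (absorbing
    boundaries) this is the only available route.
    """
    T = wf_propagator(params, n_substeps=n_substeps)
    w, v = np.linalg.eig(T.T)
    p = np.abs(v[:, np.argmax(w.real)].real)
    return p / p.sum()


def wf_generator(params: WFParams) -> np.ndarray:
    """Continuous-time generator L (acting on cell-mass vectors).

    Equilibrium-preserving finite-volume discretization: the flux over
    interface i+1/2 is ``-g_{i+1/2} (rho_{i+1} - rho_i)`` where
    ``rho = mass / equilibrium mass`` and ``g = D psi / dx`` with the
    unnormalized stationary density psi at the interface.  Columns sum
    to zero (conservation); off-diagonal rates are nonnegative
    (positivity); the analytic stationary law is an exact fixed point.
    """
    N = params.N
    n = N + 1
    dx = 1.0 / N
    x = params.grid
    xi = (x[:-1] + x[1:]) / 2.0
    D_i = xi * (1 - xi) / N
    a = params.n_mu - 1.0
    psi_i = (xi * (1 - xi)) ** a * np.exp(params.n_s * xi)
    M_cell = _stationary_cell_masses(params)
    g = D_i * psi_i / dx
    L = np.zeros((n, n))
    idx = np.arange(n - 1)
    np.add.at(L, (idx, idx), -g / M_cell[:-1])
    np.add.at(L, (idx, idx + 1), g / M_cell[1:])
    np.add.at(L, (idx + 1, idx), g / M_cell[:-1])
    np.add.at(L, (idx + 1, idx + 1), -g / M_cell[1:])
    return L


def wf_propagator(params: WFParams, n_substeps: int | None = None
                  ) -> np.ndarray:
    """Row-stochastic transition matrix ``T[x -> x']`` over the lag.

    Crank-Nicolson integration of the Fokker-Planck generator with
    internal step at most 0.01 generations.  Rows sum to one to 1e-12
    by construction (the scheme is conservative); entries more negative
    than -1e-10 raise :class:`DiscretizationError`.
    """
    if n_substeps is None:
        n_substeps = max(100, int(np.ceil(params.dt_pred / 0.01)))
    if params.dt_pred / n_substeps > 0.01 + 1e-12:
        raise ValueError("internal step must be <= 0.01 generations")
    L = wf_generator(params)
    h = params.dt_pred / n_substeps
    eye = np.eye(params.N + 1)
    step = sla.solve(eye - (h / 2) * L, eye + (h / 2) * L)
    T = np.linalg.matrix_power(step, n_substeps).T
    if T.min() < -1e-10:
        raise DiscretizationError(
            f"propagator entry {T.min():.2e} below tolerance; "
            "increase n_substeps")
    T = np.clip(T, 0.0, None)
    T /= T.sum(axis=1, keepdims=True)
    return T


@dataclass
class DiscreteJoint:
    """Joint pmf of (X_t, X_{t+dt}) on the allele-frequency grid."""

    grid: np.ndarray
    p_joint: np.ndarray
    params: WFParams | None = None

    marginal_past: np.ndarray = field(init=False)
    marginal_future: np.ndarray = field(init=False)

    def __post_init__(self):
        self.p_joint = np.asarray(self.p_joint, float)
        if self.p_joint.min() < -1e-12:
            raise ValueError("joint table has negative entries")
        if abs(self.p_joint.sum() - 1.0) > 1e-12:
            raise ValueError("joint table does not sum to one")
        self.marginal_past = self.p_joint.sum(axis=1)
        self.marginal_future = self.p_joint.sum(axis=0)

    @property
    def n_states(self) -> int:
        return self.p_joint.shape[0]

    def conditional_future(self) -> np.ndarray:
        """Rows ``p(x' | x)``; uniform rows where the past marginal is 0."""
        T = np.empty_like(self.p_joint)
        nz = self.marginal_past > 0
        T[nz] = self.p_joint[nz] / self.marginal_past[nz, None]
        T[~nz] = 1.0 / self.n_states
        return T

    def mutual_information(self) -> float:
        """I(X_t; X_{t+dt}) in bits by direct double summation."""
        return discrete_mi(self.p_joint)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.p_joint, index=self.grid, columns=self.grid
                     ).to_csv(path, float_format="%.12g")


def discrete_mi(p_joint: np.ndarray) -> float:
    """Mutual information (bits) of a discrete joint table."""
    p = np.asarray(p_joint, float)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    ratio = np.log(p[mask] / (px @ py)[mask])
    return float(max(np.sum(p[mask] * ratio) / LOG2, 0.0))


def wf_joint(params: WFParams, n_substeps: int | None = None
             ) -> DiscreteJoint:
    """Stationary joint ``p(x, x') = Ps(x) T[x -> x']``.

    The marginal is the propagator's own stationary vector (identical
    to the cell-integrated analytic law to discretization accuracy,
    and exactly stationary under T, so both marginals agree).
    """
    T = wf_propagator(params, n_substeps=n_substeps)
    w, v = np.linalg.eig(T.T)
    ps = np.abs(v[:, np.argmax(w.real)].real)
    ps /= ps.sum()
    joint = ps[:, None] * T
    joint /= joint.sum()
    return DiscreteJoint(grid=params.grid, p_joint=joint, params=params)
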