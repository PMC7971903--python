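"""Gaussian information bottleneck.

For jointly Gaussian past/future vectors the optimal bottleneck
representation is a noisy linear map ``X~ = A X_past + xi`` with
``xi ~ N(0, I)``.  The structure of the solution is governed by the
spectrum of ``Sigma_{past|future} Sigma_past^{-1}``: each left
eigenvector with eigenvalue ``lambda < 1`` contributes one candidate
representation direction, which switches on at the critical tradeoff
``beta_c = 1 / (1 - lambda)``.

All information quantities are reported in bits; internal computation
uses natural logarithms and converts at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

LOG2 = np.log(2.0)

#: relative eigenvalue tolerance below which a covariance is rejected
PSD_RTOL = 1e-10


class InvalidModelError(ValueError):
    """A covariance block violates symmetry / positive-definiteness."""


class DimensionMismatchError(ValueError):
    """Encoder and joint disagree on the dimension of the past vector."""


def _sym(S: np.ndarray) -> np.ndarray:
    return (S + S.T) / 2.0


def _check_spd(S: np.ndarray, name: str, semi: bool = False) -> None:
    S = np.asarray(S, float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidModelError(f"{name} is not a square matrix")
    if not np.allclose(S, S.T, atol=1e-8 * (1 + np.abs(S).max())):
        raise InvalidModelError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(_sym(S))
    floor = -PSD_RTOL * max(w.max(), 1.0) if semi else PSD_RTOL * max(w.max(), 0.0)
    if semi:
        if w.min() < floor:
            raise InvalidModelError(f"{name} is not positive semidefinite "
                                    f"(min eigenvalue {w.min():.3e})")
    elif w.min() <= max(floor, 0.0):
        raise InvalidModelError(f"{name} is not positive definite "
                                f"(min eigenvalue {w.min():.3e})")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InfoPoint:
    """A point on the compression/prediction plane, in bits."""

    i_past: float
    i_future: float

    def __post_init__(self):
        object.__setattr__(self, "i_past", float(self.i_past))
        object.__setattr__(self, "i_future", float(self.i_future))

    def as_tuple(self) -> tuple[float, float]:
        return (self.i_past, self.i_future)


@dataclass
class InfoCurve:
    """An information curve: (beta, i_past, i_future) triples, in bits."""

    beta: np.ndarray
    points: list[InfoPoint]

    @property
    def i_past(self) -> np.ndarray:
        return np.array([p.i_past for p in self.points])

    @property
    def i_future(self) -> np.ndarray:
        return np.array([p.i_future for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": np.asarray(self.beta, float),
                             "i_past_bits": self.i_past,
                             "i_future_bits": self.i_future})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


@dataclass
class JointGaussian:
    """Zero-mean second-order description of a (past, future) pair.

    Parameters
    ----------
    sigma_past, sigma_future
        Marginal covariance blocks.
    sigma_cross
        ``Cov(X_past, X_future)``, shape ``(dim_past, dim_future)``.
    """

    sigma_past: np.ndarray
    sigma_future: np.ndarray
    sigma_cross: np.ndarray
    sigma_past_given_future: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sigma_past = _sym(np.atleast_2d(np.asarray(self.sigma_past, float)))
        self.sigma_future = _sym(np.atleast_2d(np.asarray(self.sigma_future, float)))
        self.sigma_cross = np.atleast_2d(np.asarray(self.sigma_cross, float))
        _check_spd(self.sigma_past, "sigma_past")
        _check_spd(self.sigma_future, "sigma_future")
        if self.sigma_cross.shape != (self.dim_past, self.dim_future):
            raise InvalidModelError("sigma_cross has inconsistent shape")
        cond = self.sigma_past - self.sigma_cross @ np.linalg.solve(
            self.sigma_future, self.sigma_cross.T)
        self.sigma_past_given_future = _sym(cond)
        _check_spd(self.sigma_past_given_future, "sigma_past_given_future",
                   semi=True)

    @property
    def dim_past(self) -> int:
        return self.sigma_past.shape[0]

    @property
    def dim_future(self) -> int:
        return self.sigma_future.shape[0]

    def mutual_information(self) -> float:
        """I(X_past; X_future) in bits, from the determinant ratio."""
        s1, d1 = np.linalg.slogdet(self.sigma_past)
        s2, d2 = np.linalg.slogdet(self.sigma_past_given_future)
        return max(0.0, (d1 - d2) / (2 * LOG2))


@dataclass
class IBSpectrum:
    """Eigen-structure of ``Sigma_{past|future} Sigma_past^{-1}``.

    ``eigenvalues`` are ascending in (0, 1]; ``eigenvectors[:, i]`` is
    the i-th left eigenvector (unit norm, first nonzero component
    positive); ``beta_c[i] = 1/(1 - lambda_i)`` is the critical
    tradeoff at which direction i becomes active; ``scales[i]`` is
    ``w_i^T Sigma_past w_i``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    beta_c: np.ndarray
    scales: np.ndarray


@dataclass
class GaussianEncoder:
    """Noisy linear encoder ``X~ = A X_past + xi``, ``xi ~ N(0, I)``."""

    A: np.ndarray
    beta: float
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, float))

    @property
    def dim_in(self) -> int:
        return self.A.shape[1]

    def rank(self, tol: float = 1e-12) -> int:
        """Number of active (nonzero) rows."""
        return int(np.sum(np.linalg.norm(self.A, axis=1) > tol))

    def to_json(self, path, info: InfoPoint | None = None) -> None:
        payload = {"A": self.A.tolist(), "beta": float(self.beta),
                   "source": self.source}
        if info is not None:
            payload["i_past"] = info.i_past
            payload["i_future"] = info.i_future
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GaussianEncoder":
        with open(path) as fh:
            d = json.load(fh)
        return cls(A=np.array(d["A"], float), beta=d["beta"],
                   source=d.get("source", {}))


# ---------------------------------------------------------------------------
# spectrum and encoders
# ---------------------------------------------------------------------------

def _fix_sign(v: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def ib_spectrum(joint: JointGaussian) -> IBSpectrum:
    """Left eigen-decomposition of ``Sigma_{past|future} Sigma_past^{-1}``.

    The matrix is similar to the symmetric pencil eigenproblem
    ``Sigma_{past|future} w' = lambda Sigma_past w'`` after the
    substitution ``w = Sigma_past^{-1/2} u``; solving the symmetrized
    problem keeps eigenvalues real and eigenvectors well conditioned.
    """
    import scipy.linalg as sla

    Sp = joint.sigma_past
    Sc = joint.sigma_past_given_future
    # left eigvecs of Sc Sp^{-1}:  w^T Sc Sp^{-1} = lam w^T
    # equivalent generalized symmetric problem: Sc y = lam Sp y with w = y...
    # w^T Sc = lam w^T Sp  =>  Sc w = lam Sp w  (both symmetric)
    lam, W = sla.eigh(Sc, Sp)
    lam = np.clip(lam, 0.0, 1.0)
    order = np.argsort(lam, kind="stable")
    lam = lam[order]
    W = W[:, order]
    W = np.stack([_fix_sign(W[:, i] / np.linalg.norm(W[:, i]))
                  for i in range(W.shape[1])], axis=1)
    with np.errstate(divide="ignore"):
        beta_c = np.where(lam < 1.0, 1.0 / (1.0 - lam), np.inf)
    scales = np.einsum("ij,jk,ki->i", W.T, Sp, W)
    return IBSpectrum(eigenvalues=lam, eigenvectors=W, beta_c=beta_c,
                      scales=scales)


def optimal_encoder(joint: JointGaussian, beta: float,
                    source: dict | None = None) -> GaussianEncoder:
    """Optimal Gaussian IB encoder at tradeoff ``beta``.

    Row i of ``A`` is ``alpha_i w_i^T`` with
    ``alpha_i^2 = (beta (1 - lambda_i) - 1) / (lambda_i r_i)``,
    active only when ``beta > beta_c_i = 1/(1 - lambda_i)``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    spec = ib_spectrum(joint)
    n = joint.dim_past
    A = np.zeros((n, n))
    for i, (lam, bc, r) in enumerate(zip(spec.eigenvalues, spec.beta_c,
                                         spec.scales)):
        if beta > bc and lam > 0:
            alpha = np.sqrt((beta * (1.0 - lam) - 1.0) / (lam * r))
            A[i] = alpha * spec.eigenvectors[:, i]
    return GaussianEncoder(A=A, beta=float(beta), source=source or {})


def evaluate_encoder(encoder: GaussianEncoder,
                     joint: JointGaussian) -> InfoPoint:
    """Information plane coordinates of an arbitrary linear encoder.

    ``i_past = 1/2 log2 det(A Sigma_past A^T + I)`` and
    ``i_future = i_past - 1/2 log2 det(A Sigma_{past|future} A^T + I)``.
    """
    if encoder.dim_in != joint.dim_past:
        raise DimensionMismatchError(
            f"encoder expects dim {encoder.dim_in}, joint has "
            f"{joint.dim_past}")
    A = encoder.A
    _, d_past = np.linalg.slogdet(A @ joint.sigma_past @ A.T + np.eye(len(A)))
    _, d_cond = np.linalg.slogdet(
        A @ joint.sigma_past_given_future @ A.T + np.eye(len(A)))
    i_past = d_past / (2 * LOG2)
    i_future = i_past - d_cond / (2 * LOG2)
    return InfoPoint(i_past=max(i_past, 0.0), i_future=max(i_future, 0.0))


def analytic_info(joint: JointGaussian, beta: float) -> InfoPoint:
    """Closed-form information coordinates of the optimal encoder.

    Per active mode: ``i_past = 1/2 log[(beta-1)(1-lam)/lam]`` and
    ``i_future = 1/2 log[(beta-1)/(beta lam)]``.
    """
    spec = ib_spectrum(joint)
    ip = 0.0
    ifu = 0.0
    for lam, bc in zip(spec.eigenvalues, spec.beta_c):
        if beta > bc and lam > 0:
            ip += 0.5 * np.log((beta - 1.0) * (1.0 - lam) / lam)
            ifu += 0.5 * np.log((beta - 1.0) / (beta * lam))
    return InfoPoint(ip / LOG2, ifu / LOG2)


def info_curve(joint: JointGaussian,
               beta_grid: Sequence[float] | None = None) -> InfoCurve:
    """Information bottleneck curve swept over a beta grid.

    The default grid is logarithmic over [1.001, 1e4] with 200 points,
    which resolves both the critical region near ``beta_c`` and the
    saturation at the total predictive information.
    """
    if beta_grid is None:
        beta_grid = np.geomspace(1.001, 1e4, 200)
    beta_grid = np.asarray(beta_grid, float)
    if np.any(np.diff(beta_grid) < 0):
        raise ValueError("beta_grid must be sorted ascending")
    pts = [evaluate_encoder(optimal_encoder(joint, b), joint)
           for b in beta_grid]
    return InfoCurve(beta=beta_grid, points=pts)


def beta_for_past_info(joint: JointGaussian, i_past: float,
                       beta_max: float = 1e12) -> float:
    """Invert the closed-form ``i_past(beta)`` by bisection.

    ``i_past(beta)`` is continuous and strictly increasing above the
    first critical beta, so any positive target is attainable.
    """
    from scipy.optimize import brentq

    if i_past <= 0:
        raise ValueError("target i_past must be positive")
    spec = ib_spectrum(joint)
    if not np.isfinite(spec.beta_c[0]):
        raise InvalidModelError("independent past/future: no information "
                                "can be encoded at any beta")

    def f(logb):
        return analytic_info(joint, np.exp(logb)).i_past - i_past

    lo = np.log(spec.beta_c[0] * (1 + 1e-12))
    hi = np.log(beta_max)
    if f(hi) < 0:
        raise RuntimeError(f"i_past target {i_past} not bracketed below "
                           f"beta={beta_max:g}")
    return float(np.exp(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)))


def encoder_at_past_info(joint: JointGaussian, i_past: float,
                         source: dict | None = None) -> GaussianEncoder:
    """Optimal encoder carrying exactly ``i_past`` bits about the past."""
    beta = beta_for_past_info(joint, i_past)
    return optimal_encoder(joint, beta, source=source)


def optimal_future_at(joint: JointGaussian, i_past: float) -> float:
    """Bound of the information curve: best i_future at a given i_past."""
    if i_past <= 0:
        return 0.0
    beta = beta_for_past_info(joint, i_past)
    return analytic_info(joint, beta).i_future


# ---------------------------------------------------------------------------
# conditional covariances & rotations
# ---------------------------------------------------------------------------

def conditional_covariances(encoder: GaussianEncoder, joint: JointGaussian
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Covariances of past and future conditioned on the representation.

    Returns ``(Sigma_{past|X~}, Sigma_{future|X~})`` by Gaussian
    conditioning on ``X~ = A X_past + xi``.
    """
    if encoder.dim_in != joint.dim_past:
        raise DimensionMismatchError("encoder/joint dimension mismatch")
    A = encoder.A
    Sp = joint.sigma_past
    Sf = joint.sigma_future
    Sx = joint.sigma_cross
    Srep = A @ Sp @ A.T + np.eye(len(A))
    Cp = Sp @ A.T                    # Cov(past, X~)
    Cf = Sx.T @ A.T                  # Cov(future, X~)
    cond_p = _sym(Sp - Cp @ np.linalg.solve(Srep, Cp.T))
    cond_f = _sym(Sf - Cf @ np.linalg.solve(Srep, Cf.T))
    return cond_p, cond_f


def rotate_encoder(encoder: GaussianEncoder, theta: float,
                   joint: JointGaussian) -> GaussianEncoder:
    """Rotate encoder rows in the (position, velocity) plane.

    The rotated encoder is rescaled by a common positive factor so its
    ``i_past`` matches the input encoder's to 1e-6 bits; it is in
    general suboptimal for prediction.
    """
    from scipy.optimize import brentq

    if joint.dim_past != 2 or encoder.dim_in != 2:
        raise DimensionMismatchError("rotation requires a 2-D past")
    target = evaluate_encoder(encoder, joint).i_past
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    A_rot = encoder.A @ R.T
    if target <= 0 or np.linalg.norm(A_rot) == 0:
        return GaussianEncoder(A=A_rot, beta=encoder.beta,
                               source=dict(encoder.source))

    def f(log_scale):
        enc = GaussianEncoder(A=np.exp(log_scale) * A_rot, beta=encoder.beta)
        return evaluate_encoder(enc, joint).i_past - target

    lo, hi = -30.0, 30.0
    scale = np.exp(brentq(f, lo, hi, xtol=1e-13))
    return GaussianEncoder(A=scale * A_rot, beta=encoder.beta,
                           source=dict(encoder.source))
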