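"""Discrete information bottleneck via Blahut-Arimoto iterations.

Solves ``min I(X; X~) - beta I(X~; X')`` over conditional tables
``q(x~ | x)`` with a representation alphabet of fixed cardinality m.
The self-consistent equations are

    q(x~|x)  ~  q(x~) exp(-beta KL[ p(x'|x) || p(x'|x~) ]),

with the cluster marginal ``q(x~)`` and decoders ``p(x'|x~)``
recomputed from ``q(x~|x)`` each sweep.  Fixed points depend on the
initialization near the cardinality bifurcations, so solves support
seeded restarts and warm-started annealing in beta.

Encoders additionally carry an *effective support*: the set of states
the training model plausibly visits in a finite stationary history.
Off-support rows of ``q`` are ill-determined at the fixed point (any
assignment is optimal, since those states carry no probability) and
are fixed to the maximum-entropy completion, the cluster marginal.
This matters only when an encoder is frozen and transferred to a model
whose mass lies where the training model's does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gaussian_ib import LOG2, InfoCurve, InfoPoint
from .wright_fisher import DiscreteJoint, discrete_mi

_FLOOR = 1e-300

#: expected visits >= 1 in a stationary history of this many time units
#: define the default effective support of a trained encoder
DEFAULT_SUPPORT_HISTORY = 1000.0


class GridMismatchError(ValueError):
    """Encoder and joint are defined on different frequency grids."""


@dataclass
class DiscreteEncoder:
    """Conditional table ``q(x~ | x)`` over m representation values."""

    q: np.ndarray
    beta: float
    grid: np.ndarray
    converged: bool = True
    support: np.ndarray | None = None      # boolean mask over states
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        if self.q.min() < 0 or np.abs(self.q.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("rows of q must be distributions")

    @property
    def m(self) -> int:
        return self.q.shape[1]

    def marginal(self, joint: DiscreteJoint) -> np.ndarray:
        """Cluster marginal q(x~) under the joint's past marginal."""
        return joint.marginal_past @ self.q

    def to_csv(self, csv_path, meta_path=None, **meta) -> None:
        pd.DataFrame(self.q, index=self.grid).to_csv(
            csv_path, float_format="%.12g")
        if meta_path is not None:
            payload = {"m": self.m, "beta": self.beta,
                       "converged": self.converged, **meta}
            with open(meta_path, "w") as fh:
                json.dump(payload, fh, indent=1)


def _check_grid(encoder: DiscreteEncoder, joint: DiscreteJoint) -> None:
    if encoder.q.shape[0] != joint.n_states or not np.allclose(
            encoder.grid, joint.grid):
        raise GridMismatchError("encoder grid does not match joint grid")


def discrete_info(encoder: DiscreteEncoder, joint: DiscreteJoint
                  ) -> InfoPoint:
    """(I(X; X~), I(X~; X')) in bits for a frozen encoder on a joint."""
    _check_grid(encoder, joint)
    ps = joint.marginal_past
    joint_past = encoder.q * ps[:, None]            # p(x, x~)
    joint_future = joint_past.T @ joint.conditional_future()  # p(x~, x')
    return InfoPoint(i_past=discrete_mi(joint_past),
                     i_future=discrete_mi(joint_future))


def _lagrangian(encoder_q, ps, T, beta) -> float:
    jp = encoder_q * ps[:, None]
    return discrete_mi(jp) - beta * discrete_mi(jp.T @ T)


def effective_support(joint: DiscreteJoint,
                      history: float = DEFAULT_SUPPORT_HISTORY) -> np.ndarray:
    """States expected to be visited at least once in a finite history."""
    return joint.marginal_past >= 1.0 / history


def ba_solve(joint: DiscreteJoint, m: int, beta: float,
             init: np.ndarray | None = None, tol: float = 1e-10,
             max_iter: int = 50_000, seed: int | None = None,
             support_history: float = DEFAULT_SUPPORT_HISTORY,
             check_monotone: bool = False) -> DiscreteEncoder:
    """One Blahut-Arimoto solve at fixed (m, beta).

    Initialization is perturbed-uniform: uniform rows with
    multiplicative noise drawn from the seeded generator (or ``init``
    if given).  Convergence is declared when the IB Lagrangian changes
    by less than ``tol`` between sweeps; non-convergence returns the
    best iterate flagged ``converged=False``.
    """
    if m < 1:
        raise ValueError("cardinality m must be >= 1")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    ps = joint.marginal_past
    T = joint.conditional_future()
    n = joint.n_states
    rng = np.random.default_rng(seed)
    if init is not None:
        q = np.asarray(init, float).copy()
    else:
        q = np.ones((n, m)) * (1.0 + 0.05 * rng.random((n, m)))
    q /= q.sum(axis=1, keepdims=True)

    logT = np.log(np.maximum(T, _FLOOR))
    neg_h = np.einsum("ij,ij->i", T, logT)      # sum_x' p(x'|x) log p(x'|x)
    L_prev = np.inf
    converged = False
    for it in range(max_iter):
        qt = np.maximum(ps @ q, _FLOOR)
        dec = (q * ps[:, None]).T @ T / qt[:, None]
        kl = neg_h[:, None] - T @ np.log(np.maximum(dec, _FLOOR)).T
        logq = np.log(qt)[None, :] - beta * kl
        logq -= logq.max(axis=1, keepdims=True)
        q = np.exp(logq)
        q /= q.sum(axis=1, keepdims=True)
        if check_monotone or it % 10 == 0 or it == max_iter - 1:
            L = _lagrangian(q, ps, T, beta)
            if check_monotone and L > L_prev + 1e-9:
                raise AssertionError(
                    f"IB Lagrangian increased at iteration {it}")
            if abs(L_prev - L) < tol:
                converged = True
                break
            L_prev = L
    sup = effective_support(joint, support_history)
    q[~sup] = np.maximum(ps, 0.0) @ q            # max-entropy completion
    q /= q.sum(axis=1, keepdims=True)
    return DiscreteEncoder(q=q, beta=float(beta), grid=joint.grid,
                           converged=converged, support=sup)


def ba_best(joint: DiscreteJoint, m: int, beta: float, n_restarts: int = 10,
            seed: int = 0, warm_start: np.ndarray | None = None,
            **kwargs) -> DiscreteEncoder:
    """Best-of-restarts solve: highest i_future, i_past as tie-break.

    Restart 0 is the deterministic perturbed-uniform initialization
    (seeded by ``seed``); an optional warm start from a neighbouring
    beta joins the pool.
    """
    best = None
    best_key = None
    inits: list[np.ndarray | None] = [None] * n_restarts
    if warm_start is not None:
        inits.append(warm_start)
    for k, init in enumerate(inits):
        enc = ba_solve(joint, m, beta, init=init, seed=seed + k, **kwargs)
        pt = discrete_info(enc, joint)
        key = (pt.i_future, -pt.i_past / max(beta, 1e-12))
        if best_key is None or key > best_key:
            best, best_key = enc, key
    return best


def discrete_curve(joint: DiscreteJoint, m: int,
                   beta_grid: np.ndarray, n_restarts: int = 10,
                   seed: int = 0, **kwargs) -> InfoCurve:
    """Information curve over beta, annealed upward with warm starts.

    Each beta is solved from ``n_restarts`` seeded initializations plus
    the previous beta's solution; the best point (highest i_future,
    lower i_past as tie-break) is kept, which tracks the physical
    branch through the cardinality bifurcations.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    beta_grid = np.asarray(beta_grid, float)
    pts = []
    warm = None
    for b in beta_grid:
        enc = ba_best(joint, m, b, n_restarts=n_restarts, seed=seed,
                      warm_start=warm, **kwargs)
        warm = enc.q
        pts.append(discrete_info(enc, joint))
    return InfoCurve(beta=beta_grid, points=pts)


def saturating_beta(joint: DiscreteJoint, m: int, frac: float = 0.985,
                    beta_grid: np.ndarray | None = None,
                    n_restarts: int = 4, seed: int = 0,
                    **kwargs) -> tuple[float, DiscreteEncoder]:
    """Smallest grid beta whose i_past reaches ``frac`` of its plateau.

    Operational version of "beta large enough that I(X; X~) is
    approximately log m": the compression saturates within 1.5% (by
    default) of its large-beta limit for this channel cardinality.
    The sweep is annealed upward with warm starts plus restarts;
    returns (beta, encoder).
    """
    if beta_grid is None:
        beta_grid = np.geomspace(1.5, 64.0, 28)
    encs = []
    warm = None
    for b in beta_grid:
        enc = ba_best(joint, m, b, n_restarts=n_restarts, seed=seed,
                      warm_start=warm, **kwargs)
        warm = enc.q
        encs.append(enc)
    i_past = np.array([discrete_info(e, joint).i_past for e in encs])
    k = int(np.argmax(i_past >= frac * i_past[-1]))
    return float(beta_grid[k]), encs[k]


def effective_cardinality(encoder: DiscreteEncoder, joint: DiscreteJoint,
                          mass_tol: float = 1e-4,
                          divergence_tol: float = 1e-3) -> int:
    """Number of non-degenerate representation values actually in use.

    Clusters with marginal mass below ``mass_tol`` are dropped; the
    remainder are merged greedily whenever their decoders differ by a
    Jensen-Shannon divergence (bits) below ``divergence_tol``.
    """
    _check_grid(encoder, joint)
    ps = joint.marginal_past
    T = joint.conditional_future()
    qt = ps @ encoder.q
    keep = np.flatnonzero(qt > mass_tol)
    if keep.size == 0:
        return 0
    dec = (encoder.q * ps[:, None]).T @ T
    dec = dec[keep] / dec[keep].sum(axis=1, keepdims=True)

    def jsd(p, r):
        mmid = (p + r) / 2
        return 0.5 * (_kl_bits(p, mmid) + _kl_bits(r, mmid))

    groups: list[int] = []
    for i in range(len(keep)):
        for g in groups:
            if jsd(dec[i], dec[g]) < divergence_tol:
                break
        else:
            groups.append(i)
    return len(groups)


def _kl_bits(p, r):
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / np.maximum(r[mask],
                                                              _FLOOR)))
                 / LOG2)


def decoders(encoder: DiscreteEncoder, joint: DiscreteJoint) -> dict:
    """Per-cluster posteriors over past and future states.

    Returns the cluster marginal, the decoding distributions
    ``P(X_t | x~)`` and ``P(X_{t+dt} | x~)`` (rows), and their
    conditional means and standard deviations on the frequency grid.
    Mixing the decoders by the cluster marginal recovers the joint's
    marginals exactly (law of total probability).
    """
    _check_grid(encoder, joint)
    ps = joint.marginal_past
    T = joint.conditional_future()
    qt = ps @ encoder.q
    qt_safe = np.maximum(qt, _FLOOR)
    post_past = (encoder.q * ps[:, None]).T / qt_safe[:, None]
    post_future = post_past @ T
    x = joint.grid
    mean_p = post_past @ x
    mean_f = post_future @ x
    var_p = post_past @ x ** 2 - mean_p ** 2
    var_f = post_future @ x ** 2 - mean_f ** 2
    return {"cluster_marginal": qt,
            "past": post_past, "future": post_future,
            "mean_past": mean_p, "std_past": np.sqrt(np.maximum(var_p, 0)),
            "mean_future": mean_f,
            "std_future": np.sqrt(np.maximum(var_f, 0))}


def transfer_discrete(encoder: DiscreteEncoder,
                      target_joint: DiscreteJoint) -> InfoPoint:
    """Evaluate a frozen encoder under a different model's joint.

    The conditional table (including its off-support completion) is
    held fixed; both informations are recomputed under the target
    statistics.
    """
    return discrete_info(encoder, target_joint)
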