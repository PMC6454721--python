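"""Semi-NMF and balance-regularized semi-NMF (BRSNMF) for signed networks.

Semi-NMF factorizes a real symmetric matrix ``A`` as ``A ~ W H^T`` with
real centroids ``W`` (m x k) and a nonnegative indicator matrix ``H``
(m x k); row ``i`` of ``H`` scores how strongly node ``i`` belongs to each
of ``k`` communities.  BRSNMF adds two regularizers that encode weak
structural balance of a signed DDI network:

* a balance reward ``Gr = tr(H^T (sigma I - eta (A- + L+)) H)`` that
  penalizes degressive (negative) edges falling inside communities and
  enhancive (positive) edges being cut between them (``L+ = D+ - A+`` is
  the Laplacian of the positive subnetwork); ``sigma`` and ``eta`` trade
  off community size against cut quality;
* a row-sparsity penalty ``Sr = tr(H 1 H^T) = sum_i (sum_j h_ij)^2``
  pushing each drug toward membership in few communities.

The objective is::

    min_{W, H >= 0}  ||A - W H^T||_F^2 + alpha * Sr - beta * Gr

solved by alternating the exact least-squares update of ``W`` with a
multiplicative KKT update of ``H`` that preserves nonnegativity and is
non-increasing in the objective.  With ``alpha = beta = 0`` the iteration
is exactly Semi-NMF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .balance import CommunityPartition
from .network import SignedNetwork, signed_laplacian_plus, split_signs

__all__ = [
    "BrsnmfConfig",
    "FactorizationResult",
    "pos_part",
    "neg_part",
    "objective",
    "update_w",
    "update_h",
    "semi_nmf",
    "brsnmf",
    "assign_communities",
    "default_prediction_rank",
]


class SingularIndicatorError(np.linalg.LinAlgError):
    """H^T H is too ill-conditioned to solve for W, even with a ridge."""


class DivergenceError(FloatingPointError):
    """A multiplicative update produced non-finite entries."""


class UnassignableNodeError(ValueError):
    """A row of H is identically zero, so the node has no community."""


@dataclass(frozen=True)
class BrsnmfConfig:
    """Hyperparameters of a BRSNMF run.

    ``alpha`` weights the row-sparsity penalty, ``beta`` the balance
    reward; ``sigma`` and ``eta`` shape the reward (larger ``sigma``
    favours larger indicator mass per community, larger ``eta`` penalizes
    balance violations harder).  All four default to 1, the setting under
    which the partition is empirically insensitive to their exact values.
    """

    k: int
    alpha: float = 1.0
    beta: float = 1.0
    eta: float = 1.0
    sigma: float = 1.0
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    epsilon: float = 1e-12
    init: str = "kmeans"  # or "random"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if min(self.alpha, self.beta) < 0 or min(self.eta, self.sigma) <= 0:
            raise ValueError("require alpha, beta >= 0 and eta, sigma > 0")
        if self.max_iter < 1 or self.tol <= 0 or self.epsilon <= 0:
            raise ValueError("max_iter, tol and epsilon must be positive")
        if self.init not in ("kmeans", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass(frozen=True)
class FactorizationResult:
    """Outcome of a (BRS)NMF run: factors, objective trace, convergence."""

    W: np.ndarray = field(repr=False)
    H: np.ndarray = field(repr=False)
    objective_trace: np.ndarray = field(repr=False)
    converged: bool
    n_iter: int
    config: BrsnmfConfig


def pos_part(x: np.ndarray) -> np.ndarray:
    """Elementwise positive part ``(|X| + X) / 2``."""
    x = np.asarray(x, dtype=float)
    return (np.abs(x) + x) / 2.0


def neg_part(x: np.ndarray) -> np.ndarray:
    """Elementwise negative part ``(|X| - X) / 2`` (nonnegative)."""
    x = np.asarray(x, dtype=float)
    return (np.abs(x) - x) / 2.0


def _balance_matrix(net: SignedNetwork) -> np.ndarray:
    """``A- + L+``, the quadratic form penalized by the balance reward."""
    _, aminus = split_signs(net)
    return aminus + signed_laplacian_plus(net)


def _objective_terms(
    a: np.ndarray, w: np.ndarray, h: np.ndarray, cfg: BrsnmfConfig, m_bal: np.ndarray
) -> float:
    fit = float(np.linalg.norm(a - w @ h.T) ** 2)
    sparsity = float(np.sum(h.sum(axis=1) ** 2))  # tr(H 1 H^T)
    reward = cfg.sigma * float(np.sum(h * h)) - cfg.eta * float(np.sum(h * (m_bal @ h)))
    return fit + cfg.alpha * sparsity - cfg.beta * reward


def objective(
    a: np.ndarray, w: np.ndarray, h: np.ndarray, cfg: BrsnmfConfig
) -> float:
    """Evaluate the BRSNMF objective on a signed adjacency matrix.

    ``a`` may be a raw adjacency array or a :class:`SignedNetwork`.
    """
    if isinstance(a, SignedNetwork):
        net = a
    else:
        a = np.asarray(a, dtype=float)
        net = _net_from_array(a)
    arr = net.adjacency.astype(float)
    if w.shape != (arr.shape[0], cfg.k) or h.shape != w.shape:
        raise ValueError(
            f"shape mismatch: A {arr.shape}, W {w.shape}, H {h.shape}, k={cfg.k}"
        )
    return _objective_terms(arr, w, h, cfg, _balance_matrix(net))


def _net_from_array(a: np.ndarray) -> SignedNetwork:
    labels = tuple(f"n{i}" for i in range(a.shape[0]))
    return SignedNetwork(labels=labels, adjacency=a.astype(int))


def update_w(a: np.ndarray, h: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Least-squares optimal centroids ``W = A H (H^T H)^-1`` for fixed H.

    A small ridge proportional to ``tr(H^T H)/k`` keeps the Gram matrix
    invertible when communities have collapsed.
    """
    k = h.shape[1]
    gram = h.T @ h
    lam = ridge * np.trace(gram) / k
    try:
        w = np.linalg.solve(gram + lam * np.eye(k), (a @ h).T).T
    except np.linalg.LinAlgError as exc:
        raise SingularIndicatorError(
            "H^T H is singular even after ridge regularization"
        ) from exc
    if not np.isfinite(w).all():
        raise SingularIndicatorError("non-finite centroid update")
    return w


def update_h(
    a: np.ndarray,
    w: np.ndarray,
    h: np.ndarray,
    cfg: BrsnmfConfig,
    aplus: np.ndarray | None = None,
    aminus: np.ndarray | None = None,
) -> np.ndarray:
    """One multiplicative KKT step for the indicator matrix.

    ``H <- H * sqrt(N / D)`` with the gradient of the objective split into
    nonnegative parts::

        N = (A W)+  + H (W^T W)-  + beta*eta*A+ H        + beta*sigma*H
        D = (A W)-  + H (W^T W)+  + alpha*H 1
            + beta*eta*(A- H + D+ H)

    where ``A+``/``A-`` are the enhancive/degressive parts of ``A`` and
    ``D+`` the positive degree matrix, so ``N - D`` equals minus half the
    objective gradient.  Zero entries of ``H`` stay zero and the step is
    non-increasing in the objective.
    """
    if aplus is None or aminus is None:
        aplus, aminus = pos_part(a), neg_part(a)
    aw = a @ w
    wtw = w.T @ w
    num = pos_part(aw) + h @ neg_part(wtw)
    den = neg_part(aw) + h @ pos_part(wtw)
    if cfg.alpha:
        den = den + cfg.alpha * h.sum(axis=1, keepdims=True)  # H @ ones_k
    if cfg.beta:
        be = cfg.beta * cfg.eta
        dplus = aplus.sum(axis=1)
        num = num + be * (aplus @ h) + cfg.beta * cfg.sigma * h
        den = den + be * (aminus @ h) + be * (dplus[:, None] * h)
    h_new = h * np.sqrt(num / (den + cfg.epsilon))
    if not np.isfinite(h_new).all():
        raise DivergenceError(
            "non-finite indicator update; the iteration diverged "
            f"(max |H| = {np.abs(h[np.isfinite(h)]).max() if np.isfinite(h).any() else 'nan'})"
        )
    return h_new


def _init_h(a: np.ndarray, k: int, seed: int, how: str) -> np.ndarray:
    """Seeded initial indicator matrix.

    ``kmeans``: cluster the rows of ``A`` and use the one-hot membership
    plus a constant 0.2 offset (the standard Semi-NMF recipe); ``random``:
    uniform on (0, 1).
    """
    m = a.shape[0]
    rng = np.random.default_rng(seed)
    if how == "random":
        return rng.uniform(0.0, 1.0, size=(m, k))
    if k == 1:
        labels = np.zeros(m, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**32))
        labels = km.fit_predict(a)
    h = np.full((m, k), 0.2)
    h[np.arange(m), labels] += 1.0
    return h


def _alternate(
    a: np.ndarray,
    cfg: BrsnmfConfig,
    h_step,
) -> FactorizationResult:
    """Shared alternating-minimization driver."""
    h = _init_h(a, cfg.k, cfg.seed, cfg.init)
    w = update_w(a, h)
    aplus, aminus = pos_part(a), neg_part(a)
    m_bal = aminus + (np.diag(aplus.sum(axis=1)) - aplus)
    trace = [_objective_terms(a, w, h, cfg, m_bal)]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        w = update_w(a, h)
        h = h_step(a, w, h, aplus, aminus)
        obj = _objective_terms(a, w, h, cfg, m_bal)
        trace.append(obj)
        prev = trace[-2]
        if abs(obj - prev) <= cfg.tol * max(abs(prev), cfg.epsilon):
            converged = True
            break
    return FactorizationResult(
        W=w,
        H=h,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        config=cfg,
    )


def semi_nmf(
    a: np.ndarray | SignedNetwork,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    init: str = "kmeans",
) -> FactorizationResult:
    """Plain Semi-NMF of a real symmetric matrix (no balance terms).

    Alternates ``W = A H (H^T H)^-1`` with the classic multiplicative
    indicator update ``H <- H * sqrt(((A W)+ + H (W^T W)-) /
    ((A W)- + H (W^T W)+))``.
    """
    if isinstance(a, SignedNetwork):
        a = a.adjacency
    a = np.asarray(a, dtype=float)
    cfg = BrsnmfConfig(
        k=k, alpha=0.0, beta=0.0, max_iter=max_iter, tol=tol, seed=seed, init=init
    )

    def step(a_, w, h, aplus, aminus):
        aw = a_ @ w
        wtw = w.T @ w
        num = pos_part(aw) + h @ neg_part(wtw)
        den = neg_part(aw) + h @ pos_part(wtw)
        h_new = h * np.sqrt(num / (den + cfg.epsilon))
        if not np.isfinite(h_new).all():
            raise DivergenceError("non-finite Semi-NMF indicator update")
        return h_new

    return _alternate(a, cfg, step)


def brsnmf(net: SignedNetwork | np.ndarray, cfg: BrsnmfConfig) -> FactorizationResult:
    """Balance-regularized Semi-NMF of a signed network.

    Runs the seeded initialization, then alternates the exact centroid
    update with the regularized multiplicative indicator update until the
    relative objective change drops below ``cfg.tol`` or ``cfg.max_iter``
    iterations have been used.
    """
    if isinstance(net, SignedNetwork):
        a = net.adjacency.astype(float)
    else:
        a = np.asarray(net, dtype=float)
    if cfg.k > a.shape[0]:
        raise ValueError(f"k={cfg.k} exceeds the number of nodes {a.shape[0]}")

    def step(a_, w, h, aplus, aminus):
        return update_h(a_, w, h, cfg, aplus, aminus)

    return _alternate(a, cfg, step)


def assign_communities(h: np.ndarray) -> CommunityPartition:
    """Harden an indicator matrix into a partition.

    Node ``i`` joins the community with the largest ``h_ij`` (ties go to
    the lowest column index).  Columns that win no node are dropped and
    the remaining community indices compacted, with a warning.
    """
    h = np.asarray(h, dtype=float)
    if (h < 0).any():
        raise ValueError("indicator matrix must be nonnegative")
    zero_rows = np.flatnonzero(~h.any(axis=1))
    if zero_rows.size:
        raise UnassignableNodeError(
            f"rows {zero_rows.tolist()} of H are identically zero"
        )
    raw = np.argmax(h, axis=1)  # argmax takes the first maximum: lowest index
    used = np.unique(raw)
    if used.size < h.shape[1]:
        warnings.warn(
            f"{h.shape[1] - used.size} of {h.shape[1]} communities are empty; "
            "indices compacted",
            stacklevel=2,
        )
    remap = {c: i + 1 for i, c in enumerate(used)}
    assignment = np.array([remap[c] for c in raw])
    return CommunityPartition(assignment=assignment, k=used.size)


def default_prediction_rank(a: np.ndarray | SignedNetwork, tol: float = 1e-8) -> int:
    """Default latent dimension for cold-start prediction: ``rank(A)/10``.

    The numerical rank is taken at the given singular-value tolerance; the
    result is rounded and floored at 1.
    """
    if isinstance(a, SignedNetwork):
        a = a.adjacency
    r = int(np.linalg.matrix_rank(np.asarray(a, dtype=float), tol=tol))
    return max(1, round(r / 10))
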