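"""Signed drug-drug-interaction networks and their triad statistics.

A comprehensive DDI network is a signed, undirected graph over ``m`` drugs:
an enhancive interaction (one drug increasing the other's pharmacological
effect) is a ``+1`` edge, a degressive one a ``-1`` edge, and ``0`` means
no known interaction.  The adjacency matrix ``A`` is symmetric with a zero
diagonal and entries in ``{-1, 0, +1}``.

Weak structural balance classifies each triangle (3-cycle) of such a
network by the multiset of its edge signs:

* ``PPP`` and ``NNP`` -- strongly balanced,
* ``NNN`` -- weakly balanced,
* ``PPN`` -- unbalanced (a single negative edge inside an otherwise
  positive triangle, or equivalently a positive edge bridging two
  mutually antagonistic nodes).

This module holds the network container, its sign decomposition
``A = A+ - A-``, the positive-part graph Laplacian ``L+ = D+ - A+``, the
triad census, and the sign-shuffle null model used to show that the triad
composition of a real DDI network differs from chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SignedNetwork",
    "TriadCensus",
    "split_signs",
    "signed_laplacian_plus",
    "triad_census",
    "shuffle_signs",
    "expected_shuffled_triad_fractions",
]


class ValidationError(ValueError):
    """Raised when an input violates the signed-network contract."""


@dataclass(frozen=True)
class SignedNetwork:
    """A signed, undirected network with labelled nodes.

    Parameters
    ----------
    labels:
        Ordered node identifiers (opaque strings), one per matrix row.
    adjacency:
        ``m x m`` integer matrix, symmetric, zero diagonal, entries in
        ``{-1, 0, +1}``.
    """

    labels: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError(f"adjacency must be square, got shape {a.shape}")
        if len(self.labels) != a.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for a {a.shape[0]}-node matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate node labels")
        if not np.isin(a, (-1, 0, 1)).all():
            bad = np.argwhere(~np.isin(a, (-1, 0, 1)))[0]
            raise ValidationError(f"entry {a[tuple(bad)]} at {tuple(bad)} not in {{-1,0,+1}}")
        if np.diagonal(a).any():
            raise ValidationError("self-loops are not allowed (nonzero diagonal)")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        object.__setattr__(self, "adjacency", a.astype(np.int8, copy=False))
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency)))

    def edge_sign_counts(self) -> tuple[int, int]:
        """Return ``(E+, E-)``: counts of enhancive and degressive edges."""
        upper = np.triu(self.adjacency)
        return int((upper == 1).sum()), int((upper == -1).sum())

    def subnetwork(self, indices: Sequence[int]) -> "SignedNetwork":
        """Induced subnetwork on the given node indices (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return SignedNetwork(
            labels=tuple(self.labels[i] for i in idx),
            adjacency=self.adjacency[np.ix_(idx, idx)],
        )


@dataclass(frozen=True)
class TriadCensus:
    """Counts of the four sign patterns over all triangles.

    ``NNP`` keys on the sign multiset, so PNN and NPN are the same class.
    """

    ppp: int
    nnp: int
    nnn: int
    ppn: int

    @property
    def total(self) -> int:
        return self.ppp + self.nnp + self.nnn + self.ppn

    def fractions(self) -> dict[str, float]:
        """Triad-class fractions; all zero when the network has no triangle."""
        t = self.total
        if t == 0:
            return {"ppp": 0.0, "nnp": 0.0, "nnn": 0.0, "ppn": 0.0}
        return {
            "ppp": self.ppp / t,
            "nnp": self.nnp / t,
            "nnn": self.nnn / t,
            "ppn": self.ppn / t,
        }


def split_signs(net: SignedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Decompose the signed adjacency into nonnegative parts.

    Returns ``(A+, A-)`` with ``a+_ij = (|a_ij| + a_ij)/2`` and
    ``a-_ij = (|a_ij| - a_ij)/2``, so ``A = A+ - A-`` and the two parts
    have disjoint supports.
    """
    a = net.adjacency.astype(float)
    abs_a = np.abs(a)
    return (abs_a + a) / 2.0, (abs_a - a) / 2.0


def signed_laplacian_plus(net: SignedNetwork) -> np.ndarray:
    """Graph Laplacian of the positive subnetwork, ``L+ = D+ - A+``.

    ``D+`` is the diagonal degree matrix of ``A+``.  ``L+`` is symmetric
    positive semidefinite with zero row sums; its quadratic form measures
    how much a community indicator cuts enhancive edges.
    """
    aplus, _ = split_signs(net)
    return np.diag(aplus.sum(axis=1)) - aplus


def triad_census(net: SignedNetwork) -> TriadCensus:
    """Count every triangle of the network by its sign pattern.

    Uses trace identities on the positive/negative parts: a triangle with
    signs drawn from matrices ``X, Y, Z`` closes ``tr(XYZ)`` walks, so
    ``#PPP = tr(P^3)/6``, ``#NNN = tr(N^3)/6``, ``#PPN = tr(P P N)/2``
    and ``#NNP = tr(N N P)/2`` (each mixed triangle is traversed twice
    per choice of matrix order).
    """
    p, n = split_signs(net)
    pp = p @ p
    nn = n @ n
    ppp = np.sum(pp * p) / 6.0
    nnn = np.sum(nn * n) / 6.0
    ppn = np.sum(pp * n) / 2.0
    nnp = np.sum(nn * p) / 2.0
    return TriadCensus(
        ppp=int(round(ppp)),
        nnp=int(round(nnp)),
        nnn=int(round(nnn)),
        ppn=int(round(ppn)),
    )


def shuffle_signs(net: SignedNetwork, seed: int) -> SignedNetwork:
    """Randomize edge polarities while keeping the interaction support fixed.

    The nonzero positions of the adjacency are untouched; the multiset of
    edge signs is permuted uniformly at random.  This is the null model in
    which enhancive/degressive labels carry no structural information, so
    its triad composition is the chance baseline against which a real DDI
    network's balance is judged.
    """
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(net.adjacency))
    signs = net.adjacency[iu, ju].copy()
    rng.shuffle(signs)
    a = np.zeros_like(net.adjacency)
    a[iu, ju] = signs
    a[ju, iu] = signs
    return SignedNetwork(labels=net.labels, adjacency=a)


def expected_shuffled_triad_fractions(
    n_positive: int, n_negative: int
) -> dict[str, float]:
    """Expected triad-class fractions under the uniform sign-shuffle null.

    When ``E+`` positive and ``E-`` negative signs are assigned to the
    ``E = E+ + E-`` edges by a uniform permutation, the three edges of any
    triangle are a simple random sample without replacement, so the class
    probabilities are hypergeometric::

        P(PPP) = C(E+,3) / C(E,3)        P(NNN) = C(E-,3) / C(E,3)
        P(PPN) = C(E+,2) C(E-,1) / C(E,3)
        P(NNP) = C(E-,2) C(E+,1) / C(E,3)

    This expectation does not depend on the topology of the support graph,
    only on the sign counts, and is what a Monte-Carlo shuffle experiment
    estimates.
    """
    ep, en = int(n_positive), int(n_negative)
    e = ep + en
    if e < 3:
        raise ValueError("need at least 3 edges for a triangle")
    denom = math.comb(e, 3)
    return {
        "ppp": math.comb(ep, 3) / denom,
        "nnp": math.comb(en, 2) * ep / denom,
        "nnn": math.comb(en, 3) / denom,
        "ppn": math.comb(ep, 2) * en / denom,
    }
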