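"""Community partitions of signed networks and their balance diagnostics.

Given a hard partition of a signed DDI network into ``k`` communities, two
families of statistics describe how well the partition respects weak
structural balance:

* the **community balance index** (CBI): the community-size-weighted mean
  fraction of non-PPN (i.e. balanced) triangles inside communities, in
  ``[0, 1]`` -- the global figure of merit for a partition;
* per-community densities of enhancive and degressive interactions and
  their contrasts -- the within-community log-ratio ``delta_w``, the
  between-community log-ratio ``delta_b``, and the density sum/difference
  ``SR_w = Re + Rd`` / ``DR_w = Re - Rd`` where ``Re`` (``Rd``) is the
  number of enhancive (degressive) pairs over all internal drug pairs.

A strongly balanced community has ``delta_w > 0`` (enhancive-dominated
inside); a weakly balanced one has ``delta_w < 0``; a well-separated pair
of communities has ``delta_b < 0`` (degressive-dominated between).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import SignedNetwork, triad_census

__all__ = ["CommunityPartition", "BalanceReport", "cbi", "within_between_report"]

#: pseudo-count of interactions added to each numerator before taking logs,
#: so that communities with zero enhancive or zero degressive pairs still
#: yield finite log-ratios
PSEUDO_COUNT = 0.5


class DegeneratePartitionError(ValueError):
    """Raised when a partition has no communities to evaluate."""


@dataclass(frozen=True)
class CommunityPartition:
    """Hard assignment of ``m`` nodes to communities ``1..k``."""

    assignment: np.ndarray = field(repr=False)
    k: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if self.k < 1:
            raise DegeneratePartitionError("partition must have k >= 1 communities")
        if a.ndim != 1:
            raise ValueError("assignment must be a 1-d vector")
        if a.size and (a.min() < 1 or a.max() > self.k):
            raise ValueError(f"community indices must lie in 1..{self.k}")
        object.__setattr__(self, "assignment", a)

    @property
    def n_nodes(self) -> int:
        return self.assignment.size

    def members(self, c: int) -> np.ndarray:
        """Indices of the nodes assigned to community ``c`` (1-based)."""
        return np.flatnonzero(self.assignment == c)

    def sizes(self) -> np.ndarray:
        """Length-``k`` vector of community sizes."""
        return np.bincount(self.assignment, minlength=self.k + 1)[1:]


@dataclass(frozen=True)
class BalanceReport:
    """Balance diagnostics of a partition of a signed network.

    ``delta_within[c]`` and the off-diagonal ``delta_between[c, d]`` are the
    within/between enhancive-vs-degressive log-ratio contrasts; the diagonal
    of ``delta_between`` repeats ``delta_within``.  Entries are ``NaN`` for
    communities (or pairs) too small to define a ratio.
    """

    cbi: float
    delta_within: np.ndarray
    delta_between: np.ndarray
    sr_within: np.ndarray
    dr_within: np.ndarray
    sizes: np.ndarray
    triadless_communities: tuple[int, ...]
    undersized_communities: tuple[int, ...]

    def to_dict(self) -> dict:
        """JSON-serializable form (NaN rendered as null by ``json.dump``)."""

        def _clean(x):
            return [None if (isinstance(v, float) and math.isnan(v)) else v for v in x]

        return {
            "cbi": self.cbi,
            "cbi_percent": 100.0 * self.cbi,
            "sizes": self.sizes.tolist(),
            "delta_within": _clean(self.delta_within.tolist()),
            "delta_between": [_clean(row) for row in self.delta_between.tolist()],
            "sr_within": _clean(self.sr_within.tolist()),
            "dr_within": _clean(self.dr_within.tolist()),
            "triadless_communities": list(self.triadless_communities),
            "undersized_communities": list(self.undersized_communities),
        }


def cbi(net: SignedNetwork, part: CommunityPartition) -> float:
    """Community balance index of a partition.

    ``CBI = sum_c n_c (1 - #PPN_c / #triads_c) / sum_c n_c`` where the
    counts are taken over triangles fully inside community ``c`` (the
    induced subnetwork).  A community with no internal triangle violates
    no balance constraint, so its term is defined as 1.
    """
    if part.n_nodes != net.n_nodes:
        raise ValueError("partition does not cover the network's nodes")
    total_weight = 0.0
    acc = 0.0
    for c in range(1, part.k + 1):
        members = part.members(c)
        if members.size == 0:
            continue
        census = triad_census(net.subnetwork(members))
        balanced_frac = 1.0 if census.total == 0 else 1.0 - census.ppn / census.total
        acc += members.size * balanced_frac
        total_weight += members.size
    if total_weight == 0:
        raise DegeneratePartitionError("partition assigns no nodes")
    return acc / total_weight


def _pair_ratios(block: np.ndarray, n_pairs: int) -> tuple[float, float]:
    """Raw enhancive/degressive densities of a block of the adjacency."""
    n_pos = int((block == 1).sum())
    n_neg = int((block == -1).sum())
    return n_pos / n_pairs, n_neg / n_pairs


def _log_contrast(n_pos: float, n_neg: float, n_pairs: int) -> float:
    """``ln(Re) - ln(Rd)`` with pseudo-counted numerators, always finite."""
    re = (n_pos + PSEUDO_COUNT) / n_pairs
    rd = (n_neg + PSEUDO_COUNT) / n_pairs
    return math.log(re) - math.log(rd)


def within_between_report(
    net: SignedNetwork, part: CommunityPartition
) -> BalanceReport:
    """Full balance diagnostics for a partition.

    For each community the internal enhancive/degressive densities are
    computed over its ``n_c (n_c - 1) / 2`` drug pairs, and for each pair
    of communities over the ``n_c * n_d`` cross pairs.  Log-contrasts use a
    pseudo-count (:data:`PSEUDO_COUNT`) so they remain finite when a class
    of interaction is absent; ``SR_w``/``DR_w`` use the raw densities.
    Communities with fewer than two members have no internal pair and are
    reported with ``NaN`` markers.
    """
    if part.n_nodes != net.n_nodes:
        raise ValueError("partition does not cover the network's nodes")
    k = part.k
    a = net.adjacency
    delta_w = np.full(k, np.nan)
    sr_w = np.full(k, np.nan)
    dr_w = np.full(k, np.nan)
    delta_b = np.full((k, k), np.nan)
    sizes = part.sizes()
    triadless: list[int] = []
    undersized: list[int] = []
    members = [part.members(c) for c in range(1, k + 1)]

    for c in range(k):
        idx = members[c]
        n_c = idx.size
        if n_c < 2:
            undersized.append(c + 1)
            continue
        block = a[np.ix_(idx, idx)]
        n_pairs = n_c * (n_c - 1) // 2
        # block is symmetric: each unordered pair appears twice
        n_pos = int((block == 1).sum()) // 2
        n_neg = int((block == -1).sum()) // 2
        sr_w[c] = (n_pos + n_neg) / n_pairs
        dr_w[c] = (n_pos - n_neg) / n_pairs
        delta_w[c] = _log_contrast(n_pos, n_neg, n_pairs)
        if triad_census(net.subnetwork(idx)).total == 0:
            triadless.append(c + 1)

    for c in range(k):
        delta_b[c, c] = delta_w[c]
        for d in range(c + 1, k):
            n_c, n_d = members[c].size, members[d].size
            if n_c == 0 or n_d == 0:
                continue
            cross = a[np.ix_(members[c], members[d])]
            n_pairs = n_c * n_d
            n_pos = int((cross == 1).sum())
            n_neg = int((cross == -1).sum())
            delta_b[c, d] = delta_b[d, c] = _log_contrast(n_pos, n_neg, n_pairs)

    return BalanceReport(
        cbi=cbi(net, part),
        delta_within=delta_w,
        delta_between=delta_b,
        sr_within=sr_w,
        dr_within=dr_w,
        sizes=sizes,
        triadless_communities=tuple(triadless),
        undersized_communities=tuple(undersized),
    )
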