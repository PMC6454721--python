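"""Generators for planted signed networks and community-linked features.

These emulate the structure a weakly balanced DDI network is believed to
have: drugs fall into communities where interactions are mostly enhancive
(strongly balanced blocks) or mostly degressive (weakly balanced blocks),
while interactions between communities are mostly degressive.  Binary
"drug-binding-protein"-style feature profiles are generated so that each
community owns a block of marker proteins, giving features a tunable
amount of community signal.

All generators are pure functions of their arguments and seed: the same
inputs always produce the same network, partition and features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .balance import CommunityPartition
from .coldstart import FeatureMatrix
from .network import SignedNetwork

__all__ = [
    "PlantedSpec",
    "planted_signed_network",
    "community_linked_features",
    "toy_signed_network",
    "coldstart_benchmark",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted-partition signed network.

    ``within_sign[c] = -1`` plants a weakly balanced community (degressive
    inside); ``between_positive_rate`` is the fraction of between-community
    edges that violate the all-negative ideal; ``flip_rate`` flips that
    fraction of all edge signs uniformly at random afterwards.
    """

    community_sizes: tuple[int, ...]
    within_edge_prob: float = 0.8
    between_edge_prob: float = 0.8
    within_sign: tuple[int, ...] | None = None
    between_positive_rate: float = 0.0
    flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.community_sizes):
            raise ValueError("community sizes must be positive")
        for name in ("within_edge_prob", "between_edge_prob",
                     "between_positive_rate", "flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        signs = self.within_sign
        if signs is None:
            signs = tuple(1 for _ in self.community_sizes)
        if len(signs) != len(self.community_sizes):
            raise ValueError("within_sign length must match community_sizes")
        if any(s not in (-1, 1) for s in signs):
            raise ValueError("within_sign entries must be +1 or -1")
        object.__setattr__(self, "within_sign", tuple(signs))
        object.__setattr__(self, "community_sizes", tuple(self.community_sizes))

    @property
    def n_nodes(self) -> int:
        return sum(self.community_sizes)

    @property
    def k(self) -> int:
        return len(self.community_sizes)


def planted_signed_network(
    spec: PlantedSpec,
) -> tuple[SignedNetwork, CommunityPartition]:
    """Draw a signed network with a planted community structure.

    Each within-community pair carries an edge with probability
    ``within_edge_prob`` and the community's planted sign; each
    between-community pair with probability ``between_edge_prob`` and sign
    ``-1`` except for a ``between_positive_rate`` fraction.  Finally a
    ``flip_rate`` fraction of all edges has its sign flipped.  Returns the
    network and the ground-truth partition.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_nodes
    labels = np.repeat(np.arange(1, spec.k + 1), spec.community_sizes)
    a = np.zeros((m, m), dtype=int)
    iu, ju = np.triu_indices(m, k=1)
    same = labels[iu] == labels[ju]

    p_edge = np.where(same, spec.within_edge_prob, spec.between_edge_prob)
    has_edge = rng.random(iu.size) < p_edge

    within_sign = np.array([0] + list(spec.within_sign))[labels[iu]]
    between_sign = np.where(
        rng.random(iu.size) < spec.between_positive_rate, 1, -1
    )
    sign = np.where(same, within_sign, between_sign)
    sign = np.where(rng.random(iu.size) < spec.flip_rate, -sign, sign)
    vals = np.where(has_edge, sign, 0)
    a[iu, ju] = vals
    a[ju, iu] = vals
    net = SignedNetwork(
        labels=tuple(f"d{i:03d}" for i in range(m)), adjacency=a
    )
    part = CommunityPartition(assignment=labels, k=spec.k)
    return net, part


def community_linked_features(
    part: CommunityPartition,
    p: int,
    signal: float,
    noise: float,
    seed: int,
    labels: tuple[str, ...] | None = None,
) -> FeatureMatrix:
    """Binary feature profiles statistically tied to a partition.

    The ``p`` features are split into ``k`` disjoint marker blocks of
    ``floor(p / k)`` features each (any remainder belongs to no community).
    A drug's marker features fire with probability ``signal`` and all
    other features with probability ``noise``; ``signal == noise`` makes
    the features carry no community information.
    """
    if p < part.k:
        raise ValueError(f"need at least k={part.k} features, got p={p}")
    if not (0.0 <= signal <= 1.0 and 0.0 <= noise <= 1.0):
        raise ValueError("signal and noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    m = part.n_nodes
    block = p // part.k
    prob = np.full((m, p), noise)
    for c in range(part.k):
        rows = part.members(c + 1)
        prob[np.ix_(rows, np.arange(c * block, (c + 1) * block))] = signal
    values = (rng.random((m, p)) < prob).astype(np.int8)
    if labels is None:
        labels = tuple(f"d{i:03d}" for i in range(m))
    return FeatureMatrix(
        labels=labels,
        values=values,
        feature_names=tuple(f"prot{j:04d}" for j in range(p)),
    )


def toy_signed_network() -> tuple[SignedNetwork, CommunityPartition]:
    """A small hand-built four-community signed network for demos and smoke tests.

    Three strongly balanced communities (all-enhancive triangles), one
    weakly balanced community (all-degressive triangle), degressive edges
    between communities, and a single planted unbalanced PPN triangle that
    spans communities 1 and 2.  The topology is a synthetic construction
    for illustration, not a published network.
    """
    edges = [
        # community 1: enhancive clique fragment
        ("a1", "a2", 1), ("a1", "a3", 1), ("a2", "a3", 1),
        ("a2", "a4", 1), ("a3", "a4", 1),
        # community 2: enhancive triangle
        ("b1", "b2", 1), ("b1", "b3", 1), ("b2", "b3", 1),
        # community 3: enhancive triangle
        ("c1", "c2", 1), ("c1", "c3", 1), ("c2", "c3", 1),
        # community 4: weakly balanced (all-degressive) triangle
        ("e1", "e2", -1), ("e1", "e3", -1), ("e2", "e3", -1),
        # degressive bridges between communities
        ("a1", "b1", -1), ("a2", "c1", -1), ("a3", "e1", -1),
        ("b2", "c2", -1), ("b3", "e2", -1), ("c3", "e3", -1),
        # one enhancive edge bridging communities 1-2: the network's only
        # unbalanced PPN triangle (a1, b1, b2)
        ("a1", "b2", 1),
    ]
    labels: list[str] = []
    for u, v, _ in edges:
        for x in (u, v):
            if x not in labels:
                labels.append(x)
    idx = {x: i for i, x in enumerate(labels)}
    a = np.zeros((len(labels), len(labels)), dtype=int)
    for u, v, s in edges:
        a[idx[u], idx[v]] = s
        a[idx[v], idx[u]] = s
    net = SignedNetwork(labels=tuple(labels), adjacency=a)
    assignment = np.array([{"a": 1, "b": 2, "c": 3, "e": 4}[x[0]] for x in labels])
    return net, CommunityPartition(assignment=assignment, k=4)


def coldstart_benchmark(
    seed: int = 0,
    community_sizes: tuple[int, ...] = (40, 40, 40),
    within_edge_prob: float = 0.9,
    between_edge_prob: float = 0.1,
    flip_rate: float = 0.05,
    between_positive_rate: float = 0.05,
    p: int = 60,
    signal: float = 0.9,
    noise: float = 0.1,
) -> tuple[SignedNetwork, CommunityPartition, FeatureMatrix]:
    """The standard synthetic cold-start benchmark.

    Three strongly balanced 40-drug communities with dense enhancive
    interactions inside, sparse degressive interactions between, 5% sign
    noise, and 60 binary protein-style features with strong community
    signal.  Returns the network, the planted partition and the features.
    """
    spec = PlantedSpec(
        community_sizes=tuple(community_sizes),
        within_edge_prob=within_edge_prob,
        between_edge_prob=between_edge_prob,
        flip_rate=flip_rate,
        between_positive_rate=between_positive_rate,
        seed=seed,
    )
    net, part = planted_signed_network(spec)
    features = community_linked_features(
        part, p=p, signal=signal, noise=noise, seed=seed + 1, labels=net.labels
    )
    return net, part, features
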