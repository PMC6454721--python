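"""Cold-start prediction of signed drug-drug interactions.

A "new" drug has no known interaction, so its row of the DDI matrix is
empty and network methods alone cannot score it.  The cold-start pipeline
bridges the gap through drug features (binary drug-binding-protein
profiles or any binary fingerprint):

1. **Training.** Factorize the known-drug network ``A ~ W H^T`` with
   BRSNMF, then fit a partial-least-squares regression ``H = F B`` from
   the ``m x p`` feature matrix ``F`` to the latent indicators ``H``.
2. **Prediction.** Map the ``n x p`` query features into the latent space,
   ``H_x = F_x B``, and score all query-by-known pairs as
   ``A_x = H_x W^T``.  Large positive scores suggest enhancive
   interactions, large negative scores degressive ones, and scores near
   zero suggest no interaction.

Because absolute score cutoffs are not comparable across latent
dimensions, all evaluation is rank-based: top-n / bottom-n polarity
accuracy, AUROC and AUPR for interaction detection (``|label|`` against
``|score|``), and the mean percentile ranking (MPR) of true interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import svd
from sklearn.metrics import average_precision_score, roc_auc_score

from .factorization import BrsnmfConfig, FactorizationResult, brsnmf
from .network import SignedNetwork

__all__ = [
    "FeatureMatrix",
    "ColdStartModel",
    "PredictionResult",
    "RankingMetrics",
    "pls_coefficients",
    "train",
    "predict",
    "evaluate_ranking",
    "cross_validate",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Binary drug-feature profiles (rows: drugs, columns: e.g. proteins)."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-d")
        if v.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError(
                f"shape {v.shape} does not match {len(self.labels)} labels x "
                f"{len(self.feature_names)} features"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate drug labels in feature matrix")
        if v.size and not np.isin(v, (0, 1)).all():
            r, c = np.argwhere(~np.isin(v, (0, 1)))[0]
            raise ValueError(f"non-binary value {v[r, c]} at row {r}, column {c}")
        object.__setattr__(self, "values", v.astype(np.int8, copy=False))
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(
            self, "feature_names", tuple(str(x) for x in self.feature_names)
        )

    @property
    def n_drugs(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            labels=tuple(self.labels[i] for i in idx),
            values=self.values[idx],
            feature_names=self.feature_names,
        )


@dataclass(frozen=True)
class ColdStartModel:
    """Trained cold-start predictor: centroids ``W`` and PLS map ``B``."""

    W: np.ndarray = field(repr=False)
    B: np.ndarray = field(repr=False)
    training_labels: tuple[str, ...]
    feature_names: tuple[str, ...]
    config: BrsnmfConfig
    factorization: FactorizationResult | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.B.shape[1] != self.W.shape[1]:
            raise ValueError(
                f"B maps to {self.B.shape[1]} latent dims but W has {self.W.shape[1]}"
            )


@dataclass(frozen=True)
class PredictionResult:
    """Signed interaction scores for query drugs against training drugs."""

    scores: np.ndarray = field(repr=False)
    query_labels: tuple[str, ...]
    target_labels: tuple[str, ...]

    def ranked_pairs(self) -> list[tuple[str, str, float]]:
        """All (query, target, score) triples, best (largest) score first.

        Ties are broken by (query label, target label) so the ranking is a
        deterministic total order.
        """
        n, m = self.scores.shape
        triples = [
            (self.query_labels[i], self.target_labels[j], float(self.scores[i, j]))
            for i in range(n)
            for j in range(m)
        ]
        triples.sort(key=lambda t: (-t[2], t[0], t[1]))
        return triples


@dataclass(frozen=True)
class RankingMetrics:
    """Rank-based evaluation of signed interaction predictions."""

    top_n_accuracy: dict[int, float]
    bottom_n_accuracy: dict[int, float]
    auroc: float
    aupr: float
    mpr: float
    n_pairs: int
    n_enhancive: int
    n_degressive: int


def pls_coefficients(
    x: np.ndarray, y: np.ndarray, n_components: int
) -> np.ndarray:
    """Partial-least-squares regression coefficients for ``Y ~ X B``.

    NIPALS-style PLS2 on the raw (uncentered) matrices, so the fitted map
    is strictly linear: ``B`` is ``p x k`` and a zero feature row maps to
    a zero latent row.  Each component takes the dominant singular pair of
    the cross-covariance ``X^T Y`` and deflates both blocks by the
    corresponding score direction.
    """
    x = np.array(x, dtype=float)
    y = np.array(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n_components = int(n_components)
    if n_components < 1:
        raise ValueError("need at least one PLS component")
    p = x.shape[1]
    ws, ps, qs = [], [], []
    for _ in range(n_components):
        c = x.T @ y
        if np.linalg.norm(c) < 1e-12:
            break
        u_svd, _, _ = svd(c, full_matrices=False)
        w = u_svd[:, 0]
        t = x @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_load = x.T @ t / tt
        q_load = y.T @ t / tt
        x = x - np.outer(t, p_load)
        y = y - np.outer(t, q_load)
        ws.append(w)
        ps.append(p_load)
        qs.append(q_load)
    if not ws:
        return np.zeros((p, np.atleast_2d(y).shape[1]))
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    q_mat = np.column_stack(qs)
    # rotation from raw X to scores: R = W (P^T W)^{-1}; B = R Q^T
    r = w_mat @ np.linalg.solve(p_mat.T @ w_mat, np.eye(w_mat.shape[1]))
    return r @ q_mat.T


def train(
    net: SignedNetwork, features: FeatureMatrix, cfg: BrsnmfConfig
) -> ColdStartModel:
    """Fit BRSNMF on the known-drug network and a PLS map from features.

    The number of PLS components is ``min(k, p, m - 1)``: the latent
    target has ``k`` dimensions and PLS cannot exceed the data rank.
    """
    if features.labels != net.labels:
        raise ValueError(
            "feature matrix labels must match the network's labels in order"
        )
    fac = brsnmf(net, cfg)
    m, p = features.values.shape
    n_comp = min(cfg.k, p, m - 1)
    if n_comp < 1:
        raise ValueError(f"cannot fit PLS with m={m} drugs and p={p} features")
    b = pls_coefficients(features.values.astype(float), fac.H, n_comp)
    return ColdStartModel(
        W=fac.W,
        B=b,
        training_labels=net.labels,
        feature_names=features.feature_names,
        config=cfg,
        factorization=fac,
    )


def predict(model: ColdStartModel, features_x: FeatureMatrix) -> PredictionResult:
    """Score query-drug interactions: ``A_x = (F_x B) W^T``.

    The map is linear in the query features; positive scores point toward
    enhancive interactions, negative toward degressive.
    """
    if features_x.feature_names != model.feature_names:
        raise ValueError("query feature columns do not match the trained model")
    h_x = features_x.values.astype(float) @ model.B
    scores = h_x @ model.W.T
    return PredictionResult(
        scores=scores,
        query_labels=features_x.labels,
        target_labels=model.training_labels,
    )


def evaluate_ranking(
    truth: np.ndarray,
    pred: PredictionResult,
    n_list: Iterable[int] = (10, 50),
) -> RankingMetrics:
    """Rank-based metrics of signed predictions against signed labels.

    ``truth`` is an ``n x m`` matrix over query-by-target pairs with
    entries in {-1, 0, +1}.  Reported are:

    * top-n accuracy -- the fraction of enhancive (+1) pairs among the
      ``n`` largest signed scores, and bottom-n accuracy -- the fraction
      of degressive (-1) pairs among the ``n`` smallest;
    * AUROC and AUPR for detecting any interaction (``|label| = 1``)
      with ``|score|`` as the ranking statistic (``NaN`` when the truth is
      one-class);
    * MPR -- for every true interaction, its percentile position (0 = top)
      in its query drug's candidates sorted by ``|score|`` descending,
      averaged over all true interactions.
    """
    truth = np.asarray(truth)
    if truth.shape != pred.scores.shape:
        raise ValueError(f"truth {truth.shape} vs scores {pred.scores.shape}")
    if truth.size and not np.isin(truth, (-1, 0, 1)).all():
        raise ValueError("truth entries must be in {-1, 0, +1}")
    scores = pred.scores
    n, m = scores.shape
    flat_labels = truth.ravel()
    # deterministic total order: score, then (query, target) label
    tie_key = np.array(
        [(pred.query_labels[i], pred.target_labels[j]) for i in range(n) for j in range(m)],
        dtype=object,
    )
    order_desc = sorted(
        range(n * m),
        key=lambda idx: (-scores.ravel()[idx], tuple(tie_key[idx])),
    )
    top_acc: dict[int, float] = {}
    bottom_acc: dict[int, float] = {}
    for nn in n_list:
        nn = int(nn)
        top = flat_labels[order_desc[:nn]]
        bottom = flat_labels[order_desc[-nn:]]
        top_acc[nn] = float((top == 1).mean()) if top.size else float("nan")
        bottom_acc[nn] = float((bottom == -1).mean()) if bottom.size else float("nan")

    y = np.abs(flat_labels)
    s = np.abs(scores.ravel())
    if 0 < y.sum() < y.size:
        auroc = float(roc_auc_score(y, s))
        aupr = float(average_precision_score(y, s))
    else:
        auroc = float("nan")
        aupr = float("nan")

    percentiles = []
    for i in range(n):
        row = np.abs(scores[i])
        # rank 0 = largest |score|; average ranks over ties for stability
        order = np.argsort(-row, kind="stable")
        ranks = np.empty(m)
        ranks[order] = np.arange(m)
        denom = max(m - 1, 1)
        for j in np.flatnonzero(np.abs(truth[i]) == 1):
            percentiles.append(ranks[j] / denom)
    mpr = float(np.mean(percentiles)) if percentiles else float("nan")

    return RankingMetrics(
        top_n_accuracy=top_acc,
        bottom_n_accuracy=bottom_acc,
        auroc=auroc,
        aupr=aupr,
        mpr=mpr,
        n_pairs=n * m,
        n_enhancive=int((flat_labels == 1).sum()),
        n_degressive=int((flat_labels == -1).sum()),
    )


def _fold_indices(m: int, scheme: str | int, seed: int) -> list[np.ndarray]:
    """Drug-level fold assignment: LOOCV or seeded n-fold."""
    if isinstance(scheme, str) and scheme.lower() == "loocv":
        return [np.array([i]) for i in range(m)]
    n_folds = int(scheme)
    if n_folds < 2 or n_folds > m:
        raise ValueError(f"n_folds={n_folds} invalid for m={m} drugs")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def cross_validate(
    net: SignedNetwork,
    features: FeatureMatrix,
    cfg: BrsnmfConfig,
    scheme: str | int = 10,
    seed: int = 0,
    n_list: Iterable[int] = (10, 50),
) -> list[RankingMetrics]:
    """Cold-start cross-validation at the drug level.

    Every fold removes a set of drugs *and all their interactions* from
    the network, trains on the remainder, predicts the removed drugs'
    interaction rows from their features alone, and scores them against
    the removed interactions.  Folds partition drugs (never pairs), so no
    held-out drug leaks any interaction into training.
    """
    if features.labels != net.labels:
        raise ValueError("feature labels must match network labels")
    m = net.n_nodes
    if m < 3:
        raise ValueError("need at least 3 drugs for cross-validation")
    folds = _fold_indices(m, scheme, seed)
    results = []
    all_idx = np.arange(m)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        if train_idx.size <= cfg.k:
            raise ValueError(
                f"fold leaves {train_idx.size} training drugs for k={cfg.k}"
            )
        sub_net = net.subnetwork(train_idx)
        # cold-start hygiene: no held-out drug appears in the training network
        assert not set(sub_net.labels) & {net.labels[i] for i in test_idx}
        model = train(sub_net, features.subset(train_idx), cfg)
        pred = predict(model, features.subset(test_idx))
        truth = net.adjacency[np.ix_(test_idx, train_idx)]
        results.append(evaluate_ranking(truth, pred, n_list))
    return results
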