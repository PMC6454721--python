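"""Readers and writers for the package's plain-text formats.

* signed edge list: three delimited columns ``drug_a, drug_b, sign`` with
  sign in ``{+1, -1, 1, -1}``; an optional header is detected by a
  non-numeric third field; node order is first appearance;
* partition file: two columns ``drug, community_index``;
* feature matrix: header row of feature (protein) names, first column the
  drug label, binary body;
* balance report: JSON;
* cold-start model: a directory of labelled delimited matrices plus a
  config JSON.

Writers emit a byte-stable dialect (tab-delimited, LF endings) so runs
are reproducible and diffable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .balance import BalanceReport, CommunityPartition
from .coldstart import ColdStartModel, FeatureMatrix, PredictionResult
from .factorization import BrsnmfConfig
from .network import SignedNetwork, ValidationError

__all__ = [
    "read_signed_edgelist",
    "write_signed_edgelist",
    "read_partition",
    "write_partition",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_balance_report",
    "save_model",
    "load_model",
    "write_predictions",
]

_SIGN_TOKENS = {"1": 1, "+1": 1, "-1": -1}


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_signed_edgelist(path: str | Path) -> SignedNetwork:
    """Parse a signed edge list into a validated network.

    Node order is first appearance.  Self-loops are rejected; duplicate
    edges collapse when their signs agree and are an error otherwise.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows: list[tuple[str, str, int]] = []
    labels: list[str] = []
    seen: dict[tuple[str, str], int] = {}
    label_pos: dict[str, int] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(_detect_delimiter(line))]
        if len(parts) != 3:
            raise ValidationError(
                f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
            )
        u, v, sign_txt = parts
        if sign_txt not in _SIGN_TOKENS:
            if lineno == 1:  # header row
                continue
            raise ValidationError(
                f"{path}:{lineno}: sign {sign_txt!r} not in {{+1, -1}}"
            )
        if u == v:
            raise ValidationError(f"{path}:{lineno}: self-loop on {u!r}")
        s = _SIGN_TOKENS[sign_txt]
        key = (u, v) if u <= v else (v, u)
        if key in seen:
            if seen[key] != s:
                raise ValidationError(
                    f"{path}:{lineno}: conflicting duplicate signs for pair {key}"
                )
            continue
        seen[key] = s
        for x in (u, v):
            if x not in label_pos:
                label_pos[x] = len(labels)
                labels.append(x)
        rows.append((u, v, s))
    if not rows:
        raise ValidationError(f"{path}: no edges found")
    m = len(labels)
    a = np.zeros((m, m), dtype=int)
    for u, v, s in rows:
        i, j = label_pos[u], label_pos[v]
        a[i, j] = a[j, i] = s
    return SignedNetwork(labels=tuple(labels), adjacency=a)


def write_signed_edgelist(net: SignedNetwork, path: str | Path) -> None:
    path = Path(path)
    iu, ju = np.nonzero(np.triu(net.adjacency))
    lines = ["drug_a\tdrug_b\tsign"]
    for i, j in zip(iu, ju):
        s = int(net.adjacency[i, j])
        lines.append(f"{net.labels[i]}\t{net.labels[j]}\t{'+1' if s > 0 else '-1'}")
    path.write_text("\n".join(lines) + "\n")


def read_partition(path: str | Path, labels: tuple[str, ...]) -> CommunityPartition:
    """Read a two-column partition file aligned to the given node order."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["drug", "community"], comment="#", dtype=str)
    if str(df.iloc[0, 1]).strip().lower() in ("community", "community_index"):
        df = df.iloc[1:]
    mapping = {str(r.drug).strip(): int(r.community) for r in df.itertuples()}
    missing = [lab for lab in labels if lab not in mapping]
    if missing:
        raise ValidationError(f"partition file misses drugs: {missing[:5]}")
    assignment = np.array([mapping[lab] for lab in labels])
    return CommunityPartition(assignment=assignment, k=int(assignment.max()))


def write_partition(
    part: CommunityPartition, labels: tuple[str, ...], path: str | Path
) -> None:
    lines = ["drug\tcommunity"]
    lines += [f"{lab}\t{c}" for lab, c in zip(labels, part.assignment)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Read a delimited binary feature matrix with a header row."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: header-only file, no drugs")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate drug label {dup!r}")
    values = df.to_numpy()
    bad = np.argwhere(~np.isin(values, (0, 1)))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"{path}: non-binary value {values[r, c]!r} at row {r + 1} "
            f"(drug {df.index[r]!r}), column {c + 1} ({df.columns[c]!r})"
        )
    return FeatureMatrix(
        labels=tuple(str(x) for x in df.index),
        values=values.astype(np.int8),
        feature_names=tuple(str(c) for c in df.columns),
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fm.values, index=list(fm.labels), columns=list(fm.feature_names))
    df.index.name = "drug"
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_balance_report(report: BalanceReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def _write_labelled_matrix(
    mat: np.ndarray, row_labels: tuple[str, ...], path: Path
) -> None:
    df = pd.DataFrame(mat, index=list(row_labels))
    df.index.name = "label"
    df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.12g")


def _read_labelled_matrix(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), tuple(str(x) for x in df.index)


def save_model(model: ColdStartModel, directory: str | Path) -> None:
    """Serialize a cold-start model as a directory of text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_labelled_matrix(model.W, model.training_labels, directory / "W.tsv")
    _write_labelled_matrix(model.B, model.feature_names, directory / "B.tsv")
    (directory / "config.json").write_text(
        json.dumps(dataclasses.asdict(model.config), indent=2) + "\n"
    )


def load_model(directory: str | Path) -> ColdStartModel:
    directory = Path(directory)
    w, training_labels = _read_labelled_matrix(directory / "W.tsv")
    b, feature_names = _read_labelled_matrix(directory / "B.tsv")
    cfg = BrsnmfConfig(**json.loads((directory / "config.json").read_text()))
    return ColdStartModel(
        W=w, B=b, training_labels=training_labels,
        feature_names=feature_names, config=cfg,
    )


def write_predictions(pred: PredictionResult, path: str | Path) -> None:
    lines = ["query\ttarget\tscore\trank"]
    for rank, (q, t, s) in enumerate(pred.ranked_pairs(), start=1):
        lines.append(f"{q}\t{t}\t{s:.12g}\t{rank}")
    Path(path).write_text("\n".join(lines) + "\n")
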