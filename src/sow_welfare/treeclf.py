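"""Depth-limited CART classifier distilling cluster labels.

The welfare labels produced by clustering manual-observation indices
are predicted from the 13 automatically recorded features (7 feeder
features at the sow level, 6 posture percentages at the group level)
with a small axis-aligned binary decision tree — interpretable enough
to read as husbandry rules. Splits minimize weighted Gini impurity
over midpoints of adjacent observed values; ties break by feature name
then lower threshold so trees are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CLASSES = ("aggressive", "gentle", "scapegoat")


class TreeError(ValueError):
    pass


@dataclass
class TreeNode:
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  # feature <= threshold
    right: "TreeNode | None" = None  # feature > threshold
    prediction: str | None = None
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": True, "prediction": self.prediction, "counts": self.counts}
        return {
            "leaf": False,
            "feature": self.feature,
            "threshold": self.threshold,
            "counts": self.counts,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if d["leaf"]:
            return cls(prediction=d["prediction"], counts=dict(d.get("counts", {})))
        return cls(
            feature=d["feature"],
            threshold=float(d["threshold"]),
            counts=dict(d.get("counts", {})),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class TreeModel:
    root: TreeNode
    max_depth: int
    features: list[str]
    classes: tuple[str, ...] = CLASSES

    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_leaf else 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def to_dict(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "features": self.features,
            "classes": list(self.classes),
            "root": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        return cls(
            root=TreeNode.from_dict(d["root"]),
            max_depth=int(d["max_depth"]),
            features=list(d["features"]),
            classes=tuple(d["classes"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TreeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def stratified_split(
    records: pd.DataFrame,
    test_fraction: float,
    seed: int,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class random split into train/test partitions.

    Each class contributes round(n_class × test_fraction) records to
    the test set, so class proportions are preserved to within one
    record. Classes with fewer than 2 records cannot be split.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise TreeError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in sorted(records[label_col].unique()):
        idx = records.index[records[label_col] == cls].to_numpy()
        if len(idx) < 2:
            raise TreeError(f"class {cls!r} has fewer than 2 records")
        n_test = int(round(len(idx) * test_fraction))
        test_idx.extend(rng.permutation(idx)[:n_test])
    test_mask = records.index.isin(test_idx)
    return records.loc[~test_mask], records.loc[test_mask]


def gini(counts) -> float:
    """Gini impurity 1 − Σ p² of a class-count vector."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise TreeError("counts must be non-negative")
    n = c.sum()
    if n == 0:
        raise TreeError("gini of an empty node is undefined")
    p = c / n
    return float(1.0 - (p**2).sum())


def _class_counts(y: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    return np.array([(y == c).sum() for c in classes], dtype=float)


def best_split(
    records: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    features: Sequence[str],
) -> tuple[str, float, float] | None:
    """Exhaustive search for the impurity-minimizing axis-aligned split.

    Candidate thresholds are midpoints of consecutive distinct sorted
    values of each feature; the split maximizing the weighted Gini
    decrease is returned, ties broken by feature-name order then lower
    threshold. Returns None when no split decreases impurity.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < 2:
        return None
    classes = np.unique(y)
    parent = gini(_class_counts(y, classes))
    best = None
    for feature in sorted(features):
        values = records[feature].to_numpy(dtype=float)
        order = np.argsort(values, kind="stable")
        vs, ys = values[order], y[order]
        # prefix class counts at each boundary between distinct values
        left = np.zeros(len(classes))
        total = _class_counts(ys, classes)
        for i in range(n - 1):
            left[np.searchsorted(classes, ys[i])] += 1
            if vs[i + 1] <= vs[i]:
                continue
            threshold = (vs[i] + vs[i + 1]) / 2.0
            nl = i + 1
            right = total - left
            decrease = parent - (nl * gini(left) + (n - nl) * gini(right)) / n
            if decrease > 1e-12 and (best is None or decrease > best[2] + 1e-12):
                best = (feature, float(threshold), float(decrease))
    return best


def grow_tree(
    records: pd.DataFrame,
    labels,
    max_depth: int,
    features: Sequence[str] | None = None,
    classes: Sequence[str] = CLASSES,
    min_samples_leaf: int = 1,
    min_impurity_decrease: float = 0.0,
) -> TreeModel:
    """Recursively grow a Gini CART tree on `features` to `max_depth`.

    Growth stops at purity, the depth bound, or when no split improves
    impurity. Pruning knobs (`min_samples_leaf`, `min_impurity_decrease`)
    default to off.
    """
    y = np.asarray(labels)
    if len(records) == 0:
        raise TreeError("cannot grow a tree on an empty training set")
    if features is None:
        features = [c for c in records.columns if records[c].dtype.kind in "fi"]
    features = list(features)

    def majority(ys: np.ndarray) -> str:
        counts = _class_counts(ys, classes)
        return classes[int(counts.argmax())]  # ties: class order

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        ys = y[idx]
        counts = {c: int((ys == c).sum()) for c in classes}
        node = TreeNode(prediction=majority(ys), counts=counts)
        if depth >= max_depth or len(np.unique(ys)) == 1:
            return node
        split = best_split(records.iloc[idx], ys, features)
        if split is None or split[2] < min_impurity_decrease:
            return node
        feature, threshold, _ = split
        mask = records.iloc[idx][feature].to_numpy(dtype=float) <= threshold
        if mask.sum() < min_samples_leaf or (~mask).sum() < min_samples_leaf:
            return node
        node.feature, node.threshold = feature, threshold
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        node.prediction = None
        return node

    root = build(np.arange(len(records)), 0)
    return TreeModel(root=root, max_depth=max_depth, features=features, classes=tuple(classes))


def predict(tree: TreeModel, record: Mapping[str, float]) -> str:
    """Deterministic root-to-leaf traversal: '≤' goes left, '>' right."""
    node = tree.root
    while not node.is_leaf:
        if node.feature not in record:
            raise TreeError(f"record is missing feature {node.feature!r}")
        node = node.left if record[node.feature] <= node.threshold else node.right
    return node.prediction


def rule_path(tree: TreeModel, record: Mapping[str, float]) -> list[str]:
    """Human-readable conditions traversed for one record."""
    node = tree.root
    path = []
    while not node.is_leaf:
        value = record[node.feature]
        if value <= node.threshold:
            path.append(f"{node.feature} <= {node.threshold:g}")
            node = node.left
        else:
            path.append(f"{node.feature} > {node.threshold:g}")
            node = node.right
    path.append(f"=> {node.prediction}")
    return path


def predict_frame(tree: TreeModel, records: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [predict(tree, row) for row in records.to_dict("records")],
        index=records.index,
        name="prediction",
        dtype=object,
    )


def rules_text(tree: TreeModel) -> str:
    """Flat 'if ... then ...' listing of every root-to-leaf path."""
    lines = []

    def walk(node: TreeNode, conds: list[str]):
        if node.is_leaf:
            cond = " and ".join(conds) if conds else "always"
            lines.append(f"if {cond} then {node.prediction}  (counts: {node.counts})")
            return
        walk(node.left, conds + [f"{node.feature} <= {node.threshold:g}"])
        walk(node.right, conds + [f"{node.feature} > {node.threshold:g}"])

    walk(tree.root, [])
    return "\n".join(lines)


@dataclass
class EvalReport:
    """Accuracy, per-class precision/recall/F1 and the confusion matrix."""

    accuracy: float
    confusion: pd.DataFrame  # rows: truth, columns: prediction
    per_class: pd.DataFrame  # index: class; precision, recall, f1, support
    macro_f1: float
    weighted_f1: float
    dataset: str = ""
    feature_set: str = ""

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "feature_set": self.feature_set,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "per_class": self.per_class.to_dict("index"),
            "confusion": self.confusion.to_dict("index"),
        }


def evaluate(
    predictions,
    truth,
    classes: Sequence[str] = CLASSES,
    dataset: str = "",
    feature_set: str = "",
) -> EvalReport:
    """Confusion matrix and derived metrics (0/0 conventions → 0)."""
    pred = np.asarray(predictions)
    y = np.asarray(truth)
    if len(pred) != len(y):
        raise TreeError("predictions and truth must have equal length")
    bad = set(pred) | set(y)
    if not bad <= set(classes):
        raise TreeError(f"labels outside {classes}: {sorted(bad - set(classes))}")
    confusion = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(y, pred):
        confusion.loc[t, p] += 1
    total = confusion.to_numpy().sum()
    accuracy = float(np.trace(confusion.to_numpy())) / total if total else 0.0
    rows = {}
    for c in classes:
        tp = confusion.loc[c, c]
        precision = tp / confusion[c].sum() if confusion[c].sum() else 0.0
        recall = tp / confusion.loc[c].sum() if confusion.loc[c].sum() else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows[c] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
            "support": int(confusion.loc[c].sum()),
        }
    per_class = pd.DataFrame(rows).T
    support = per_class["support"].to_numpy()
    weighted = float((per_class["f1"] * support).sum() / support.sum()) if support.sum() else 0.0
    return EvalReport(
        accuracy=accuracy,
        confusion=confusion,
        per_class=per_class,
        macro_f1=float(per_class["f1"].mean()),
        weighted_f1=weighted,
        dataset=dataset,
        feature_set=feature_set,
    )


def reference_tree() -> TreeModel:
    """A fixed, hand-specified example tree over group/feeder features.

    Encodes the canonical interpretable rule used in docs and tests: a
    sow is classified ``aggressive`` when her group spends more than
    3.39 % of the day eating, she makes more than 3.5 non-nutritive
    feeder visits per day, and her group spends more than 15.28 % of
    the day standing. The remaining leaves carry plausible defaults
    (``gentle`` for calm-group branches, ``scapegoat`` for the
    low-standing branch).
    """
    leaf = lambda cls: TreeNode(prediction=cls)
    root = TreeNode(
        feature="eating",
        threshold=3.39,
        left=leaf("gentle"),
        right=TreeNode(
            feature="nb_nnv_per_day",
            threshold=3.5,
            left=leaf("gentle"),
            right=TreeNode(
                feature="standing",
                threshold=15.28,
                left=leaf("scapegoat"),
                right=leaf("aggressive"),
            ),
        ),
    )
    return TreeModel(
        root=root, max_depth=3, features=["eating", "nb_nnv_per_day", "standing"]
    )
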