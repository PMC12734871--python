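"""Per-level GIN classifiers for the natural-product hierarchy.

One network is trained independently per level (pathway, superclass, class),
evaluated by stratified 10-fold cross-validation with macro-averaged F1 and
accuracy, then refit on all data.  Hierarchical consistency of a prediction
(class parent chain matching the ontology) is checked after decoding; an
optional strict mode instead masks class probabilities to children of the
predicted superclass.

Confidence is the maximum softmax probability at each level — the quantity
reported as "Acc. %" alongside each assignment — and drives the curation
queue: assignments whose weakest level falls below a threshold, or whose
levels disagree with the hierarchy, are flagged for expert review.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .feature_io import Ontology
from .gin import GinConfig, GinNetwork
from .molgraph import FeatureVocab, MoleculeGraph, featurize_batch

__all__ = [
    "LEVELS",
    "LevelModel",
    "ClassPrediction",
    "CvReport",
    "stratified_folds",
    "macro_f1",
    "accuracy",
    "train_level_model",
    "HierarchyClassifier",
    "predict_hierarchy",
    "flag_low_confidence",
    "merge_rare_classes",
]

LEVELS = ("pathway", "superclass", "class")


def stratified_folds(labels: Sequence[str], k: int, seed: int) -> list[list[int]]:
    """Partition indices into k folds preserving per-class proportions.

    Each class's (shuffled) members are dealt round-robin across folds,
    starting from a rotating offset so that classes smaller than k do not
    all land in the low-numbered folds.  Per-fold per-class counts therefore
    differ by at most 1.
    """
    n = len(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for idx, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(idx)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for lab in sorted(by_class):
        members = by_class[lab]
        order = rng.permutation(len(members))
        for pos, oi in enumerate(order):
            folds[(offset + pos) % k].append(members[oi])
        offset = (offset + len(members)) % k
    return folds


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def macro_f1(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None) -> float:
    """Unweighted mean of per-class F1 over classes present in y_true or y_pred.

    A class with no true and no predicted members contributes F1 = 0 only if
    it is within ``n_classes`` and appears in neither — such classes are
    skipped, matching the common 'macro over observed labels' convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = _confusion(y_true, y_pred, n_classes)
    present = (cm.sum(axis=1) + cm.sum(axis=0)) > 0
    f1s = []
    for c in range(n_classes):
        if not present[c]:
            continue
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s)) if f1s else 0.0


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true)
    return float(np.mean(y_true == np.asarray(y_pred)))


@dataclass
class CvReport:
    level: str
    fold_macro_f1: list[float]
    fold_accuracy: list[float]
    seed: int

    @property
    def mean_macro_f1(self) -> float:
        return float(np.mean(self.fold_macro_f1))

    @property
    def sd_macro_f1(self) -> float:
        return float(np.std(self.fold_macro_f1, ddof=1))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1))

    def summary(self) -> str:
        return (
            f"{self.level}: macro-F1 {self.mean_macro_f1:.3f} ± {self.sd_macro_f1:.3f}, "
            f"accuracy {self.mean_accuracy:.3f} ± {self.sd_accuracy:.3f} "
            f"({len(self.fold_macro_f1)} folds, seed {self.seed})"
        )


@dataclass
class LevelModel:
    """A trained classifier for one hierarchy level."""

    level: str
    label_set: tuple[str, ...]
    network: GinNetwork
    vocab: FeatureVocab

    def predict_proba(self, graphs: Sequence[MoleculeGraph]) -> np.ndarray:
        batch = featurize_batch(graphs, self.vocab, warn_oov=False)
        return self.network.predict_proba(batch)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.network.save(directory)
        (directory / "labels.json").write_text(
            json.dumps({"level": self.level, "label_set": list(self.label_set)})
        )
        (directory / "vocab.json").write_text(self.vocab.to_json())

    @classmethod
    def load(cls, directory: str | Path) -> "LevelModel":
        directory = Path(directory)
        meta = json.loads((directory / "labels.json").read_text())
        return cls(
            level=meta["level"],
            label_set=tuple(meta["label_set"]),
            network=GinNetwork.load(directory),
            vocab=FeatureVocab.from_json((directory / "vocab.json").read_text()),
        )


def merge_rare_classes(
    labels: Sequence[str],
    parent_labels: Sequence[str],
    min_count: int = 10,
) -> list[str]:
    """Merge classes with < min_count examples into a per-parent 'other' bucket.

    Keeps stratified 10-fold CV meaningful at class level, where scaffold
    diversity produces long label tails.
    """
    counts = Counter(labels)
    return [
        lab if counts[lab] >= min_count else f"other ({parent})"
        for lab, parent in zip(labels, parent_labels)
    ]


def train_level_model(
    graphs: Sequence[MoleculeGraph],
    labels: Sequence[str],
    level: str,
    vocab: FeatureVocab | None = None,
    config: GinConfig | None = None,
    seed: int = 0,
    n_folds: int = 10,
    run_cv: bool = True,
) -> tuple[LevelModel, CvReport]:
    """Cross-validate and fit one per-level GIN.

    Deterministic given (graphs, labels, config, seed): the seed drives fold
    assignment, weight initialization and dropout.  The returned model is
    refit on the full data set after CV.
    """
    if len(graphs) != len(labels):
        raise ValueError("graphs and labels must align")
    label_set = tuple(sorted(set(labels)))
    if len(label_set) < 2:
        raise ValueError(
            f"level {level!r} has a single label {label_set}; classification is vacuous"
        )
    config = config or GinConfig()
    if vocab is None:
        vocab = FeatureVocab.fit(graphs)
    y = np.array([label_set.index(lab) for lab in labels])
    batch_all = featurize_batch(graphs, vocab, warn_oov=False)

    fold_f1: list[float] = []
    fold_acc: list[float] = []
    if run_cv:
        folds = stratified_folds(labels, n_folds, seed)
        for fi, test_idx in enumerate(folds):
            test_mask = np.zeros(len(graphs), dtype=bool)
            test_mask[test_idx] = True
            train_graphs = [g for g, m in zip(graphs, test_mask) if not m]
            net = GinNetwork(config, vocab.node_dim, vocab.edge_dim, len(label_set))
            net.fit(featurize_batch(train_graphs, vocab, warn_oov=False),
                    y[~test_mask], seed=seed * 1000 + fi)
            test_graphs = [g for g, m in zip(graphs, test_mask) if m]
            pred = net.predict_proba(
                featurize_batch(test_graphs, vocab, warn_oov=False)
            ).argmax(axis=1)
            fold_f1.append(macro_f1(y[test_mask], pred, len(label_set)))
            fold_acc.append(accuracy(y[test_mask], pred))

    final = GinNetwork(config, vocab.node_dim, vocab.edge_dim, len(label_set))
    final.fit(batch_all, y, seed=seed)
    model = LevelModel(level=level, label_set=label_set, network=final, vocab=vocab)
    report = CvReport(level=level, fold_macro_f1=fold_f1, fold_accuracy=fold_acc, seed=seed)
    return model, report


@dataclass
class ClassPrediction:
    """Hierarchical assignment for one molecule with per-level confidence."""

    name: str
    labels: dict[str, str]
    confidences: dict[str, float]
    consistent: bool
    distributions: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def min_confidence(self) -> float:
        return min(self.confidences.values())


@dataclass
class HierarchyClassifier:
    """Bundle of per-level models sharing one feature vocabulary."""

    models: Mapping[str, LevelModel]
    ontology: Ontology | None = None
    strict: bool = False

    def predict(self, graphs: Sequence[MoleculeGraph]) -> list[ClassPrediction]:
        probs = {lvl: self.models[lvl].predict_proba(graphs) for lvl in self.models}
        out = []
        for i, g in enumerate(graphs):
            out.append(self._decode(g.name, {lvl: probs[lvl][i] for lvl in probs}))
        return out

    def _decode(self, name: str, dist: dict[str, np.ndarray]) -> ClassPrediction:
        labels: dict[str, str] = {}
        confs: dict[str, float] = {}
        for lvl in LEVELS:
            if lvl not in self.models:
                continue
            p = dist[lvl].copy()
            if (
                self.strict
                and lvl == "class"
                and self.ontology is not None
                and "superclass" in labels
            ):
                mask = np.array(
                    [
                        self.ontology.class_parent.get(lab) == labels["superclass"]
                        for lab in self.models[lvl].label_set
                    ]
                )
                if mask.any():
                    p = np.where(mask, p, 0.0)
                    p = p / p.sum()
            # argmax with ties broken by label order (argmax returns first max)
            idx = int(np.argmax(p))
            labels[lvl] = self.models[lvl].label_set[idx]
            confs[lvl] = float(p[idx])
            dist[lvl] = p
        consistent = True
        if self.ontology is not None and set(LEVELS) <= set(labels):
            consistent = self.ontology.is_consistent(
                labels["pathway"], labels["superclass"], labels["class"]
            )
        return ClassPrediction(
            name=name, labels=labels, confidences=confs,
            consistent=consistent, distributions=dist,
        )


def predict_hierarchy(
    models: Mapping[str, LevelModel],
    graph: MoleculeGraph,
    ontology: Ontology | None = None,
    strict: bool = False,
) -> ClassPrediction:
    """Classify one molecule at every available level."""
    return HierarchyClassifier(models, ontology, strict).predict([graph])[0]


def flag_low_confidence(
    predictions: Sequence[ClassPrediction], threshold: float
) -> list[ClassPrediction]:
    """Curation queue: predictions needing expert review.

    A prediction is flagged when its weakest per-level confidence falls below
    ``threshold`` or its labels are hierarchically inconsistent; the queue is
    sorted ascending by that weakest confidence (most doubtful first).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    flagged = [
        p for p in predictions if p.min_confidence < threshold or not p.consistent
    ]
    return sorted(flagged, key=lambda p: p.min_confidence)
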