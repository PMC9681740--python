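"""Training protocol, evaluation metrics, experiment grid, cross-validation.

Metrics follow the standard confusion-matrix definitions:

    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Multi-class experiments report accuracy (per-class one-vs-rest scores are
emitted as supplementary columns); binary experiments additionally report
precision/recall/F1 for a stated positive class — by convention the
second-listed class of the experiment (configurable, always recorded).

An experiment trains per protocol (augmented train/val, untouched test),
then evaluates the best-validation-accuracy checkpoint on the held-out
test split. Cross-validation uses stratified k-fold with shuffling;
augmentation is applied to each fold's training portion only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .bodymap import BodyMapRegistry
from .estimators import (
    MultiModalWoundClassifier,
    WoundImageClassifier,
    WoundLocationClassifier,
)
from .pipeline import (
    DatasetManifest,
    ManifestError,
    SplitAssignment,
    WoundClass,
    augment_records,
    pair_modalities,
    split_records,
    subset_classes,
)
from .training import TrainingConfig, TrainingDiverged, train  # noqa: F401  (re-exported)

__all__ = [
    "CVReport",
    "ConfusionMatrix",
    "ExperimentResult",
    "ExperimentSpec",
    "MetricsReport",
    "TrainingConfig",
    "accuracy",
    "confusion",
    "cross_validate",
    "external_validate",
    "f1_score",
    "precision",
    "recall",
    "run_experiment",
    "train",
    "write_cv_report",
    "write_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix; ``matrix[i, j]`` counts true class i predicted j."""

    matrix: np.ndarray
    labels: tuple

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    def _pos(self, positive) -> int:
        try:
            return self.labels.index(positive)
        except ValueError:
            raise ValueError(f"positive label {positive!r} not among {self.labels}") from None

    def binary_counts(self, positive=None) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) treating ``positive`` one-vs-rest."""
        p = self._pos(positive) if positive is not None else len(self.labels) - 1
        m = self.matrix
        tp = int(m[p, p])
        fp = int(m[:, p].sum() - tp)
        fn = int(m[p, :].sum() - tp)
        tn = int(m.sum() - tp - fp - fn)
        return tp, tn, fp, fn


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Tally a confusion matrix; label set defaults to the sorted union."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true.tolist(), y_pred.tolist()):
        if t not in index or p not in index:
            raise ValueError(f"label outside the declared set: {t!r} / {p!r}")
        m[index[t], index[p]] += 1
    return ConfusionMatrix(m, labels)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.n == 0:
        return 0.0
    return float(np.trace(cm.matrix)) / cm.n


def precision(cm: ConfusionMatrix, positive=None) -> float:
    tp, _tn, fp, _fn = cm.binary_counts(positive)
    return tp / (tp + fp) if (tp + fp) > 0 else 0.0


def recall(cm: ConfusionMatrix, positive=None) -> float:
    tp, _tn, _fp, fn = cm.binary_counts(positive)
    return tp / (tp + fn) if (tp + fn) > 0 else 0.0


def f1_score(cm_or_precision, cm_recall=None, positive=None) -> float:
    """F1 from a confusion matrix, or directly from (precision, recall)."""
    if isinstance(cm_or_precision, ConfusionMatrix):
        p = precision(cm_or_precision, positive)
        r = recall(cm_or_precision, positive)
    else:
        p, r = float(cm_or_precision), float(cm_recall)
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


@dataclass(frozen=True)
class MetricsReport:
    """Evaluation summary of one experiment on its held-out set."""

    accuracy: float
    n_eval: int
    confusion_matrix: ConfusionMatrix
    positive_class: object = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    per_class: dict = field(default_factory=dict)
    degenerate: bool = False  # any zero denominator encountered

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None, positive=None) -> "MetricsReport":
        cm = confusion(y_true, y_pred, labels)
        per_class = {}
        for lab in cm.labels:
            per_class[lab] = {
                "precision": precision(cm, lab),
                "recall": recall(cm, lab),
                "f1": f1_score(cm, positive=lab),
            }
        degenerate = False
        p = r = f = None
        if len(cm.labels) == 2:
            pos = positive if positive is not None else cm.labels[-1]
            tp, _tn, fp, fn = cm.binary_counts(pos)
            degenerate = (tp + fp) == 0 or (tp + fn) == 0
            p = precision(cm, pos)
            r = recall(cm, pos)
            f = f1_score(cm, positive=pos)
            positive = pos
        return cls(
            accuracy=accuracy(cm),
            n_eval=cm.n,
            confusion_matrix=cm,
            positive_class=positive,
            precision=p,
            recall=r,
            f1=f,
            per_class=per_class,
            degenerate=degenerate,
        )


@dataclass(frozen=True)
class ExperimentSpec:
    """One cell of the experiment grid: class subset x modality x model combo."""

    classes: tuple
    modality: str  # location | image | multimodal
    backbone: str = "tinytest"
    wlc_kind: str = "mlp"
    fusion: str = "features"
    image_size: int | None = None
    positive_class: WoundClass | None = None
    dataset: str = ""

    def __post_init__(self) -> None:
        classes = tuple(
            WoundClass.parse(c) if not isinstance(c, WoundClass) else c for c in self.classes
        )
        object.__setattr__(self, "classes", classes)
        if len(classes) < 2:
            raise ValueError("an experiment needs at least two classes")
        if self.modality not in ("location", "image", "multimodal"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.positive_class is None and len(classes) == 2:
            # convention: the second-listed class of a binary experiment
            object.__setattr__(self, "positive_class", classes[1])

    @property
    def name(self) -> str:
        return "-".join(c.value for c in self.classes)

    @property
    def model_name(self) -> str:
        if self.modality == "location":
            return self.wlc_kind.upper()
        if self.modality == "image":
            return self.backbone.upper()
        return f"{self.backbone.upper()} + {self.wlc_kind.upper()}"


def _make_estimator(spec: ExperimentSpec, training: TrainingConfig, seed: int):
    common = dict(
        epochs=training.epochs,
        batch_size=training.batch_size,
        learning_rate=training.learning_rate,
        combined_policy=training.combined_policy,
        seed=seed,
    )
    if spec.modality == "location":
        return WoundLocationClassifier(kind=spec.wlc_kind, **common)
    if spec.modality == "image":
        return WoundImageClassifier(backbone=spec.backbone, input_size=spec.image_size, **common)
    return MultiModalWoundClassifier(
        backbone=spec.backbone,
        wlc_kind=spec.wlc_kind,
        fusion=spec.fusion,
        input_size=spec.image_size,
        **common,
    )


def _modality_X(spec: ExperimentSpec, paired):
    if spec.modality == "location":
        return paired.locations
    if spec.modality == "image":
        return paired.images
    return (paired.images, paired.locations)


@dataclass(frozen=True)
class ExperimentResult:
    experiment: str
    model: str
    metrics: MetricsReport


def run_experiment(
    spec: ExperimentSpec,
    manifest: DatasetManifest,
    registry: BodyMapRegistry,
    training: TrainingConfig | None = None,
    split: SplitAssignment | None = None,
    augment: bool = True,
    permute_locations: bool = False,
) -> ExperimentResult:
    """Run one grid cell end to end on an unsplit manifest of originals.

    Subsets classes, draws the stratified 60/15/25 split (test first),
    augments train/val, pairs modalities by record index, trains per
    protocol, and evaluates the best-validation checkpoint on the test
    originals. ``permute_locations`` deliberately shuffles location vectors
    against images in the training data (an alignment ablation); the
    pairing contract itself is untouched.
    """
    training = training or TrainingConfig()
    split = split or SplitAssignment()
    sub, label_map = subset_classes(manifest, spec.classes)
    originals = sub.originals()
    statuses = {r.split for r in originals}
    if statuses == {"unassigned"}:
        assigned = split_records(originals, split)
    elif "unassigned" not in statuses:
        assigned = originals  # honour a pre-assigned split
    else:
        raise ManifestError("manifest mixes assigned and unassigned records")
    assigned_manifest = DatasetManifest(
        name=sub.name, records=assigned, registry_version=sub.registry_version, root=sub.root
    )
    work = augment_records(assigned_manifest) if augment else assigned_manifest
    trainval = [r for r in work.records if r.split in ("train", "val")]
    test = [r for r in work.records if r.split == "test"]
    tr_recs = [r for r in trainval if r.split == "train"]
    va_recs = [r for r in trainval if r.split == "val"]
    paired_tr = pair_modalities(work, registry, tr_recs, spec.image_size, label_map)
    paired_va = pair_modalities(work, registry, va_recs, spec.image_size, label_map)
    paired_te = pair_modalities(work, registry, test, spec.image_size, label_map)
    if permute_locations:
        rng = np.random.default_rng(training.seed + 1)
        paired_tr.locations = paired_tr.locations[rng.permutation(len(paired_tr))]
        paired_va.locations = paired_va.locations[rng.permutation(len(paired_va))]
    est = _make_estimator(spec, training, training.seed)
    est.fit(
        _modality_X(spec, paired_tr),
        paired_tr.labels,
        X_val=_modality_X(spec, paired_va),
        y_val=paired_va.labels,
    )
    y_pred = est.predict(_modality_X(spec, paired_te))
    labels = [label_map[c] for c in sorted(label_map, key=lambda c: c.value)]
    pos = label_map[spec.positive_class] if spec.positive_class is not None else None
    report = MetricsReport.from_predictions(paired_te.labels, y_pred, labels, pos)
    return ExperimentResult(spec.name, spec.model_name, report)


@dataclass(frozen=True)
class CVReport:
    """Per-fold accuracies of a stratified k-fold run plus their mean."""

    fold_accuracies: tuple[float, ...]
    fold_plans: tuple[tuple[int, ...], ...]  # test record indexes per fold

    @property
    def k(self) -> int:
        return len(self.fold_accuracies)

    @property
    def average(self) -> float:
        return float(np.mean(self.fold_accuracies))


def cross_validate(
    spec: ExperimentSpec,
    manifest: DatasetManifest,
    registry: BodyMapRegistry,
    k: int = 5,
    seed: int = 0,
    training: TrainingConfig | None = None,
    augment: bool = True,
) -> CVReport:
    """Stratified k-fold over the original (un-augmented) records.

    Folds partition the originals; each fold's training portion is
    augmented, the held-out portion is evaluated untouched.
    """
    training = training or TrainingConfig(seed=seed)
    sub, label_map = subset_classes(manifest, spec.classes)
    originals = sub.originals()
    y = np.array([label_map[r.wound_class] for r in originals])
    counts = np.bincount(y)
    if (counts < k).any():
        small = [c.value for c, i in label_map.items() if counts[i] < k]
        raise ValueError(f"classes with fewer than k={k} records: {small}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    plans = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        te_set = set(te_idx.tolist())
        records = [
            replace(rec, split="test" if pos in te_set else "train")
            for pos, rec in enumerate(originals)
        ]
        fold_manifest = DatasetManifest(
            name=f"{sub.name}-fold{fold}",
            records=records,
            registry_version=sub.registry_version,
            root=sub.root,
        )
        work = augment_records(fold_manifest) if augment else fold_manifest
        tr = [r for r in work.records if r.split == "train"]
        te = [r for r in work.records if r.split == "test"]
        paired_tr = pair_modalities(work, registry, tr, spec.image_size, label_map)
        paired_te = pair_modalities(work, registry, te, spec.image_size, label_map)
        est = _make_estimator(spec, training, training.seed + fold)
        est.fit(_modality_X(spec, paired_tr), paired_tr.labels)
        y_pred = est.predict(_modality_X(spec, paired_te))
        accs.append(float(np.mean(y_pred == paired_te.labels)))
        plans.append(tuple(int(originals[i].index) for i in te_idx))
    return CVReport(tuple(accs), tuple(plans))


def external_validate(
    estimator,
    label_map: dict[WoundClass, int],
    manifest_b: DatasetManifest,
    registry: BodyMapRegistry,
    image_size: int | None = None,
) -> MetricsReport:
    """Evaluate a model trained on dataset A on dataset B's common classes.

    Only classes present in both label spaces are scored; B's labels are
    translated into A's integer label map, so predictions land in a shared
    space. Disjoint class sets are an error.
    """
    classes_b = set(manifest_b.classes)
    common = sorted(set(label_map) & classes_b, key=lambda c: c.value)
    if not common:
        raise ValueError(
            f"no common classes between the model ({sorted(c.value for c in label_map)}) "
            f"and dataset ({sorted(c.value for c in classes_b)})"
        )
    records = [r for r in manifest_b.originals() if r.wound_class in common]
    paired = pair_modalities(manifest_b, registry, records, image_size, label_map)
    if isinstance(estimator, MultiModalWoundClassifier):
        X = (paired.images, paired.locations)
    elif isinstance(estimator, WoundLocationClassifier):
        X = paired.locations
    else:
        X = paired.images
    y_pred = estimator.predict(X)
    labels = sorted(set(paired.labels.tolist()) | set(np.asarray(y_pred).tolist()))
    pos = label_map[common[-1]] if len(common) == 2 else None
    return MetricsReport.from_predictions(paired.labels, y_pred, labels, pos)


def write_report(results: list[ExperimentResult], out_dir: str | Path) -> dict[str, Path]:
    """Write the experiment grid as CSV + Markdown (accuracy %, best flagged)."""
    if not results:
        raise ValueError("no experiment results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [(r.model, r.experiment, 100.0 * r.metrics.accuracy) for r in results],
        columns=["model", "experiment", "accuracy_pct"],
    )
    table = df.pivot_table(index="model", columns="experiment", values="accuracy_pct")
    csv_path = out_dir / "results.csv"
    table.to_csv(csv_path, float_format="%.2f")
    lines = ["| Model | " + " | ".join(table.columns) + " |"]
    lines.append("|" + "---|" * (len(table.columns) + 1))
    best = table.max(axis=0)
    for model, row in table.iterrows():
        cells = []
        for col in table.columns:
            v = row[col]
            cell = "" if pd.isna(v) else f"{v:.2f}"
            if not pd.isna(v) and np.isclose(v, best[col]):
                cell = f"**{cell}**"
            cells.append(cell)
        lines.append(f"| {model} | " + " | ".join(cells) + " |")
    md_path = out_dir / "results.md"
    md_path.write_text("\n".join(lines) + "\n")
    return {"csv": csv_path, "markdown": md_path}


def write_cv_report(
    cv_results: list[tuple[str, str, CVReport]], out_dir: str | Path
) -> dict[str, Path]:
    """Write cross-validation tables: one row per (experiment, model),
    fold columns plus the average."""
    if not cv_results:
        raise ValueError("no cross-validation results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    k = cv_results[0][2].k
    cols = [f"Fold{i + 1}" for i in range(k)] + ["Average"]
    rows = []
    for experiment, model, report in cv_results:
        rows.append(
            [experiment, model]
            + [100.0 * a for a in report.fold_accuracies]
            + [100.0 * report.average]
        )
    df = pd.DataFrame(rows, columns=["experiment", "model"] + cols)
    csv_path = out_dir / "cv_results.csv"
    df.to_csv(csv_path, index=False, float_format="%.2f")
    lines = ["| " + " | ".join(df.columns) + " |", "|" + "---|" * len(df.columns)]
    for _, row in df.iterrows():
        cells = [
            f"{v:.2f}" if isinstance(v, float) else str(v) for v in row.tolist()
        ]
        lines.append("| " + " | ".join(cells) + " |")
    md_path = out_dir / "cv_results.md"
    md_path.write_text("\n".join(lines) + "\n")
    return {"csv": csv_path, "markdown": md_path}
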