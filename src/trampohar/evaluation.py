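"""Leave-one-subject-out evaluation, confusion-matrix metrics, label merging
and the four personalization schemes.

Evaluation follows the wearable-HAR convention that generalization must be
measured across people: leave-one-subject-out cross-validation (LOSO-CV)
trains on all subjects but one and tests on the held-out subject, rotating
through every subject.  The headline number is the unweighted mean of the
per-subject accuracies (which can differ from pooled accuracy when subjects
contribute different window counts; reports carry both).

Confusion matrices use rows = predicted class, columns = correct class.
Precision of class c is the correctly-predicted fraction of row c, recall the
correctly-predicted fraction of column c, and the F-measure their harmonic
mean; all are reported in percent.

Personalization assumes a deployed model meeting a new user from whom a few
recording sets are available for adaptation:

* ``None`` — the base model, untouched;
* ``FT`` — all weights fine-tuned on the user's adaptation sets;
* ``FT-Classifier`` — only the softmax layer fine-tuned (extractor frozen);
* ``Mixin`` — retrained from scratch on the other subjects' data pooled with
  the user's adaptation sets.

By default the first three sets (by set index) adapt and the remaining sets
evaluate; ``rotate_sets`` averages over every 3-of-5 choice instead.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .features import FeatureConfig, extract_table
from .models import FittedModel, ModelSpec, TrainConfig, build, train, train_rf
from .signal_core import (
    LABEL_ORDER,
    MotionLabel,
    Recording,
    Window,
    WindowingConfig,
    segment_all,
)

logger = logging.getLogger("trampohar")

__all__ = [
    "ConfusionMatrix", "ClassMetrics", "EvalReport", "PersonalizationScheme",
    "round_half_up", "metrics", "merge_labels", "loso_split", "run_loso",
    "personalize", "render_table",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding, for printed-style percentage rendering."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# confusion matrices and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Integer count matrix, rows = predicted, columns = correct."""

    counts: np.ndarray
    labels: tuple[str, ...] = tuple(l.code for l in LABEL_ORDER)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_predictions(
        cls,
        y_pred: np.ndarray,
        y_true: np.ndarray,
        labels: tuple[str, ...] = tuple(l.code for l in LABEL_ORDER),
    ) -> "ConfusionMatrix":
        k = len(labels)
        counts = np.zeros((k, k), dtype=np.int64)
        np.add.at(counts, (np.asarray(y_pred), np.asarray(y_true)), 1)
        return cls(counts, labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy_pct(self) -> float:
        return 100.0 * np.trace(self.counts) / self.total

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F (percent) plus overall accuracy."""

    labels: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f_measure: dict[str, float]
    accuracy: float


def metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Precision, recall, F-measure per class and overall accuracy, in %.

    A zero row or column sum yields 0 for the affected metric (warned); an
    all-zero matrix is an error.
    """
    c = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(c).astype(float)
    rows = c.sum(axis=1).astype(float)
    cols = c.sum(axis=0).astype(float)
    if (rows == 0).any() or (cols == 0).any():
        logger.warning("zero row/column sums in confusion matrix; metrics imputed 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(rows > 0, diag / np.where(rows > 0, rows, 1), 0.0) * 100
        rec = np.where(cols > 0, diag / np.where(cols > 0, cols, 1), 0.0) * 100
        s = prec + rec
        f = np.where(s > 0, 2 * prec * rec / np.where(s > 0, s, 1), 0.0)
    return ClassMetrics(
        labels=cm.labels,
        precision=dict(zip(cm.labels, prec)),
        recall=dict(zip(cm.labels, rec)),
        f_measure=dict(zip(cm.labels, f)),
        accuracy=cm.accuracy_pct(),
    )


def merge_labels(
    cm: ConfusionMatrix, groups: Sequence[Sequence[str | MotionLabel]]
) -> ConfusionMatrix:
    """Merge classes by summing rows and columns over each group.

    ``groups`` must partition the matrix's labels; the total count is
    conserved, and diagonal mass can only grow (within-group confusions
    become correct), so pooled accuracy never decreases.
    """
    codes = [
        tuple(g.code if isinstance(g, MotionLabel) else str(g) for g in group)
        for group in groups
    ]
    flat = [c for g in codes for c in g]
    if sorted(flat) != sorted(cm.labels):
        raise ValueError("groups must form a partition of the matrix labels")
    idx = [[cm.labels.index(c) for c in g] for g in codes]
    k = len(codes)
    merged = np.zeros((k, k), dtype=np.int64)
    for a, ia in enumerate(idx):
        for b, ib in enumerate(idx):
            merged[a, b] = cm.counts[np.ix_(ia, ib)].sum()
    return ConfusionMatrix(merged, tuple("+".join(g) for g in codes))


def render_table(cm: ConfusionMatrix) -> str:
    """Text confusion table: predicted rows, correct columns, a trailing
    precision column and bottom recall / F-measure rows."""
    m = metrics(cm)
    w = max(6, max(len(l) for l in cm.labels) + 1)
    head = "Pre.\\Cor.".ljust(10) + "".join(l.rjust(w) for l in cm.labels)
    lines = [head + "Precision [%]".rjust(15)]
    for i, l in enumerate(cm.labels):
        row = l.ljust(10) + "".join(str(c).rjust(w) for c in cm.counts[i])
        lines.append(row + f"{round_half_up(m.precision[l]):.1f}".rjust(15))
    lines.append(
        "Recall [%]".ljust(10)
        + "".join(f"{round_half_up(m.recall[l]):.1f}".rjust(w) for l in cm.labels)
        + f"{round_half_up(m.accuracy):.1f}".rjust(15)
    )
    lines.append(
        "F [%]".ljust(10)
        + "".join(f"{round_half_up(m.f_measure[l]):.1f}".rjust(w) for l in cm.labels)
    )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# LOSO-CV
# ---------------------------------------------------------------------------


def _subjects_of(data: Iterable) -> list[str]:
    seen: dict[str, None] = {}
    for item in data:
        seen.setdefault(item.subject_id, None)
    return list(seen)


def loso_split(data: Iterable) -> list[tuple[list[str], str]]:
    """One fold per subject: (training subjects, held-out subject).

    ``data`` is anything whose items carry ``subject_id`` (manifest entries,
    recordings, windows).
    """
    subjects = _subjects_of(data)
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    return [([s for s in subjects if s != t], t) for t in subjects]


@dataclass
class EvalReport:
    """Per-subject confusion matrices plus the two accuracy summaries."""

    per_subject: dict[str, ConfusionMatrix]
    model_name: str = ""

    def subject_accuracy(self, subject_id: str) -> float:
        return self.per_subject[subject_id].accuracy_pct()

    @property
    def avg_accuracy(self) -> float:
        """Unweighted mean of per-subject accuracies (the headline number)."""
        return float(
            np.mean([cm.accuracy_pct() for cm in self.per_subject.values()])
        )

    @property
    def pooled(self) -> ConfusionMatrix:
        cms = list(self.per_subject.values())
        out = cms[0]
        for cm in cms[1:]:
            out = out + cm
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "avg_accuracy_pct": self.avg_accuracy,
            "pooled_accuracy_pct": self.pooled.accuracy_pct(),
            "label_order": list(next(iter(self.per_subject.values())).labels),
            "per_subject": {
                s: {
                    "accuracy_pct": cm.accuracy_pct(),
                    "confusion": cm.counts.tolist(),
                }
                for s, cm in self.per_subject.items()
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _group_windows(windows: Sequence[Window]) -> dict[str, list[Window]]:
    out: dict[str, list[Window]] = {}
    for w in windows:
        out.setdefault(w.subject_id, []).append(w)
    return out


def run_loso(
    recordings: Sequence[Recording],
    model_kind: str = "ours",
    windowing: WindowingConfig = WindowingConfig(),
    config: TrainConfig = TrainConfig(),
    feature_config: FeatureConfig | None = None,
    rf_estimators: int = 300,
) -> EvalReport:
    """Full LOSO-CV of one model kind over a recording set.

    ``model_kind`` is ``ours | vgg16fc | simple | depth:<k>`` (CNNs on
    flattened windows) or ``rf`` (Random Forest on hand-crafted features).
    Per-fold seeds are derived from ``config.seed`` + fold index and logged.
    """
    windows = segment_all(recordings, windowing)
    by_subject = _group_windows(windows)
    folds = loso_split(windows)
    use_rf = model_kind == "rf"
    if use_rf:
        fc = feature_config or FeatureConfig(rate_hz=recordings[0].sample_rate_hz)
        table = extract_table(windows, fc)
    per_subject: dict[str, ConfusionMatrix] = {}
    for fold, (train_subjects, test_subject) in enumerate(folds):
        fold_seed = config.seed + fold
        logger.info("LOSO fold %d: test subject %s (seed %d)", fold, test_subject, fold_seed)
        test_windows = by_subject[test_subject]
        y_true = np.array([w.label.index for w in test_windows])
        if use_rf:
            tr = table[table.subject_id != test_subject]
            te = table[table.subject_id == test_subject]
            forest = train_rf(tr, seed=fold_seed, n_estimators=rf_estimators)
            y_pred = forest.predict(te)
        else:
            train_windows = [w for s in train_subjects for w in by_subject[s]]
            model = train(
                build(model_kind), train_windows, replace(config, seed=fold_seed)
            )
            y_pred = model.predict(test_windows)
        per_subject[test_subject] = ConfusionMatrix.from_predictions(y_pred, y_true)
    return EvalReport(per_subject=per_subject, model_name=model_kind)


# ---------------------------------------------------------------------------
# personalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PersonalizationScheme:
    """How (or whether) a base model adapts to a new user's sets."""

    name: str            # None | FT | FT-Classifier | Mixin
    n_user_sets: int = 3

    _KNOWN = ("None", "FT", "FT-Classifier", "Mixin")

    def __post_init__(self) -> None:
        if self.name not in self._KNOWN:
            raise ValueError(f"unknown scheme {self.name!r}; expected one of {self._KNOWN}")


@dataclass
class PersonalizationResult:
    scheme: PersonalizationScheme
    subject_id: str
    model: FittedModel
    cm: ConfusionMatrix

    @property
    def accuracy_pct(self) -> float:
        return self.cm.accuracy_pct()


def _split_user_sets(
    user_windows: Sequence[Window], adapt_sets: Sequence[int]
) -> tuple[list[Window], list[Window]]:
    adapt = [w for w in user_windows if w.set_index in adapt_sets]
    heldout = [w for w in user_windows if w.set_index not in adapt_sets]
    if not adapt or not heldout:
        raise ValueError(
            "the user needs both adaptation sets and at least one held-out set"
        )
    return adapt, heldout


def personalize(
    recordings: Sequence[Recording],
    subject_id: str,
    scheme: PersonalizationScheme,
    base_model: FittedModel | None = None,
    model_kind: str = "ours",
    windowing: WindowingConfig = WindowingConfig(),
    config: TrainConfig = TrainConfig(),
    ft_config: TrainConfig | None = None,
    rotate_sets: bool = False,
) -> PersonalizationResult | list[PersonalizationResult]:
    """Adapt a model to one subject and evaluate on that subject's held-out sets.

    The subject's first ``scheme.n_user_sets`` sets (by set index) adapt the
    model and the remaining sets evaluate it; ``rotate_sets=True`` instead
    returns one result per possible adaptation-set choice.  Fine-tuning uses
    ``ft_config`` (default: the base config with epochs reduced to 20, a small
    adaptation set needs fewer passes); ``Mixin`` retrains from scratch with
    the full config.  ``None`` returns the base model untouched, so its
    predictions are identical to the base model's.
    """
    windows = segment_all(recordings, windowing)
    by_subject = _group_windows(windows)
    if subject_id not in by_subject:
        raise ValueError(f"unknown subject {subject_id!r}")
    user_windows = by_subject[subject_id]
    other_windows = [w for s, ws in by_subject.items() if s != subject_id for w in ws]
    user_sets = sorted({w.set_index for w in user_windows})
    if len(user_sets) < scheme.n_user_sets + 1:
        raise ValueError(
            f"subject {subject_id} has {len(user_sets)} sets; scheme needs "
            f">= {scheme.n_user_sets + 1}"
        )
    if ft_config is None:
        ft_config = replace(config, epochs=20)

    if base_model is None and scheme.name != "Mixin":
        base_model = train(build(model_kind), other_windows, config)

    def _one(adapt_sets: tuple[int, ...]) -> PersonalizationResult:
        adapt, heldout = _split_user_sets(user_windows, adapt_sets)
        if scheme.name == "None":
            model = base_model
        elif scheme.name == "FT":
            model = base_model.clone().continue_training(adapt, ft_config, "all")
        elif scheme.name == "FT-Classifier":
            model = base_model.clone().continue_training(adapt, ft_config, "head")
        else:  # Mixin
            model = train(build(model_kind), other_windows + adapt, config)
        y_true = np.array([w.label.index for w in heldout])
        cm = ConfusionMatrix.from_predictions(model.predict(heldout), y_true)
        return PersonalizationResult(scheme, subject_id, model, cm)

    if rotate_sets:
        return [
            _one(c) for c in itertools.combinations(user_sets, scheme.n_user_sets)
        ]
    return _one(tuple(user_sets[: scheme.n_user_sets]))
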