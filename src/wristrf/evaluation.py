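"""Stratified cross-validation, bilateral decision fusion, and screening metrics.

Subjects are dealt into K validation subsets (default 7) so that subset
sizes differ by at most one and each subset's class split stays within one
subject of exact 27:40-style proportionality. Each subset validates once
while the remaining K-1 train a fresh network. The partition is over
subjects: when the two arms of a subject are presented separately, both
arms always land in the same subset, so no subject leaks across the
train/validation boundary.

In separate-arm mode each arm yields its own prediction (its truth label
being the subject's group), tallied once as if every arm were its own
subject ("separate") and once per bilateral fusion scheme: agreement keeps
the shared label; a left/right conflict resolves to the left arm
(``keep_left``), the right arm (``keep_right``), the diseased class
(``keep_osteo``), or the healthy class (``keep_healthy``).

Reported metrics are fold means (not pooled counts) of sensitivity,
specificity, accuracy and Youden's J = sensitivity + specificity - 1, with
group 1 (osteopenic/osteoporotic) as the positive class. A fold whose
validation subset lacks positives (or negatives) leaves the affected
metric undefined; undefined values are excluded from the mean with a
warning rather than silently counted as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cohort import GROUP1, GROUP2, Cohort
from .features import FeatureRecipe, assemble
from .mlp import ClassifierConfig, MLPClassifier

__all__ = [
    "FUSION_SCHEMES",
    "FoldAssignment",
    "ConfusionCounts",
    "CVResult",
    "stratified_partition",
    "fuse_arm_predictions",
    "compute_metrics",
    "run_cv",
]

FUSION_SCHEMES = ("separate", "keep_left", "keep_right", "keep_osteo", "keep_healthy")
METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "youden_j")


@dataclass(frozen=True)
class FoldAssignment:
    """A partition of subjects into k validation subsets."""

    k: int
    membership: Mapping[str, int]  # subject_id -> subset index in 0..k-1
    seed: int

    def subset(self, index: int) -> list[str]:
        return sorted(sid for sid, j in self.membership.items() if j == index)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies with group 1 (diseased) as positive."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "ConfusionCounts":
        """Tally (predicted, truth) label pairs."""
        tp = fp = tn = fn = 0
        for pred, truth in pairs:
            if truth == GROUP1:
                tp, fn = (tp + 1, fn) if pred == GROUP1 else (tp, fn + 1)
            elif truth == GROUP2:
                tn, fp = (tn + 1, fp) if pred == GROUP2 else (tn, fp + 1)
            else:
                raise ValueError(f"unknown truth label {truth!r}")
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy and Youden's J from a tally.

    A metric whose denominator is empty (e.g. sensitivity with no
    positives) is returned as ``None`` — explicitly undefined, never 0.
    """
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sens = counts.tp / pos if pos > 0 else None
    spec = counts.tn / neg if neg > 0 else None
    acc = (counts.tp + counts.tn) / counts.total if counts.total > 0 else None
    youden = sens + spec - 1.0 if (sens is not None and spec is not None) else None
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc, "youden_j": youden}


# ---------------------------------------------------------------------------
# Stratified partition
# ---------------------------------------------------------------------------


def stratified_partition(labels: Mapping[str, str], k: int, seed: int = 0) -> FoldAssignment:
    """Deal subjects into k subsets, stratified by class.

    Within each class the subjects are shuffled by ``seed``; the first
    class is then dealt round-robin across subsets 0..k-1 and the second
    class round-robin in reverse order, so each class's remainder lands on
    opposite ends and total subset sizes differ by at most one.
    """
    ids = sorted(labels)
    n = len(ids)
    if k < 1 or k > n:
        raise ValueError(f"k={k} must be in 1..{n}")
    classes = sorted(set(labels.values()))
    if len(classes) < 2:
        raise ValueError("both classes must be present for a stratified partition")

    rng = np.random.default_rng(seed)
    membership: dict[str, int] = {}
    for c_idx, cls in enumerate(classes):
        members = [sid for sid in ids if labels[sid] == cls]
        rng.shuffle(members)
        order = range(k) if c_idx % 2 == 0 else range(k - 1, -1, -1)
        slots = list(order)
        for i, sid in enumerate(members):
            membership[sid] = slots[i % k]

    assignment = FoldAssignment(k=k, membership=membership, seed=seed)
    _check_partition(assignment, labels)
    return assignment


def _check_partition(assignment: FoldAssignment, labels: Mapping[str, str]) -> None:
    k = assignment.k
    sizes = np.zeros(k, dtype=int)
    per_class: dict[str, np.ndarray] = {}
    for sid, j in assignment.membership.items():
        sizes[j] += 1
        per_class.setdefault(labels[sid], np.zeros(k, dtype=int))[j] += 1
    if sizes.max() - sizes.min() > 1:
        raise AssertionError(f"subset sizes {sizes.tolist()} differ by more than 1")
    n = sizes.sum()
    for cls, counts in per_class.items():
        expected = counts.sum() * sizes / n
        if np.max(np.abs(counts - expected)) > 1.0 + 1e-9:
            raise AssertionError(
                f"class {cls!r} counts {counts.tolist()} deviate from proportionality"
            )


# ---------------------------------------------------------------------------
# Bilateral fusion
# ---------------------------------------------------------------------------


def fuse_arm_predictions(left_label: str, right_label: str, scheme: str) -> str:
    """Resolve two per-arm predictions into one subject-level diagnosis."""
    if scheme == "separate":
        raise ValueError("'separate' bypasses fusion; call sites tally arms directly")
    if scheme not in FUSION_SCHEMES:
        raise ValueError(f"unknown fusion scheme {scheme!r}")
    for lab in (left_label, right_label):
        if lab not in (GROUP1, GROUP2):
            raise ValueError(f"unknown label {lab!r}")
    if left_label == right_label:
        return left_label
    if scheme == "keep_left":
        return left_label
    if scheme == "keep_right":
        return right_label
    if scheme == "keep_osteo":
        return GROUP1
    return GROUP2  # keep_healthy


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Per-fold confusion counts and fold-mean metrics, per result block.

    Blocks are fusion schemes in separate-arm mode, or the single block
    ``"subject"`` when arms were averaged or concatenated upstream.
    """

    k: int
    seed: int
    recipe: FeatureRecipe
    fold_assignment: FoldAssignment
    per_scheme: dict[str, list[ConfusionCounts]]

    def fold_metrics(self, scheme: str) -> list[dict[str, float | None]]:
        return [compute_metrics(c) for c in self.per_scheme[scheme]]

    def mean_metrics(self, scheme: str) -> dict[str, float | None]:
        folds = self.fold_metrics(scheme)
        out: dict[str, float | None] = {}
        for name in METRIC_NAMES:
            vals = [f[name] for f in folds if f[name] is not None]
            if len(vals) < len(folds):
                warnings.warn(
                    f"{len(folds) - len(vals)} fold(s) had undefined {name}; "
                    "excluded from the mean",
                    stacklevel=2,
                )
            out[name] = float(np.mean(vals)) if vals else None
        return out

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "recipe": {
                "encoding": self.recipe.encoding,
                "arm_mode": self.recipe.arm_mode,
                "include_circumference": self.recipe.include_circumference,
                "normalize_eq1": self.recipe.normalize_eq1,
            },
            "folds": {sid: int(j) for sid, j in sorted(self.fold_assignment.membership.items())},
            "schemes": {
                scheme: {
                    "per_fold": [
                        {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
                        for c in counts
                    ],
                    "mean": self.mean_metrics(scheme),
                }
                for scheme, counts in self.per_scheme.items()
            },
        }


def run_cv(
    cohort: Cohort,
    recipe: FeatureRecipe,
    classifier_config: ClassifierConfig | None = None,
    k: int = 7,
    seed: int = 0,
    schemes: Sequence[str] | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline on a cohort.

    For each fold a fresh network is trained on the training subjects'
    feature vectors only and evaluated on the held-out subjects. In
    separate-arm mode both arms of each validation subject are predicted
    independently and tallied arm-level ("separate") and per fusion scheme;
    otherwise a single "subject" block is produced.

    ``classifier_config`` may be a template whose ``n_in`` is overridden by
    the recipe's actual feature length; per-fold training seeds derive from
    ``seed`` so the whole procedure is reproducible.
    """
    labels = cohort.labels()
    bad = sorted(sid for sid, g in labels.items() if g not in (GROUP1, GROUP2))
    if bad:
        raise ValueError(f"subjects with unknown group cannot be cross-validated: {bad}")

    assignment = stratified_partition(labels, k, seed)
    by_id = {s.subject_id: s for s in cohort}

    separate = recipe.arm_mode == "separate"
    if schemes is None:
        schemes = FUSION_SCHEMES if separate else ("subject",)
    elif not separate:
        schemes = ("subject",)

    per_scheme: dict[str, list[ConfusionCounts]] = {s: [] for s in schemes}

    for fold in range(k):
        val_ids = set(assignment.subset(fold))
        train_ids = [sid for sid in sorted(by_id) if sid not in val_ids]
        if val_ids & set(train_ids):
            raise AssertionError("subject appears in both training and validation")
        train_labels = {labels[sid] for sid in train_ids}
        if len(train_labels) < 2:
            raise ValueError(
                f"fold {fold}: training data contains a single class; re-seed the partition"
            )

        X_rows, y_rows = [], []
        for sid in train_ids:
            for fv in assemble(by_id[sid], recipe):
                X_rows.append(fv.values)
                y_rows.append(labels[sid])
        X_train = np.vstack(X_rows)

        n_in = X_train.shape[1]
        fold_seed = (seed * 1009 + fold) % (2**31)
        if classifier_config is None:
            config = ClassifierConfig(n_in=n_in, seed=fold_seed)
        else:
            config = replace(classifier_config, n_in=n_in, seed=fold_seed)
        model = MLPClassifier(config).fit(X_train, y_rows)

        arm_pairs: list[tuple[str, str]] = []  # (pred, truth) per arm
        subject_preds: dict[str, dict[str, str]] = {}
        for sid in sorted(val_ids):
            for fv in assemble(by_id[sid], recipe):
                pred, _ = model.predict(fv.values)
                arm_pairs.append((pred, labels[sid]))
                subject_preds.setdefault(sid, {})[fv.arm_tag] = pred

        for scheme in schemes:
            if scheme in ("separate", "subject"):
                per_scheme[scheme].append(ConfusionCounts.from_pairs(arm_pairs))
            else:
                fused = [
                    (fuse_arm_predictions(p["left"], p["right"], scheme), labels[sid])
                    for sid, p in sorted(subject_preds.items())
                ]
                per_scheme[scheme].append(ConfusionCounts.from_pairs(fused))

    return CVResult(
        k=k, seed=seed, recipe=recipe, fold_assignment=assignment, per_scheme=per_scheme
    )
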