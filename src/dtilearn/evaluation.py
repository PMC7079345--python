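"""Dataset assembly, splitting, metrics and cross-validation for DTI models.

The interaction network is bipartite (drugs x targets); every curated
interacting pair is a positive, and negatives are drawn uniformly at random
from the remaining pairs until class balance is reached.  Evaluation uses
accuracy, sensitivity (TPR), specificity, precision (PPV), the Matthews
correlation coefficient and ROC-AUC.  Splits follow the protocol: one tenth
of the pairs held out for testing, eight tenths of the remainder for
training, the rest for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "InteractionDataset",
    "DatasetSplit",
    "ConfusionCounts",
    "MetricsReport",
    "UNDEFINED",
    "balanced_negative_sampling",
    "split_dataset",
    "confusion_from_scores",
    "compute_metrics",
    "compute_auc",
    "evaluate_predictions",
    "cross_validate",
    "read_pairs_tsv",
    "write_pairs_tsv",
]

#: Marker for a metric whose denominator is zero (reported, never silently 0).
UNDEFINED = float("nan")


class SamplingError(ValueError):
    """Raised when the requested negative sample cannot be drawn."""


@dataclass
class InteractionDataset:
    """A bipartite drug-target network with labelled pairs."""

    drugs: list[str]
    targets: list[str]
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        drug_set, target_set = set(self.drugs), set(self.targets)
        pos, neg = set(self.positives), set(self.negatives)
        if pos & neg:
            raise ValueError("positives and negatives overlap")
        for d, t in list(pos) + list(neg):
            if d not in drug_set or t not in target_set:
                raise ValueError(f"pair ({d!r}, {t!r}) references unknown ids")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.positives) + list(self.negatives)

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positives) + [0] * len(self.negatives))


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive train/validation/test index sets."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in (self.train_idx, self.val_idx, self.test_idx)]
        object.__setattr__(self, "train_idx", parts[0])
        object.__setattr__(self, "val_idx", parts[1])
        object.__setattr__(self, "test_idx", parts[2])
        allv = np.concatenate(parts)
        if len(np.unique(allv)) != allv.size:
            raise ValueError("split parts are not disjoint")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """ACC / TPR / SPC / PPV / MCC (and optionally AUC) of one evaluation."""

    ACC: float
    TPR: float
    SPC: float
    PPV: float
    MCC: float
    AUC: float = UNDEFINED

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.ACC, "TPR": self.TPR, "SPC": self.SPC,
                "PPV": self.PPV, "MCC": self.MCC, "AUC": self.AUC}


def balanced_negative_sampling(dataset: InteractionDataset, seed: int = 0) -> InteractionDataset:
    """Draw |positives| negatives uniformly from the non-interacting pairs.

    Sampling is without replacement over (drugs x targets) \\ positives and
    reproducible given the seed.
    """
    pos = set(dataset.positives)
    candidates = [
        (d, t) for d in dataset.drugs for t in dataset.targets if (d, t) not in pos
    ]
    n_needed = len(dataset.positives)
    if len(candidates) < n_needed:
        raise SamplingError(
            f"need {n_needed} negatives but only {len(candidates)} "
            "non-interacting pairs exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_needed, replace=False)
    negatives = [candidates[i] for i in sorted(idx)]
    return InteractionDataset(
        drugs=list(dataset.drugs),
        targets=list(dataset.targets),
        positives=list(dataset.positives),
        negatives=negatives,
    )


def _allocate_counts(class_sizes: np.ndarray, n_take: int) -> np.ndarray:
    """Largest-remainder allocation of n_take draws across classes."""
    total = class_sizes.sum()
    exact = class_sizes * n_take / total
    base = np.floor(exact).astype(int)
    short = n_take - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return np.minimum(base, class_sizes)


def split_dataset(n: int, seed: int = 0, labels=None) -> DatasetSplit:
    """Seeded train/validation/test partition of n pairs.

    |test| = floor(0.10 n); |train| = floor(0.80 (n - |test|)); the rest is
    validation (0.72 / 0.18 / 0.10 overall).  When labels are given the
    assignment is stratified per class with largest-remainder rounding.
    """
    if n < 10:
        raise ValueError(f"need at least 10 pairs to split, got {n}")
    n_test = n // 10
    n_train = int(0.80 * (n - n_test))
    rng = np.random.default_rng(seed)

    if labels is None:
        labels = np.zeros(n, dtype=int)
    labels = np.asarray(labels).ravel()
    if labels.size != n:
        raise ValueError("labels length must equal n")

    classes, inv = np.unique(labels, return_inverse=True)
    class_sizes = np.bincount(inv)
    test_counts = _allocate_counts(class_sizes, n_test)
    train_counts = _allocate_counts(class_sizes - test_counts, n_train)

    train, val, test = [], [], []
    for ci in range(classes.size):
        members = np.where(inv == ci)[0]
        members = members[rng.permutation(members.size)]
        t_end = test_counts[ci]
        tr_end = t_end + train_counts[ci]
        test.append(members[:t_end])
        train.append(members[t_end:tr_end])
        val.append(members[tr_end:])
    return DatasetSplit(
        train_idx=np.sort(np.concatenate(train)),
        val_idx=np.sort(np.concatenate(val)),
        test_idx=np.sort(np.concatenate(test)),
    )


def confusion_from_scores(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int).ravel()
    pred = (np.asarray(scores, dtype=float).ravel() >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (labels == 1))),
        FP=int(np.sum((pred == 1) & (labels == 0))),
        TN=int(np.sum((pred == 0) & (labels == 0))),
        FN=int(np.sum((pred == 0) & (labels == 1))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """ACC, TPR, SPC, PPV and MCC from a confusion matrix.

    MCC uses the standard form (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)
    (TN+FP)); any metric with a zero denominator is reported as NaN rather
    than silently 0.
    """
    if counts.total == 0:
        raise ValueError("confusion counts are all zero")
    TP, FP, TN, FN = counts.TP, counts.FP, counts.TN, counts.FN
    mcc_den = math.sqrt(float(TP + FP) * (TN + FN) * (TP + FN) * (TN + FP))
    return MetricsReport(
        ACC=(TN + TP) / counts.total,
        TPR=_ratio(TP, FN + TP),
        SPC=_ratio(TN, TN + FP),
        PPV=_ratio(TP, TP + FP),
        MCC=(TP * TN - FP * FN) / mcc_den if mcc_den > 0 else UNDEFINED,
    )


def compute_auc(labels, scores) -> float:
    """Area under the ROC curve (trapezoidal / Mann-Whitney with midranks)."""
    labels = np.asarray(labels).astype(int).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float).ravel()))


def evaluate_predictions(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report (ACC/TPR/SPC/PPV/MCC/AUC) from scores and true labels."""
    report = compute_metrics(confusion_from_scores(labels, scores, threshold))
    report.AUC = compute_auc(labels, scores)
    return report


def cross_validate(make_model, X, y, k: int = 5, seed: int = 0,
                   threshold: float = 0.5) -> tuple[list[MetricsReport], MetricsReport]:
    """Seeded stratified k-fold CV; returns per-fold reports and their mean.

    ``make_model`` is a zero-argument factory returning an unfitted
    estimator with fit / predict_score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(np.bincount(y)) < k:
        raise ValueError("each fold must contain both classes")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    for train_idx, test_idx in cv.split(X, y):
        model = make_model()
        model.fit(X[train_idx], y[train_idx])
        scores = model.predict_score(X[test_idx])
        reports.append(evaluate_predictions(y[test_idx], scores, threshold))
    fields = ("ACC", "TPR", "SPC", "PPV", "MCC", "AUC")
    mean = MetricsReport(**{
        f: float(np.mean([getattr(r, f) for r in reports])) for f in fields
    })
    return reports, mean


# -- pairs file I/O ---------------------------------------------------------

def read_pairs_tsv(path) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Read (drug_id, target_id, label) rows from a TSV file."""
    pairs: list[tuple[str, str]] = []
    labels: list[int] = []
    text = Path(path).read_text()
    for row, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"row {row}: expected drug<TAB>target<TAB>label")
        if fields[2] not in ("0", "1"):
            raise ValueError(f"row {row}: label must be 0 or 1")
        pairs.append((fields[0], fields[1]))
        labels.append(int(fields[2]))
    return pairs, np.array(labels, dtype=int)


def write_pairs_tsv(dataset: InteractionDataset, path=None) -> str:
    lines = [f"{d}\t{t}\t1" for d, t in dataset.positives]
    lines += [f"{d}\t{t}\t0" for d, t in dataset.negatives]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
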