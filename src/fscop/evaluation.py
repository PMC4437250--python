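"""Classification performance measures and repeated cross-validation.

Binary performance is summarized from a pooled confusion table by
sensitivity ``Sn = TP/(TP+FN)``, specificity ``Sp = TN/(TN+FP)``,
overall accuracy ``Acc = (TP+TN)/(TP+FN+TN+FP)``, balanced accuracy
``Avc = (Sn+Sp)/2``, and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

which is NaN whenever a denominator factor vanishes (never silently
substituted by zero).

The evaluation protocol is repeated stratified k-fold cross-validation
(default 5 folds, 30 repeats).  Within every fold, centroids and the
selection LP are built from the training samples only; the selected
features are then handed to a downstream classifier trained on the
same training samples, and the fold's test predictions are pooled
across folds into one confusion table per repeat.  Stratification
keeps class proportions in every fold — essential for the imbalanced
cohorts this protocol is aimed at.  Repeat ``r`` is seeded with
``base_seed + r`` so any single run can be replayed.

Downstream classifiers are pluggable: anything callable as
``classifier(train_values, train_labels) -> predict(test_values)``,
with values restricted to the selected features (rows), works — e.g. a
scikit-learn estimator via :func:`sklearn_classifier`.  The default is
the built-in weighted nearest-centroid predictor, which reuses the
optimal LP weights of the fold.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_model import LabeledMatrix, compute_centroids
from .lp_model import FsCopConfig, build_lp
from .solver import FsCopSolution, predict, solve

__all__ = [
    "ConfusionTable",
    "MetricSet",
    "CvReport",
    "confusion",
    "metrics",
    "avc_from_rates",
    "repeated_cv",
    "fit_fold",
    "best_by_mcc",
    "sklearn_classifier",
]

Classifier = Callable[[np.ndarray, Sequence[str]], Callable[[np.ndarray], Sequence[str]]]


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    """Sn, Sp, Acc, Avc in [0, 1]; MCC in [-1, 1] or NaN."""

    sn: float
    sp: float
    acc: float
    avc: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"sn": self.sn, "sp": self.sp, "acc": self.acc,
                "avc": self.avc, "mcc": self.mcc}


METRIC_NAMES = ("sn", "sp", "acc", "avc", "mcc")


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive_class: str,
) -> ConfusionTable:
    """Exact TP/FN/TN/FP counts with ``positive_class`` as the positive label."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"{len(true_labels)} true vs {len(predicted_labels)} predicted labels"
        )
    if positive_class not in set(true_labels) | set(predicted_labels):
        raise ValueError(f"unknown positive class {positive_class!r}")
    tp = fn = tn = fp = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionTable(tp=tp, fn=fn, tn=tn, fp=fp)


def metrics(ct: ConfusionTable) -> MetricSet:
    """Derive the five performance measures from a confusion table.

    Requires at least one positive (``tp + fn``) and one negative
    (``tn + fp``) evaluated sample.  MCC propagates as NaN when its
    denominator has a zero factor.
    """
    if ct.tp + ct.fn < 1:
        raise ValueError("no positive samples evaluated")
    if ct.tn + ct.fp < 1:
        raise ValueError("no negative samples evaluated")
    sn = ct.tp / (ct.tp + ct.fn)
    sp = ct.tn / (ct.tn + ct.fp)
    acc = (ct.tp + ct.tn) / ct.total
    denom = (
        (ct.tp + ct.fp) * (ct.tp + ct.fn) * (ct.tn + ct.fp) * (ct.tn + ct.fn)
    )
    if denom == 0:
        mcc = float("nan")
    else:
        mcc = (ct.tp * ct.tn - ct.fp * ct.fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, acc=acc, avc=avc_from_rates(sn, sp), mcc=mcc)


def avc_from_rates(sn: float, sp: float) -> float:
    """Balanced accuracy ``(Sn + Sp) / 2`` from sensitivity and specificity."""
    if not (0 <= sn <= 1 and 0 <= sp <= 1):
        raise ValueError(f"rates must be in [0, 1], got sn={sn}, sp={sp}")
    return (sn + sp) / 2


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CvReport:
    """Per-repeat metrics of a repeated k-fold cross-validation.

    ``fold_selections[r][f]`` is the ordered feature selection of fold
    ``f`` in repeat ``r``; ``seeds[r]`` is the fold-shuffling seed of
    repeat ``r``.  ``means``/``sds`` are recomputed from the per-run
    metrics (sd with ``ddof=1``; NaN propagates, and a single repeat
    has undefined sd).
    """

    runs: tuple[MetricSet, ...]
    seeds: tuple[int, ...]
    fold_selections: tuple[tuple[tuple[str, ...], ...], ...]
    positive_class: str
    folds: int

    @property
    def n_repeats(self) -> int:
        return len(self.runs)

    @property
    def means(self) -> dict[str, float]:
        return {
            m: float(np.mean([getattr(r, m) for r in self.runs]))
            for m in METRIC_NAMES
        }

    @property
    def sds(self) -> dict[str, float]:
        out = {}
        for m in METRIC_NAMES:
            vals = [getattr(r, m) for r in self.runs]
            out[m] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        return out

    def selection_frequency(self) -> dict[str, float]:
        """Fraction of all folds (across repeats) selecting each feature."""
        counts: Counter[str] = Counter()
        total = 0
        for rep in self.fold_selections:
            for sel in rep:
                counts.update(sel)
                total += 1
        return {f: counts[f] / total for f in sorted(counts)}

    # -- serialization -------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """One row per repeat: seed then the five metrics, 6 decimals."""
        lines = ["seed\tsn\tsp\tacc\tavc\tmcc"]
        for seed, r in zip(self.seeds, self.runs):
            vals = "\t".join(f"{getattr(r, m):.6f}" for m in METRIC_NAMES)
            lines.append(f"{seed}\t{vals}")
        Path(path).write_text("\n".join(lines) + "\n")

    def summary_dict(self, config: FsCopConfig | None = None) -> dict:
        out = {
            "repeats": self.n_repeats,
            "folds": self.folds,
            "positive_class": self.positive_class,
            "seeds": list(self.seeds),
            "means": self.means,
            "sds": self.sds,
            "selection_frequency": self.selection_frequency(),
        }
        if config is not None:
            out["config"] = {
                "lam": config.lam,
                "min_weight": config.min_weight,
                "margin": config.margin,
                "select_threshold": config.select_threshold,
                "fixed": sorted(config.fixed.feature_ids),
            }
        return out

    def to_json(self, path: str | Path, config: FsCopConfig | None = None) -> None:
        def _clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            if isinstance(x, dict):
                return {k: _clean(v) for k, v in x.items()}
            if isinstance(x, list):
                return [_clean(v) for v in x]
            return x

        Path(path).write_text(
            json.dumps(_clean(self.summary_dict(config)), indent=2, sort_keys=True)
            + "\n"
        )


def fit_fold(
    train_data: LabeledMatrix, config: FsCopConfig
) -> tuple["FsCopSolution", tuple[str, ...]]:
    """Run the selection pipeline on one training fold.

    Centroids and the LP are functions of the training samples only;
    returns the optimal solution and its selected features.
    """
    centroids = compute_centroids(train_data)
    lp = build_lp(train_data, centroids, config)
    solution = solve(lp)
    if not solution.is_optimal:
        raise RuntimeError(f"fold solve failed: {solution.status}: {solution.message}")
    return solution, solution.selected


def repeated_cv(
    data: LabeledMatrix,
    config: FsCopConfig,
    folds: int = 5,
    repeats: int = 30,
    base_seed: int = 0,
    classifier: Classifier | None = None,
    positive_class: str | None = None,
) -> CvReport:
    """Repeated stratified k-fold CV of the selection + classification pipeline.

    Per repeat ``r`` (seed ``base_seed + r``): stratified folds are
    drawn; in each fold the selection model is fit on training samples
    only and the classifier (default: the fold's weighted
    nearest-centroid predictor) labels the held-out samples; all test
    predictions of the repeat are pooled into one confusion table.

    ``positive_class`` defaults to the first class appearing in the
    label sequence.  Every class must have at least ``folds`` samples.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    small = {c: m for c, m in data.class_counts.items() if m < folds}
    if small:
        raise ValueError(
            "stratified CV needs every class to have at least as many samples "
            f"as folds ({folds}); too small: {small}"
        )
    if positive_class is None:
        positive_class = data.class_ids[0]
    elif positive_class not in data.class_ids:
        raise ValueError(f"unknown positive class {positive_class!r}")

    labels = np.asarray(data.labels)
    run_metrics: list[MetricSet] = []
    seeds: list[int] = []
    all_selections: list[tuple[tuple[str, ...], ...]] = []

    for r in range(repeats):
        seed = base_seed + r
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        pooled_true: list[str] = []
        pooled_pred: list[str] = []
        fold_sels: list[tuple[str, ...]] = []
        for f, (train_idx, test_idx) in enumerate(
            skf.split(np.zeros(len(labels)), labels)
        ):
            train = data.subset_samples(train_idx)
            try:
                solution, selected = fit_fold(train, config)
            except Exception as exc:
                raise RuntimeError(
                    f"repeat {r} (seed {seed}), fold {f}: {exc}"
                ) from exc
            fold_sels.append(selected)

            test_values = data.values[:, test_idx]
            if classifier is None:
                centroids = compute_centroids(train)
                preds = [
                    predict(centroids, solution.weights, test_values[:, t])
                    for t in range(test_values.shape[1])
                ]
            else:
                sel = list(selected)
                tr = train.values[[data.feature_index(s) for s in sel], :]
                te = test_values[[data.feature_index(s) for s in sel], :]
                try:
                    predictor = classifier(tr, list(train.labels))
                    preds = list(predictor(te))
                except Exception as exc:
                    raise RuntimeError(
                        f"classifier failed in repeat {r} (seed {seed}), "
                        f"fold {f}: {exc}"
                    ) from exc
            pooled_true.extend(labels[test_idx])
            pooled_pred.extend(preds)

        ct = confusion(pooled_true, pooled_pred, positive_class)
        if ct.total != data.n_samples:
            raise AssertionError("pooled confusion counts do not sum to n")
        run_metrics.append(metrics(ct))
        seeds.append(seed)
        all_selections.append(tuple(fold_sels))

    return CvReport(
        runs=tuple(run_metrics),
        seeds=tuple(seeds),
        fold_selections=tuple(all_selections),
        positive_class=positive_class,
        folds=folds,
    )


def best_by_mcc(reports: Mapping[str, CvReport]) -> tuple[str, CvReport]:
    """Entry with the highest mean MCC; NaN means rank last, ties by order."""
    if not reports:
        raise ValueError("no reports to compare")
    best_name: str | None = None
    best_val = -math.inf
    for name, rep in reports.items():
        val = rep.means["mcc"]
        if math.isnan(val):
            continue
        if val > best_val:
            best_name, best_val = name, val
    if best_name is None:
        raise ValueError("all reports have NaN mean MCC")
    return best_name, reports[best_name]


def sklearn_classifier(estimator_factory: Callable[[], object]) -> Classifier:
    """Adapt a scikit-learn estimator factory to the classifier plug-in contract.

    The contract passes matrices as features x samples; scikit-learn
    wants samples x features, so this adapter transposes.
    """

    def train(train_values: np.ndarray, train_labels: Sequence[str]):
        est = estimator_factory()
        est.fit(train_values.T, list(train_labels))

        def predict_fn(test_values: np.ndarray) -> Sequence[str]:
            return [str(y) for y in est.predict(test_values.T)]

        return predict_fn

    return train
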