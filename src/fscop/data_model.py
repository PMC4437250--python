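"""Labeled expression matrices, class centroids, and fixed-feature sets.

The containers here are shared by every other module.  An expression
dataset is a ``p x n`` numeric matrix (features as rows, samples as
columns — the microarray convention) together with a class label per
sample.  Class centroids are the per-class arithmetic means of the
sample columns; they are the geometric anchors of the whole selection
model, which asks that every training sample sit closer (in weighted
L1 distance) to its own centroid than to any rival centroid.

Values are expected to be already normalized (e.g. RMA intensities for
microarrays, log-normalized counts for RNA-seq); no normalization is
performed here beyond an optional per-feature z-score
(:func:`standardize`).  Missing values are a hard error — the model has
no imputation step, and silently imputing would change the distances
the constraints are built from.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "LabeledMatrix",
    "CentroidSet",
    "FixedSubset",
    "load_labeled_matrix",
    "write_labeled_matrix",
    "read_fixed_subset",
    "compute_centroids",
    "standardize",
]

PathLike = Union[str, Path, io.IOBase]


@dataclass(frozen=True)
class LabeledMatrix:
    """A validated features-by-samples expression matrix with class labels.

    Parameters
    ----------
    feature_ids
        Ordered, unique feature identifiers (length ``p``).
    sample_ids
        Ordered, unique sample identifiers (length ``n``).
    values
        ``p x n`` float matrix, all entries finite.
    labels
        Class label per sample, aligned with ``sample_ids``.  At least
        two distinct classes must be present and every class has at
        least one sample.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "values", values)

        p, n = len(self.feature_ids), len(self.sample_ids)
        if values.ndim != 2 or values.shape != (p, n):
            raise ValueError(
                f"values must be a {p} x {n} matrix, got shape {values.shape}"
            )
        if p < 1:
            raise ValueError("need at least one feature")
        if n < 2:
            raise ValueError("need at least two samples")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        if not np.isfinite(values).all():
            bad = int(np.flatnonzero(~np.isfinite(values).all(axis=1))[0])
            raise ValueError(
                f"non-finite value in feature {self.feature_ids[bad]!r}; "
                "missing values are not supported"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise ValueError(f"duplicate {name} ID {x!r}")
                seen.add(x)
        if len(set(self.labels)) < 2:
            raise ValueError("need at least two distinct classes")

    # -- derived views -------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def class_ids(self) -> tuple[str, ...]:
        """Distinct class labels in order of first appearance."""
        out: list[str] = []
        for lab in self.labels:
            if lab not in out:
                out.append(lab)
        return tuple(out)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in self.class_ids}
        for lab in self.labels:
            counts[lab] += 1
        return counts

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature ID {feature_id!r}") from None

    # -- subsetting ----------------------------------------------------

    def subset_samples(self, indices: Sequence[int]) -> "LabeledMatrix":
        """New matrix keeping only the sample columns at ``indices`` (in order)."""
        idx = list(indices)
        return LabeledMatrix(
            feature_ids=self.feature_ids,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            values=self.values[:, idx],
            labels=tuple(self.labels[i] for i in idx),
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "LabeledMatrix":
        """New matrix keeping only the given feature rows, in the given order."""
        idx = [self.feature_index(f) for f in feature_ids]
        return LabeledMatrix(
            feature_ids=tuple(feature_ids),
            sample_ids=self.sample_ids,
            values=self.values[idx, :],
            labels=self.labels,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class CentroidSet:
    """Per-class, per-feature mean expression values.

    ``means`` is ``c x p``: row ``j`` is the centroid of class
    ``class_ids[j]``, i.e. the arithmetic mean over that class's sample
    columns.  The rival centroid of a sample in class ``j`` is any row
    ``j' != j``.
    """

    class_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    means: np.ndarray

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        object.__setattr__(self, "means", means)
        c, p = len(self.class_ids), len(self.feature_ids)
        if means.shape != (c, p):
            raise ValueError(f"means must be {c} x {p}, got {means.shape}")

    def class_index(self, class_id: str) -> int:
        try:
            return self.class_ids.index(class_id)
        except ValueError:
            raise KeyError(f"unknown class {class_id!r}") from None

    def centroid(self, class_id: str) -> np.ndarray:
        return self.means[self.class_index(class_id)]


@dataclass(frozen=True)
class FixedSubset:
    """Features the user forces into the final selection.

    Each member receives a weight lower bound of ``min_weight`` in the
    optimization, so it always survives the positive-weight selection
    rule.  Typical members are literature biomarkers (e.g. the probe
    sets of a gene known to be disease-associated) or the output of
    another feature-selection algorithm being refined.
    """

    feature_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "feature_ids", frozenset(str(f) for f in self.feature_ids)
        )

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.feature_ids))

    def __contains__(self, feature_id: object) -> bool:
        return feature_id in self.feature_ids

    def validate(self, data: LabeledMatrix) -> None:
        """Raise if any member is absent from ``data``, naming the offender."""
        known = set(data.feature_ids)
        missing = sorted(self.feature_ids - known)
        if missing:
            raise ValueError(
                f"fixed feature(s) not present in the matrix: {', '.join(missing)}"
            )


# ---------------------------------------------------------------------------
# readers


def _read_table(source: PathLike) -> pd.DataFrame:
    # sep=None sniffs TSV vs CSV; the first column is the row index.
    return pd.read_csv(source, sep=None, engine="python", index_col=0)


def load_labeled_matrix(
    matrix_source: PathLike,
    labels_source: Union[PathLike, Mapping[str, str]],
) -> LabeledMatrix:
    """Read an expression matrix and a sample-label table into a LabeledMatrix.

    The matrix is a delimited (TSV or CSV, auto-detected) table whose
    first column holds feature IDs and whose header row holds sample
    IDs.  The labels source is either a mapping ``{sample_id: class}``
    or a two-column delimited file ``(sample_id, class_label)``; a
    header row in the label file is detected and skipped automatically.

    Labels are joined to samples **by ID**, never by column position.
    Samples present in the label file but absent from the matrix are
    ignored with a warning; a matrix sample without a label is a hard
    error naming the sample.
    """
    df = _read_table(matrix_source)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature ID {dup[0]!r} in matrix")

    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression matrix: {exc}") from exc

    if isinstance(labels_source, Mapping):
        label_map = {str(k): str(v) for k, v in labels_source.items()}
    else:
        lab = pd.read_csv(
            labels_source, sep=None, engine="python", header=None, dtype=str,
            comment="#",
        )
        if lab.shape[1] < 2:
            raise ValueError("labels file must have two columns: sample_id, class")
        lab = lab.iloc[:, :2]
        # header auto-detection: a first row whose sample ID does not occur
        # in the matrix is taken to be a header
        if len(lab) and str(lab.iat[0, 0]) not in set(df.columns):
            lab = lab.iloc[1:]
        label_map = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(str)))

    extra = sorted(set(label_map) - set(df.columns))
    if extra:
        warnings.warn(
            f"{len(extra)} labeled sample(s) absent from matrix, ignored: "
            + ", ".join(extra[:5]),
            stacklevel=2,
        )

    labels = []
    for sid in df.columns:
        if sid not in label_map:
            raise ValueError(f"no class label for sample {sid!r}")
        labels.append(label_map[sid])

    return LabeledMatrix(
        feature_ids=tuple(df.index),
        sample_ids=tuple(df.columns),
        values=values,
        labels=tuple(labels),
    )


def write_labeled_matrix(
    data: LabeledMatrix, matrix_path: Union[str, Path], labels_path: Union[str, Path]
) -> None:
    """Write matrix + labels in the exact TSV formats :func:`load_labeled_matrix` reads."""
    df = data.to_frame()
    df.index.name = "feature_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.10g")
    lines = ["sample_id\tclass"]
    lines += [f"{s}\t{l}" for s, l in zip(data.sample_ids, data.labels)]
    Path(labels_path).write_text("\n".join(lines) + "\n")


def read_fixed_subset(source: PathLike) -> FixedSubset:
    """Read a plain-text fixed-feature list: one ID per line, ``#`` comments."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    ids = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return FixedSubset(frozenset(ids))


# ---------------------------------------------------------------------------
# transforms


def compute_centroids(data: LabeledMatrix) -> CentroidSet:
    """Per-class arithmetic means of the sample columns (``c x p``)."""
    labels = np.asarray(data.labels)
    means = np.empty((data.n_classes, data.n_features))
    for j, cls in enumerate(data.class_ids):
        means[j] = data.values[:, labels == cls].mean(axis=1)
    return CentroidSet(
        class_ids=data.class_ids, feature_ids=data.feature_ids, means=means
    )


def standardize(data: LabeledMatrix) -> LabeledMatrix:
    """Per-feature z-score over all samples (sample sd, ``ddof=1``).

    Constant features map to all-zero rows rather than dividing by
    zero.  Standardizing is idempotent up to floating error.  Useful
    when the margin parameter of the selection model must be
    interpretable on a common scale across features; off by default in
    the pipeline because normalized expression values are usually fed
    in directly.
    """
    mu = data.values.mean(axis=1, keepdims=True)
    sd = data.values.std(axis=1, ddof=1, keepdims=True)
    centred = data.values - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centred / np.where(sd > 0, sd, 1.0), 0.0)
    return LabeledMatrix(
        feature_ids=data.feature_ids,
        sample_ids=data.sample_ids,
        values=z,
        labels=data.labels,
    )
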