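"""Build the feature-selection linear program.

The model assigns each feature ``i`` a weight ``w_i in [0, 1]`` and
each training sample ``k`` a nonnegative slack ``xi_k``, and minimizes

    sum_i w_i  +  lambda * sum_k xi_k

subject to, for every sample ``k`` of class ``j`` and every rival
class ``j' != j``,

    sum_i (|s_ki - m_i^j| - |s_ki - m_i^j'|) * w_i  -  xi_k  <=  -delta

where ``m_i^j`` is the class-``j`` centroid of feature ``i``.  The
constraint says the weighted L1 distance to the own centroid must be
smaller than to every rival centroid, by at least the margin ``delta``
(a strict inequality is not expressible in an LP; the margin replaces
it).  The slack lets inseparable samples violate their constraints at
a price of ``lambda`` per unit.  Features in the fixed subset get the
tighter weight bound ``w_f in [min_weight, 1]`` and therefore always
come out with a positive weight — that is the mechanism by which
user-chosen biomarkers are guaranteed a place in the selection.

Because each slack appears with coefficient ``-1`` in every row of its
sample and is unbounded above, the program is feasible for any valid
configuration; minimization alone keeps slacks small.

For the binary case there is exactly one rival class, so one row per
sample.  For ``c > 2`` classes one row is emitted per (sample, rival)
pair — the own centroid must beat *every* rival — which reduces to the
binary model at ``c = 2`` and is the strictest consistent
generalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import CentroidSet, FixedSubset, LabeledMatrix

__all__ = ["FsCopConfig", "LinearProgram", "build_lp", "describe_lp"]


@dataclass(frozen=True)
class FsCopConfig:
    """Hyperparameters of the selection model.

    Parameters
    ----------
    lam
        Slack penalty ``lambda >= 0``.  Larger values buy separation at
        the cost of more (or heavier) selected features; ``lam = 0``
        makes slack free and the all-zero weight vector optimal.
    min_weight
        Lower weight bound for fixed features, in ``(0, 1]``.  A value
        above 1 would contradict the global upper bound ``w <= 1`` and
        is rejected.
    fixed
        Features forced into the selection (possibly empty).
    margin
        The margin ``delta > 0`` standing in for the strict
        own-centroid-wins inequality.  Scale-dependent: it is measured
        in the same units as weighted expression distances.
    select_threshold
        Selection cutoff ``tau``: features with optimal weight strictly
        above ``tau`` are selected.  Must sit below both ``min_weight``
        (so fixed features always pass) and ``margin``.
    """

    lam: float = 1.0
    min_weight: float = 0.1
    fixed: FixedSubset = field(default_factory=FixedSubset)
    margin: float = 1e-3
    select_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if not self.lam >= 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not 0 < self.min_weight <= 1:
            raise ValueError(
                f"min_weight must be in (0, 1], got {self.min_weight} "
                "(a value above 1 contradicts the weight upper bound)"
            )
        if not self.margin > 0:
            raise ValueError(f"margin must be > 0, got {self.margin}")
        if not 0 < self.select_threshold < self.min_weight:
            raise ValueError(
                "select_threshold must satisfy 0 < tau < min_weight, got "
                f"tau={self.select_threshold}, min_weight={self.min_weight}"
            )
        if not self.select_threshold < self.margin:
            raise ValueError(
                "select_threshold must be below margin, got "
                f"tau={self.select_threshold}, margin={self.margin}"
            )


@dataclass(frozen=True)
class LinearProgram:
    """Solver-independent description of one selection LP.

    Decision variables are ordered: ``p`` weight variables (one per
    feature, matching ``feature_ids``) followed by ``n`` slack
    variables (one per sample, matching ``sample_ids``).

    ``inequality @ x <= rhs`` row-wise; ``row_provenance[r]`` is the
    ``(sample_id, own_class, rival_class)`` triple that produced row
    ``r``.
    """

    objective: np.ndarray
    inequality: np.ndarray
    rhs: np.ndarray
    bounds: tuple[tuple[float, float | None], ...]
    row_provenance: tuple[tuple[str, str, str], ...]
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    config: FsCopConfig

    @property
    def n_weights(self) -> int:
        return len(self.feature_ids)

    @property
    def n_slacks(self) -> int:
        return len(self.sample_ids)

    @property
    def n_rows(self) -> int:
        return self.inequality.shape[0]


def build_lp(
    data: LabeledMatrix, centroids: CentroidSet, config: FsCopConfig
) -> LinearProgram:
    """Assemble objective, constraint rows, and variable bounds.

    ``centroids`` must come from ``data`` itself or, inside
    cross-validation, from the training portion only.  Emits exactly
    one row per (sample, rival class) pair: ``n * (c - 1)`` rows in
    total, ``n`` for a binary problem.
    """
    config.fixed.validate(data)
    if data.n_classes < 2:  # unreachable through LabeledMatrix, kept as a guard
        raise ValueError("need at least two classes to build the model")
    if centroids.feature_ids != data.feature_ids:
        raise ValueError("centroid features do not match the data matrix")

    p, n = data.n_features, data.n_samples
    c = len(centroids.class_ids)
    n_vars = p + n

    # distance of every sample to every centroid, per feature: (n, c, p)
    dist = np.abs(data.values.T[:, None, :] - centroids.means[None, :, :])

    class_row = {cls: j for j, cls in enumerate(centroids.class_ids)}
    rows = np.zeros((n * (c - 1), n_vars))
    provenance: list[tuple[str, str, str]] = []
    r = 0
    for k, (sid, own) in enumerate(zip(data.sample_ids, data.labels)):
        j = class_row[own]
        for jr, rival in enumerate(centroids.class_ids):
            if jr == j:
                continue
            rows[r, :p] = dist[k, j] - dist[k, jr]
            rows[r, p + k] = -1.0  # one slack per sample, shared across rivals
            provenance.append((sid, own, rival))
            r += 1

    rhs = np.full(n * (c - 1), -config.margin)

    objective = np.concatenate([np.ones(p), np.full(n, config.lam)])
    bounds: list[tuple[float, float | None]] = []
    for f in data.feature_ids:
        lo = config.min_weight if f in config.fixed else 0.0
        bounds.append((lo, 1.0))
    bounds.extend([(0.0, None)] * n)

    return LinearProgram(
        objective=objective,
        inequality=rows,
        rhs=rhs,
        bounds=tuple(bounds),
        row_provenance=tuple(provenance),
        feature_ids=data.feature_ids,
        sample_ids=data.sample_ids,
        config=config,
    )


def describe_lp(lp: LinearProgram) -> str:
    """Human-readable one-paragraph summary for logs and the CLI."""
    cfg = lp.config
    fixed = sorted(cfg.fixed.feature_ids)
    lines = [
        f"selection LP: {lp.n_weights} weight variable(s), "
        f"{lp.n_slacks} slack variable(s), {lp.n_rows} constraint row(s)",
        f"lambda={cfg.lam}, margin={cfg.margin}, "
        f"select_threshold={cfg.select_threshold}",
        f"{len(fixed)} fixed feature(s)"
        + (
            f" with weight >= {cfg.min_weight}: " + ", ".join(fixed)
            if fixed
            else ""
        ),
    ]
    return "\n".join(lines)
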