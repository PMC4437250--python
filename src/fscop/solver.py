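"""Solve the selection LP exactly and turn weights into a feature subset.

The LP is handed to the HiGHS dual simplex via
:func:`scipy.optimize.linprog`, which returns a certifiably optimal
basic solution and is deterministic for identical input.  Selection is
then a threshold rule — features whose optimal weight exceeds ``tau``
are kept — and prediction is weighted nearest-centroid: a sample goes
to the class whose centroid is closest in the weighted L1 metric, the
same metric the constraints were written in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .data_model import CentroidSet
from .lp_model import FsCopConfig, LinearProgram

__all__ = ["FsCopSolution", "solve", "select_features", "predict"]

logger = logging.getLogger(__name__)

OPTIMAL = "optimal"
INFEASIBLE = "infeasible_config"
FAILURE = "solver_failure"


@dataclass(frozen=True)
class FsCopSolution:
    """Optimal weights, slacks and bookkeeping from one LP solve.

    ``selected`` lists feature IDs with weight strictly above the
    selection threshold, ordered by descending weight (ties broken by
    input feature order); it always contains the fixed subset because
    fixed features are bounded below by ``min_weight > tau``.
    """

    weights: np.ndarray
    slacks: np.ndarray
    objective: float
    status: str
    message: str
    selected: tuple[str, ...]
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    config: FsCopConfig

    @property
    def is_optimal(self) -> bool:
        return self.status == OPTIMAL

    def weight_of(self, feature_id: str) -> float:
        return float(self.weights[self.feature_ids.index(feature_id)])

    def to_rows(self) -> list[dict]:
        """Weight table rows (feature_id, weight, selected, fixed), descending weight."""
        order = sorted(
            range(len(self.feature_ids)), key=lambda i: (-self.weights[i], i)
        )
        sel = set(self.selected)
        return [
            {
                "feature_id": self.feature_ids[i],
                "weight": float(self.weights[i]),
                "selected": self.feature_ids[i] in sel,
                "fixed": self.feature_ids[i] in self.config.fixed,
            }
            for i in order
        ]


def solve(lp: LinearProgram) -> FsCopSolution:
    """Globally optimal basic solution of the LP (HiGHS dual simplex).

    Raises ``RuntimeError`` on solver failure rather than silently
    returning a suboptimal point; an infeasible model (impossible for
    a valid configuration, since slack variables are unbounded) is
    reported through ``status`` for defensive completeness.
    """
    res = linprog(
        lp.objective,
        A_ub=lp.inequality,
        b_ub=lp.rhs,
        bounds=list(lp.bounds),
        method="highs-ds",
        options={"primal_feasibility_tolerance": 1e-9,
                 "dual_feasibility_tolerance": 1e-9},
    )
    p = lp.n_weights
    if res.status == 0:
        weights = np.asarray(res.x[:p])
        slacks = np.asarray(res.x[p:])
        selected = _threshold_select(weights, lp.feature_ids, lp.config)
        if not np.any(weights > lp.config.select_threshold):
            logger.warning(
                "all optimal weights are ~0: the data does not support any "
                "feature at this margin/lambda; selection is empty"
            )
        return FsCopSolution(
            weights=weights,
            slacks=slacks,
            objective=float(res.fun),
            status=OPTIMAL,
            message=res.message,
            selected=selected,
            feature_ids=lp.feature_ids,
            sample_ids=lp.sample_ids,
            config=lp.config,
        )
    status = INFEASIBLE if res.status == 2 else FAILURE
    if status == FAILURE:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return FsCopSolution(
        weights=np.full(p, np.nan),
        slacks=np.full(lp.n_slacks, np.nan),
        objective=float("nan"),
        status=status,
        message=res.message,
        selected=(),
        feature_ids=lp.feature_ids,
        sample_ids=lp.sample_ids,
        config=lp.config,
    )


def _threshold_select(
    weights: np.ndarray, feature_ids: tuple[str, ...], config: FsCopConfig
) -> tuple[str, ...]:
    order = sorted(range(len(feature_ids)), key=lambda i: (-weights[i], i))
    return tuple(
        feature_ids[i] for i in order if weights[i] > config.select_threshold
    )


def select_features(solution: FsCopSolution, config: FsCopConfig) -> tuple[str, ...]:
    """Features with optimal weight strictly above ``config.select_threshold``.

    Ordered by descending weight, ties broken by input feature order.
    Exact zeros are never selected.  Raises on a non-optimal solution.
    """
    if not solution.is_optimal:
        raise ValueError(
            f"cannot select features from a {solution.status} solution"
        )
    return _threshold_select(solution.weights, solution.feature_ids, config)


def predict(
    centroids: CentroidSet, weights: np.ndarray, sample_column: np.ndarray
) -> str:
    """Weighted nearest-centroid class assignment for one sample.

    Returns ``argmin_j sum_i w_i |x_i - m_i^j|``; ties go to the class
    earliest in ``centroids.class_ids``.  An all-zero weight vector
    makes every distance zero and the rule degenerates to the first
    class — permitted (the model allows all-zero optima on
    uninformative data) but logged as a warning.
    """
    weights = np.asarray(weights, dtype=float)
    x = np.asarray(sample_column, dtype=float)
    p = len(centroids.feature_ids)
    if weights.shape != (p,) or x.shape != (p,):
        raise ValueError(
            f"dimension mismatch: model has {p} features, got weights "
            f"{weights.shape} and sample {x.shape}"
        )
    if not np.any(weights > 0):
        logger.warning("all weights are zero; prediction falls back to tie-break")
    dists = np.abs(x[None, :] - centroids.means) @ weights
    return centroids.class_ids[int(np.argmin(dists))]
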