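"""Synthetic two-class (or c-class) expression matrices with known truth.

The generator emulates a normalized expression matrix: a small set of
informative features whose class means are shifted apart by a chosen
effect size, plus a bulk of noise features with identical means in
every class.  All values are independent Gaussians — the selection
model treats features additively in an L1 distance, so independent
features exercise every code path; correlation structure, batch
effects and intensity-dependent microarray noise are deliberately not
imitated.

Ground truth is encoded in the feature IDs (``inf_*`` vs ``noise_*``)
so a generated matrix is self-describing and needs no sidecar file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import FixedSubset, LabeledMatrix

__all__ = ["SyntheticSpec", "generate", "inject_fixed_noise_feature"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Informative feature means for class ``j`` (0-based) are
    ``j * effect_size``, so consecutive classes are separated by
    ``effect_size`` standard-deviation units when ``noise_sd = 1``.
    Noise features have mean 0 in every class.
    """

    n_per_class: tuple[int, ...] = (30, 30)
    p_informative: int = 2
    p_noise: int = 48
    effect_size: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_class", tuple(int(n) for n in self.n_per_class))
        if len(self.n_per_class) < 2:
            raise ValueError("need at least two classes")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("every class needs at least one sample")
        if self.p_informative + self.p_noise < 1:
            raise ValueError("need at least one feature")
        if self.p_informative < 0 or self.p_noise < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")


def generate(spec: SyntheticSpec) -> tuple[LabeledMatrix, frozenset[str]]:
    """Draw one dataset; deterministic per seed.

    Returns the labeled matrix and the set of informative feature IDs
    (the ground truth a selection method should recover).
    """
    rng = np.random.default_rng(spec.seed)
    c = len(spec.n_per_class)
    p = spec.p_informative + spec.p_noise
    n = sum(spec.n_per_class)

    width = max(2, len(str(p)))
    feature_ids = [f"inf_{i + 1:0{width}d}" for i in range(spec.p_informative)] + [
        f"noise_{i + 1:0{width}d}" for i in range(spec.p_noise)
    ]
    truth = frozenset(feature_ids[: spec.p_informative])

    means = np.zeros((p, n))
    labels: list[str] = []
    sample_ids: list[str] = []
    col = 0
    for j, nj in enumerate(spec.n_per_class):
        cls = f"class{j}"
        means[: spec.p_informative, col : col + nj] = j * spec.effect_size
        for k in range(nj):
            sample_ids.append(f"{cls}_s{k + 1:03d}")
            labels.append(cls)
        col += nj

    values = rng.normal(loc=means, scale=spec.noise_sd)
    data = LabeledMatrix(
        feature_ids=tuple(feature_ids),
        sample_ids=tuple(sample_ids),
        values=values,
        labels=tuple(labels),
    )
    return data, truth


def inject_fixed_noise_feature(
    data: LabeledMatrix, ground_truth: frozenset[str], k: int = 1
) -> FixedSubset:
    """Fixed subset of ``k`` uninformative features, in matrix order.

    Emulates forcing literature biomarkers that carry no signal in the
    data at hand: tests can assert that such features are still
    selected (the weight lower bound guarantees it) without destroying
    classification accuracy.
    """
    noise = [f for f in data.feature_ids if f not in ground_truth]
    if not noise:
        raise ValueError("no noise features available to fix")
    if k > len(noise):
        raise ValueError(f"requested {k} noise features, only {len(noise)} exist")
    return FixedSubset(frozenset(noise[:k]))
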