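"""Shared builders for tiny random problem instances."""

from __future__ import annotations

import numpy as np

from fscop import FixedSubset, FsCopConfig, LabeledMatrix


def random_instance(
    rng: np.random.Generator,
    max_p: int = 4,
    max_n_per_class: int = 4,
    max_c: int = 3,
    lam_choices=(0.1, 1.0, 10.0),
    with_fixed: bool = False,
) -> tuple[LabeledMatrix, FsCopConfig]:
    """A tiny labeled matrix plus a random model configuration."""
    p = int(rng.integers(1, max_p + 1))
    c = int(rng.integers(2, max_c + 1))
    counts = [int(rng.integers(1, max_n_per_class + 1)) for _ in range(c)]
    n = sum(counts)
    feature_ids = tuple(f"f{i}" for i in range(p))
    sample_ids = []
    labels = []
    for j, nj in enumerate(counts):
        for k in range(nj):
            sample_ids.append(f"c{j}s{k}")
            labels.append(f"c{j}")
    values = rng.normal(scale=2.0, size=(p, n)) + rng.normal(
        scale=1.0, size=(p, 1)
    )
    data = LabeledMatrix(
        feature_ids=feature_ids,
        sample_ids=tuple(sample_ids),
        values=values,
        labels=tuple(labels),
    )
    fixed = FixedSubset()
    if with_fixed and p >= 1:
        k = int(rng.integers(1, p + 1))
        chosen = rng.choice(p, size=k, replace=False)
        fixed = FixedSubset(frozenset(feature_ids[i] for i in chosen))
    config = FsCopConfig(
        lam=float(rng.choice(lam_choices)),
        min_weight=float(rng.uniform(0.05, 0.5)),
        margin=float(rng.uniform(1e-3, 1e-1)),
        select_threshold=1e-6,
        fixed=fixed,
    )
    return data, config


def toy_one_feature(margin: float = 1e-3, lam: float = 1.0):
    """1 feature, one sample per class at 0 and 1; centroids are the samples."""
    data = LabeledMatrix(
        feature_ids=("f1",),
        sample_ids=("a1", "b1"),
        values=np.array([[0.0, 1.0]]),
        labels=("A", "B"),
    )
    config = FsCopConfig(lam=lam, margin=margin, min_weight=0.1,
                         select_threshold=min(1e-6, margin / 10))
    return data, config
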