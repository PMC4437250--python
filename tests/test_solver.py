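import numpy as np
import pytest

from fscop import (
    CentroidSet,
    FixedSubset,
    FsCopConfig,
    LabeledMatrix,
    build_lp,
    compute_centroids,
    select_features,
    solve,
)
from fscop.solver import predict

from _helpers import random_instance, toy_one_feature
from _lp_oracle import solve_lp


def _solve_instance(data, config):
    lp = build_lp(data, compute_centroids(data), config)
    return lp, solve(lp)


class TestToyClosedForm:
    def test_margin_is_the_optimum_for_unit_lambda(self):
        data, cfg = toy_one_feature(margin=0.001, lam=1.0)
        _, sol = _solve_instance(data, cfg)
        assert sol.is_optimal
        assert sol.objective == pytest.approx(0.001, abs=1e-9)
        assert sol.weights[0] == pytest.approx(0.001, abs=1e-9)
        np.testing.assert_allclose(sol.slacks, 0.0, atol=1e-9)

    def test_free_slack_absorbs_everything_at_zero_lambda(self):
        data, cfg = toy_one_feature(margin=0.001, lam=0.0)
        _, sol = _solve_instance(data, cfg)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        assert sol.weights[0] == pytest.approx(0.0, abs=1e-9)

    def test_scale_covariance(self):
        # scaling expression by alpha scales distances by alpha, so the
        # minimal weight mass shrinks by alpha while the margin stays put
        alpha = 10.0
        data, cfg = toy_one_feature(margin=0.001, lam=1.0)
        scaled = LabeledMatrix(data.feature_ids, data.sample_ids,
                               data.values * alpha, data.labels)
        _, sol = _solve_instance(data, cfg)
        _, sol_scaled = _solve_instance(scaled, cfg)
        assert sol_scaled.weights[0] == pytest.approx(sol.weights[0] / alpha,
                                                      rel=1e-9)


class TestSolutionContracts:
    def test_objective_recomputes_from_variables(self, rng):
        for _ in range(10):
            data, cfg = random_instance(rng, with_fixed=True)
            _, sol = _solve_instance(data, cfg)
            recomputed = sol.weights.sum() + cfg.lam * sol.slacks.sum()
            assert sol.objective == pytest.approx(recomputed, rel=1e-8, abs=1e-12)

    def test_constraints_and_bounds_satisfied(self, rng):
        for _ in range(10):
            data, cfg = random_instance(rng, with_fixed=True)
            lp, sol = _solve_instance(data, cfg)
            x = np.concatenate([sol.weights, sol.slacks])
            residual = lp.inequality @ x - lp.rhs
            assert residual.max() <= 1e-6
            for v, (lo, hi) in zip(x, lp.bounds):
                assert v >= lo - 1e-9
                if hi is not None:
                    assert v <= hi + 1e-9

    def test_never_infeasible_for_valid_config(self, rng):
        # slacks are unbounded above, so any valid config is feasible
        for _ in range(20):
            data, cfg = random_instance(rng, with_fixed=True)
            _, sol = _solve_instance(data, cfg)
            assert sol.status == "optimal"


class TestOracleEquivalence:
    def test_matches_independent_simplex_on_random_instances(self, rng):
        for _ in range(60):
            data, cfg = random_instance(rng, with_fixed=bool(rng.integers(2)))
            lp, sol = _solve_instance(data, cfg)
            _, oracle_obj = solve_lp(lp.objective, lp.inequality, lp.rhs,
                                     list(lp.bounds))
            assert sol.objective == pytest.approx(oracle_obj, abs=1e-6)


class TestMonotonicity:
    def test_objective_non_decreasing_in_fixed_subset(self, rng):
        for _ in range(15):
            data, cfg = random_instance(rng, max_p=4)
            base = FsCopConfig(lam=cfg.lam, min_weight=cfg.min_weight,
                               margin=cfg.margin)
            _, sol0 = _solve_instance(data, base)
            prev = sol0.objective
            fixed: set[str] = set()
            for f in data.feature_ids:
                fixed.add(f)
                grown = FsCopConfig(lam=cfg.lam, min_weight=cfg.min_weight,
                                    margin=cfg.margin,
                                    fixed=FixedSubset(frozenset(fixed)))
                _, sol = _solve_instance(data, grown)
                assert sol.objective >= prev - 1e-8
                prev = sol.objective

    def test_total_slack_non_increasing_in_lambda(self, rng):
        for _ in range(10):
            data, cfg = random_instance(rng)
            slack_mass = []
            for lam in (0.1, 1.0, 10.0):
                c = FsCopConfig(lam=lam, min_weight=cfg.min_weight,
                                margin=cfg.margin)
                _, sol = _solve_instance(data, c)
                slack_mass.append(sol.slacks.sum())
            assert slack_mass[0] >= slack_mass[1] - 1e-7
            assert slack_mass[1] >= slack_mass[2] - 1e-7


class TestSeparableInstances:
    def test_zero_slack_on_separable_data(self, strong_synthetic):
        data, _ = strong_synthetic
        cfg = FsCopConfig()
        _, sol = _solve_instance(data, cfg)
        assert sol.slacks.sum() == pytest.approx(0.0, abs=1e-7)

    def test_zero_slack_samples_classified_correctly(self, strong_synthetic):
        data, _ = strong_synthetic
        _, sol = _solve_instance(data, FsCopConfig())
        cent = compute_centroids(data)
        for k, (sid, label) in enumerate(zip(data.sample_ids, data.labels)):
            if sol.slacks[k] <= 1e-9:
                assert predict(cent, sol.weights, data.values[:, k]) == label


class TestSelection:
    def test_threshold_and_ordering(self):
        data = LabeledMatrix(
            ("f1", "f2", "f3"), ("s1", "s2"),
            np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]]), ("A", "B"))
        cfg = FsCopConfig()
        lp, sol = _solve_instance(data, cfg)
        fake = sol.__class__(
            weights=np.array([0.8, 0.0, 0.3]), slacks=sol.slacks,
            objective=sol.objective, status="optimal", message="",
            selected=(), feature_ids=sol.feature_ids,
            sample_ids=sol.sample_ids, config=cfg)
        assert select_features(fake, cfg) == ("f1", "f3")

    def test_selection_requires_optimal_status(self, tiny_matrix):
        cfg = FsCopConfig()
        lp, sol = _solve_instance(tiny_matrix, cfg)
        failed = sol.__class__(
            weights=sol.weights, slacks=sol.slacks, objective=sol.objective,
            status="solver_failure", message="boom", selected=(),
            feature_ids=sol.feature_ids, sample_ids=sol.sample_ids, config=cfg)
        with pytest.raises(ValueError, match="solver_failure"):
            select_features(failed, cfg)

    def test_fixed_feature_always_selected(self, rng):
        for _ in range(10):
            data, cfg = random_instance(rng, with_fixed=True)
            _, sol = _solve_instance(data, cfg)
            for f in cfg.fixed:
                assert f in sol.selected
                assert sol.weight_of(f) >= cfg.min_weight - 1e-9

    def test_uninformative_data_can_select_nothing(self):
        # identical class distributions: weights buy nothing, slack is cheaper
        rng = np.random.default_rng(3)
        values = np.tile(rng.normal(size=(3, 1)), (1, 8)) + 0.0
        data = LabeledMatrix(
            tuple(f"g{i}" for i in range(3)),
            tuple(f"s{i}" for i in range(8)),
            values, ("A",) * 4 + ("B",) * 4)
        cfg = FsCopConfig(lam=0.01)
        _, sol = _solve_instance(data, cfg)
        assert sol.selected == ()


class TestPredict:
    def test_sample_on_centroid_wins(self, tiny_matrix):
        cent = compute_centroids(tiny_matrix)
        w = np.ones(3)
        assert predict(cent, w, cent.centroid("B")) == "B"

    def test_all_zero_weights_tie_break_to_first_class(self, tiny_matrix, caplog):
        cent = compute_centroids(tiny_matrix)
        with caplog.at_level("WARNING", logger="fscop.solver"):
            out = predict(cent, np.zeros(3), tiny_matrix.values[:, 0])
        assert out == tiny_matrix.class_ids[0]
        assert any("zero" in r.message for r in caplog.records)

    def test_dimension_mismatch(self, tiny_matrix):
        cent = compute_centroids(tiny_matrix)
        with pytest.raises(ValueError, match="dimension"):
            predict(cent, np.ones(2), tiny_matrix.values[:, 0])

    def test_agrees_with_exhaustive_argmin(self, rng):
        for _ in range(20):
            c, p = 3, 4
            means = rng.normal(size=(c, p))
            cent = CentroidSet(class_ids=("x", "y", "z"),
                               feature_ids=tuple(f"g{i}" for i in range(p)),
                               means=means)
            w = rng.uniform(size=p)
            x = rng.normal(size=p)
            dists = [(np.abs(x - means[j]) * w).sum() for j in range(c)]
            assert predict(cent, w, x) == cent.class_ids[int(np.argmin(dists))]


class TestEquivariance:
    def test_feature_permutation_equivariant_end_to_end(self, rng):
        data, cfg = random_instance(rng, max_p=4, with_fixed=True)
        _, sol = _solve_instance(data, cfg)
        perm = list(rng.permutation(data.n_features))
        permuted = data.subset_features([data.feature_ids[i] for i in perm])
        _, sol_p = _solve_instance(permuted, cfg)
        assert sol_p.objective == pytest.approx(sol.objective, abs=1e-8)
        assert set(sol_p.selected) == set(sol.selected)
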