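"""Weighted fusion and the genetic weight optimizer."""

import numpy as np
import pytest

from idrfuse.errors import ContractError, DataError, ParameterError
from idrfuse.evaluation import auc
from idrfuse.fusion import (
    GAConfig,
    N_METHODS,
    ValidationDataset,
    ValidationSuite,
    WeightVector,
    average_fusion,
    fitness,
    fuse,
    ga_optimize,
    project_simplex,
    read_weights,
    write_weights,
)
from idrfuse.simulate import PredictorSpec, build_validation_suite


def random_tracks(rng, L=40):
    return [rng.random(L) for _ in range(N_METHODS)]


class TestWeightVector:
    def test_must_sum_to_one(self):
        with pytest.raises(ContractError):
            WeightVector(np.full(6, 0.2))

    def test_nonnegative(self):
        v = np.array([0.5, 0.7, -0.2, 0.0, 0.0, 0.0])
        with pytest.raises(ContractError):
            WeightVector(v)


class TestFuse:
    def test_one_hot_identity(self, rng):
        tracks = random_tracks(rng)
        fused = fuse(tracks, WeightVector.one_hot(0))
        assert np.allclose(fused.probabilities, tracks[0], atol=1e-12)

    def test_uniform_weights_equal_average(self, rng):
        tracks = random_tracks(rng)
        fused = fuse(tracks, WeightVector.uniform())
        averaged = average_fusion(tracks)
        assert np.allclose(fused.probabilities, averaged.probabilities, atol=1e-12)
        assert np.allclose(averaged.probabilities, np.mean(tracks, axis=0), atol=1e-12)

    def test_matches_weighted_sum_oracle(self, rng):
        tracks = random_tracks(rng)
        w = project_simplex(rng.random(N_METHODS))
        expected = sum(wi * t for wi, t in zip(w, tracks))
        assert np.allclose(fuse(tracks, WeightVector(w)).probabilities, expected,
                           atol=1e-12)

    def test_length_mismatch_names_track(self, rng):
        tracks = random_tracks(rng)
        tracks[3] = tracks[3][:-5]
        with pytest.raises(ContractError, match="track 3"):
            fuse(tracks, WeightVector.uniform())

    def test_joint_permutation_invariance(self, rng):
        tracks = random_tracks(rng)
        w = project_simplex(rng.random(N_METHODS))
        perm = rng.permutation(N_METHODS)
        fused = fuse(tracks, WeightVector(w))
        permuted = fuse([tracks[i] for i in perm], WeightVector(w[perm]))
        assert np.allclose(fused.probabilities, permuted.probabilities, atol=1e-12)

    def test_six_identical_tracks_average_to_themselves(self, rng):
        t = rng.random(25)
        fused = average_fusion([t] * N_METHODS)
        assert np.allclose(fused.probabilities, t, atol=1e-12)


def make_suite(rng, n_datasets=3, n_proteins=4, L=30):
    datasets = []
    for d in range(n_datasets):
        labels, tracks = [], []
        for _p in range(n_proteins):
            y = (rng.random(L) < 0.4).astype(int)
            y[0], y[1] = 0, 1  # both classes present
            labels.append(y)
            tracks.append(rng.random((N_METHODS, L)))
        datasets.append(ValidationDataset(name=f"d{d}", labels=labels, tracks=tracks))
    return ValidationSuite(datasets)


class TestFitness:
    def test_perfect_tracks_reach_suite_size(self, rng):
        datasets = []
        for d in range(4):
            y = (rng.random(50) < 0.4).astype(int)
            y[0], y[1] = 0, 1
            tracks = np.tile(y.astype(float), (N_METHODS, 1))
            datasets.append(ValidationDataset(name=f"d{d}", labels=[y], tracks=[tracks]))
        suite = ValidationSuite(datasets)
        assert fitness(WeightVector.uniform(), suite) == pytest.approx(4.0)

    def test_anti_separation_gives_zero(self, rng):
        y = (rng.random(50) < 0.4).astype(int)
        y[0], y[1] = 0, 1
        tracks = np.tile(1.0 - y.astype(float), (N_METHODS, 1))
        suite = ValidationSuite([ValidationDataset(name="d", labels=[y], tracks=[tracks])])
        assert fitness(WeightVector.uniform(), suite) == pytest.approx(0.0)

    def test_matches_mann_whitney_sum(self, rng):
        suite = make_suite(rng)
        w = WeightVector(project_simplex(rng.random(N_METHODS)))
        expected = 0.0
        for ds in suite.datasets:
            y, scores = ds.pooled()
            fused = scores @ w.values
            pos, neg = fused[y == 1], fused[y == 0]
            pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            expected += pairs / (pos.size * neg.size)
        assert fitness(w, suite) == pytest.approx(expected, abs=1e-9)

    def test_single_class_dataset_names_dataset(self, rng):
        y = np.ones(20, int)
        tracks = rng.random((N_METHODS, 20))
        suite = ValidationSuite([ValidationDataset(name="degenerate", labels=[y], tracks=[tracks])])
        with pytest.raises(DataError, match="degenerate"):
            fitness(WeightVector.uniform(), suite)

    def test_invariant_under_monotone_transform(self, rng):
        suite = make_suite(rng)
        w = WeightVector(project_simplex(rng.random(N_METHODS)))
        base = fitness(w, suite)
        for ds in suite.datasets:
            y, scores = ds.pooled()
            fused = scores @ w.values
            assert auc(np.exp(3 * fused) - 1, y) == pytest.approx(auc(fused, y), abs=1e-12)
        assert base > 0  # sanity


class TestProjectSimplex:
    def test_output_is_simplex_point(self, rng):
        for _ in range(100):
            v = rng.normal(scale=3, size=N_METHODS)
            p = project_simplex(v)
            assert p.min() >= 0 and p.sum() == pytest.approx(1.0)

    def test_fixed_point_on_simplex(self, rng):
        p = rng.dirichlet(np.ones(N_METHODS))
        assert np.allclose(project_simplex(p), p, atol=1e-12)


class TestGaOptimize:
    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            GAConfig(population=1)
        with pytest.raises(ParameterError):
            GAConfig(generations=0)
        with pytest.raises(ParameterError):
            GAConfig(crossover_prob=1.5)

    def test_degenerate_ga_returns_fitter_initial_candidate(self, rng):
        suite = make_suite(rng)
        config = GAConfig(population=2, generations=1, elitism=1, seed=0,
                          crossover_prob=0.0, mutation_prob=0.0)
        result = ga_optimize(suite, config)
        init_rng = np.random.default_rng(0)
        initial = [project_simplex(init_rng.dirichlet(np.ones(N_METHODS))) for _ in range(2)]
        best_initial = max(fitness(WeightVector(v), suite) for v in initial)
        assert result.best_fitness >= best_initial - 1e-12

    def test_same_seed_identical_trajectories(self, rng):
        suite = make_suite(rng)
        config = GAConfig(population=8, generations=5, seed=3)
        a = ga_optimize(suite, config)
        b = ga_optimize(suite, config)
        assert a.trajectory == b.trajectory
        assert np.array_equal(a.best.values, b.best.values)

    def test_best_fitness_monotone_nondecreasing(self, rng):
        suite = make_suite(rng)
        result = ga_optimize(suite, GAConfig(population=10, generations=8, seed=1))
        assert all(b >= a for a, b in zip(result.trajectory, result.trajectory[1:]))

    def test_complementary_specialists_beat_every_one_hot(self):
        specs = [
            PredictorSpec(auc=0.95, auc_by_class={"LDR_protein": 0.55}),  # SDR expert
            PredictorSpec(auc=0.95, auc_by_class={"SDR_protein": 0.55}),  # LDR expert
            PredictorSpec(auc=0.55),
            PredictorSpec(auc=0.55),
            PredictorSpec(auc=0.55),
            PredictorSpec(auc=0.55),
        ]
        suite = build_validation_suite([(1, 0), (0, 1)], specs, size=12, seed=0)
        result = ga_optimize(suite, GAConfig(population=24, generations=25, seed=0))
        for k in range(N_METHODS):
            assert result.best_fitness > fitness(WeightVector.one_hot(k), suite)


def test_weight_file_round_trip(tmp_path, rng):
    w = WeightVector(project_simplex(rng.random(N_METHODS)))
    path = tmp_path / "weights.tsv"
    write_weights(w, path, seed=3, fingerprint="abc")
    back = read_weights(path)
    assert np.allclose(back.values, w.values, atol=1e-6)
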