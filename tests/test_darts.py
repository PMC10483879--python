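"""Architecture search: mixtures, cells, discretization, search descent."""

import numpy as np
import pytest

from idrfuse.autograd import Tensor
from idrfuse.darts import (
    DEFAULT_SPACE,
    ArchitectureEncoding,
    DiscreteCell,
    DiscreteNetCell,
    DiscreteNetwork,
    OperationSpace,
    SearchCell,
    SearchConfig,
    SearchNetwork,
    bilevel_search,
    cell_edges,
    cell_forward,
    darts_predict,
    discretize,
    mixed_operation,
    train_discrete,
    write_genotypes,
    read_genotypes,
)
from idrfuse.errors import ContractError, DataError, ParameterError
from idrfuse.simulate import planted_tensor_dataset


class TestMixedOperation:
    def test_singleton_space_is_identity(self, rng):
        x = rng.normal(size=(2, 3, 4, 4))
        assert np.allclose(mixed_operation(np.array([3.7]), [x]), x)

    def test_uniform_alphas_give_mean(self, rng):
        maps = [rng.normal(size=(2, 2)) for _ in range(5)]
        out = mixed_operation(np.zeros(5), maps)
        assert np.allclose(out, np.mean(maps, axis=0))

    def test_matches_direct_softmax_sum(self, rng):
        alpha = rng.normal(size=4)
        maps = [rng.normal(size=(3, 5)) for _ in range(4)]
        w = np.exp(alpha) / np.exp(alpha).sum()
        expected = sum(wi * m for wi, m in zip(w, maps))
        assert np.allclose(mixed_operation(alpha, maps), expected, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ContractError):
            mixed_operation(np.zeros(2), [np.zeros((2, 2)), np.zeros((3, 2))])


def one_hot_alpha(space, name, scale=60.0):
    vec = np.zeros(len(space))
    vec[space.index(name)] = scale
    return vec


class TestCellForward:
    def test_identity_edges_sum_inputs(self, rng):
        space = OperationSpace(("zero", "identity"))
        cell = SearchCell(np.random.default_rng(0), space, c_in=3, channels=3,
                          n_nodes=1, reduction=False)
        alphas = {(0, 2): one_hot_alpha(space, "identity"),
                  (1, 2): one_hot_alpha(space, "identity")}
        s0, s1 = rng.normal(size=(2, 2, 3, 6, 6))
        out = cell_forward(s0, s1, cell, alphas)
        assert np.allclose(out, s0 + s1, atol=1e-9)

    def test_all_zero_operations_annihilate(self, rng):
        space = OperationSpace(("zero", "identity"))
        cell = SearchCell(np.random.default_rng(0), space, c_in=2, channels=2,
                          n_nodes=2, reduction=False)
        alphas = {e: one_hot_alpha(space, "zero") for e in cell_edges(2)}
        out = cell_forward(rng.normal(size=(1, 2, 4, 4)),
                           rng.normal(size=(1, 2, 4, 4)), cell, alphas)
        assert np.abs(out).max() < 1e-9

    def test_matches_topological_evaluation_oracle(self, rng):
        space = DEFAULT_SPACE
        cell = SearchCell(np.random.default_rng(3), space, c_in=2, channels=2,
                          n_nodes=2, reduction=False)
        alphas = {e: rng.normal(size=len(space)) for e in cell_edges(2)}
        s0 = rng.normal(size=(1, 2, 6, 6))
        s1 = rng.normal(size=(1, 2, 6, 6))

        # independent oracle: explicit node-by-node evaluation
        nodes = [s0, s1]
        for j in (2, 3):
            acc = np.zeros_like(s0)
            for i in range(j):
                candidates = [
                    cell.ops[(i, j, name)](Tensor(nodes[i])).data for name in space.names
                ]
                acc = acc + mixed_operation(alphas[(i, j)], candidates)
            nodes.append(acc)
        expected = np.concatenate([nodes[2], nodes[3]], axis=1)

        assert np.allclose(cell_forward(s0, s1, cell, alphas), expected, atol=1e-6)


class TestDiscretize:
    def make_encoding(self, alphas):
        return ArchitectureEncoding(2, DEFAULT_SPACE,
                                    {ct: dict(alphas) for ct in ("normal", "reduction")})

    def test_unanimous_mass_selects_that_op(self):
        alphas = {e: one_hot_alpha(DEFAULT_SPACE, "sep_conv_3") for e in cell_edges(2)}
        genotypes = discretize(self.make_encoding(alphas))
        for genotype in genotypes.values():
            for incoming in genotype.edges.values():
                assert all(op == "sep_conv_3" for _, op in incoming)

    def test_matches_enumerate_and_rank_oracle(self, rng):
        alphas = {e: rng.normal(size=len(DEFAULT_SPACE)) for e in cell_edges(2)}
        genotypes = discretize(self.make_encoding(alphas))

        def softmax(v):
            e = np.exp(v - v.max())
            return e / e.sum()

        for genotype in genotypes.values():
            for j in (2, 3):
                ranked = []
                for i in range(j):
                    w = softmax(alphas[(i, j)])
                    best = max(
                        (idx for idx, n in enumerate(DEFAULT_SPACE.names) if n != "zero"),
                        key=lambda idx: w[idx],
                    )
                    ranked.append((i, DEFAULT_SPACE.names[best], w[best]))
                ranked.sort(key=lambda t: -t[2])
                expected = sorted((i, op) for i, op, _ in ranked[:2])
                assert genotype.edges[j] == expected

    def test_result_is_valid_dag_with_two_inputs_per_node(self, rng):
        alphas = {e: rng.normal(size=len(DEFAULT_SPACE)) for e in cell_edges(2)}
        for genotype in discretize(self.make_encoding(alphas)).values():
            genotype.validate(DEFAULT_SPACE)  # raises on violation

    def test_zero_op_never_selected_even_when_dominant(self):
        alphas = {e: one_hot_alpha(DEFAULT_SPACE, "zero") for e in cell_edges(2)}
        for genotype in discretize(self.make_encoding(alphas)).values():
            for incoming in genotype.edges.values():
                assert all(op != "zero" for _, op in incoming)


class TestContinuousDiscreteConsistency:
    def test_one_hot_forward_equals_discrete_forward(self, rng):
        space = DEFAULT_SPACE
        search = SearchCell(np.random.default_rng(5), space, c_in=2, channels=2,
                            n_nodes=2, reduction=False)
        chosen = {(0, 2): "sep_conv_3", (1, 2): "identity",
                  (0, 3): "max_pool_3", (1, 3): "dil_conv_3"}
        alphas = {}
        for edge in cell_edges(2):
            if edge in chosen:
                alphas[edge] = one_hot_alpha(space, chosen[edge], scale=200.0)
            else:
                alphas[edge] = one_hot_alpha(space, "zero", scale=200.0)
        genotype = DiscreteCell(n_nodes=2, edges={
            2: [(0, "sep_conv_3"), (1, "identity")],
            3: [(0, "max_pool_3"), (1, "dil_conv_3")],
        })
        discrete = DiscreteNetCell(np.random.default_rng(9), space, genotype,
                                   c_in=2, channels=2, reduction=False)
        # share parameters between the matching continuous/discrete ops
        for (i, j, idx), op in discrete.ops.items():
            source = search.ops[(i, j, genotype.edges[j][idx][1])]
            for pname, tensor in op._params.items():
                tensor.data = source._params[pname].data.copy()
        s0, s1 = rng.normal(size=(2, 1, 2, 5, 5))
        assert np.allclose(
            cell_forward(s0, s1, search, alphas), cell_forward(s0, s1, discrete),
            atol=1e-8,
        )


class TestBilevelSearch:
    def test_zero_epochs_returns_initialization(self):
        X, y = planted_tensor_dataset(8, seed=0)
        config = SearchConfig(epochs=0, seed=4)
        encoding, _history = bilevel_search((X, y), (X, y), config=config)
        reference = SearchNetwork(config, DEFAULT_SPACE, seed=4).encoding()
        for ct in ("normal", "reduction"):
            for edge in cell_edges(config.n_nodes):
                assert np.array_equal(encoding.alphas[ct][edge], reference.alphas[ct][edge])

    def test_same_seed_identical_results(self):
        X, y = planted_tensor_dataset(24, seed=1)
        config = SearchConfig(epochs=1, batch_size=12, seed=2)
        enc1, hist1 = bilevel_search((X[:16], y[:16]), (X[16:], y[16:]), config=config)
        enc2, hist2 = bilevel_search((X[:16], y[:16]), (X[16:], y[16:]), config=config)
        assert hist1 == hist2
        for ct in ("normal", "reduction"):
            for edge in cell_edges(2):
                assert np.array_equal(enc1.alphas[ct][edge], enc2.alphas[ct][edge])

    def test_empty_split_rejected(self):
        X, y = planted_tensor_dataset(4, seed=0)
        with pytest.raises(DataError):
            bilevel_search((X, y), (X[:0], y[:0]), config=SearchConfig(epochs=1))

    def test_softmax_weights_sum_to_one(self):
        X, y = planted_tensor_dataset(16, seed=3)
        config = SearchConfig(epochs=1, batch_size=8, seed=0)
        encoding, _ = bilevel_search((X, y), (X, y), config=config)
        for ct in ("normal", "reduction"):
            for edge in cell_edges(2):
                assert encoding.edge_weights(ct, edge).sum() == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def trained_discrete_network():
    config = SearchConfig(seed=0)
    genotypes = {
        "normal": DiscreteCell(2, {2: [(0, "identity"), (1, "sep_conv_3")],
                                   3: [(0, "identity"), (2, "identity")]}),
        "reduction": DiscreteCell(2, {2: [(0, "avg_pool_3"), (1, "identity")],
                                      3: [(1, "identity"), (2, "max_pool_3")]}),
    }
    network = DiscreteNetwork(config, DEFAULT_SPACE, genotypes, seed=0)
    X, y = planted_tensor_dataset(128, delta=2.0, seed=5)
    train_discrete(network, (X, y), epochs=10, seed=0)
    return network


class TestDiscreteNetwork:
    @pytest.fixture()
    def trained(self, trained_discrete_network):
        return trained_discrete_network

    def test_single_tensor_single_probability(self, trained, rng):
        track = darts_predict(trained, rng.normal(size=(1, 20, 20, 3)))
        assert len(track) == 1

    def test_identical_tensors_identical_probabilities(self, trained, rng):
        t = rng.normal(size=(20, 20, 3))
        track = darts_predict(trained, np.stack([t, t]))
        assert track.probabilities[0] == track.probabilities[1]

    def test_bad_shape_rejected(self, trained, rng):
        with pytest.raises(ContractError):
            darts_predict(trained, rng.normal(size=(4, 20, 19, 3)))

    def test_learns_planted_signal(self, trained):
        from idrfuse.evaluation import auc
        X, y = planted_tensor_dataset(200, delta=2.0, seed=6)
        track = darts_predict(trained, X)
        assert auc(track.probabilities, y) > 0.9


def test_genotype_file_round_trip(tmp_path):
    genotypes = {
        "normal": DiscreteCell(2, {2: [(0, "sep_conv_5"), (1, "identity")],
                                   3: [(1, "dil_conv_3"), (2, "avg_pool_3")]}),
        "reduction": DiscreteCell(2, {2: [(0, "max_pool_3"), (1, "max_pool_3")],
                                      3: [(0, "identity"), (2, "sep_conv_3")]}),
    }
    path = tmp_path / "genotypes.txt"
    write_genotypes(genotypes, path)
    back = read_genotypes(path)
    for ct in ("normal", "reduction"):
        assert back[ct].edges == genotypes[ct].edges
        assert back[ct].n_nodes == 2


def test_invalid_configs_rejected():
    with pytest.raises(ParameterError):
        SearchConfig(batch_size=0)
    with pytest.raises(ParameterError):
        OperationSpace(())
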