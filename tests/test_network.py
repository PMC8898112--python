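import numpy as np
import pytest

from genpsowvq.genpso import GenPSOConfig, genpso_optimize
from genpsowvq import network as nn
from genpsowvq.wavelet_blocks import tile_blocks

from oracles import forward_oracle


class TestInit:
    def test_deterministic(self):
        a = nn.init_network(8, True, seed=42)
        b = nn.init_network(8, True, seed=42)
        np.testing.assert_array_equal(a.flatten(), b.flatten())

    @pytest.mark.parametrize("h,recurrent,count", [
        (16, False, 2128), (16, True, 2384),
        (2, False, 64 * 2 + 2 + 2 * 64 + 64), (64, True, 64 * 64 * 3 + 64 + 64),
    ])
    def test_parameter_counts(self, h, recurrent, count):
        net = nn.init_network(h, recurrent, seed=0)
        assert net.shape.n_params == count
        assert net.flatten().size == count

    def test_disallowed_hidden_raises(self):
        with pytest.raises(ValueError, match="n_hidden"):
            nn.init_network(10)

    def test_parameters_in_init_range(self):
        p = nn.init_network(32, True, seed=1).flatten()
        assert p.min() >= -0.5 and p.max() <= 0.5


class TestFlatten:
    def test_round_trip_bijection(self):
        net = nn.init_network(4, True, seed=7)
        flat = net.flatten()
        again = nn.CompressorNet.from_flat(flat, net.shape).flatten()
        np.testing.assert_array_equal(flat, again)

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError, match="parameters"):
            nn.CompressorNet.from_flat(np.zeros(10), nn.NetShape(4, False))

    def test_node_slices_partition_incoming_weights(self):
        shape = nn.NetShape(4, True)
        groups = shape.node_slices()
        assert len(groups) == 4 + 64
        all_idx = np.concatenate(groups)
        # hidden nodes own w_in columns, biases, w_rec columns; output
        # nodes own w_out columns and biases: together every parameter once
        assert len(all_idx) == len(set(all_idx.tolist()))
        assert len(all_idx) == shape.n_params


class TestForward:
    def test_zero_parameters_give_half(self):
        net = nn.CompressorNet(
            w_in=np.zeros((64, 8)), b_hidden=np.zeros(8), w_rec=None,
            w_out=np.zeros((8, 64)), b_out=np.zeros(64))
        h, y = nn.forward(net, np.random.default_rng(0).random(64))
        np.testing.assert_array_equal(h, 0.5)
        np.testing.assert_array_equal(y, 0.5)

    def test_nonrecurrent_ignores_context(self, rng):
        net = nn.init_network(8, recurrent=False, seed=2)
        x = rng.random(64)
        _, y1 = nn.forward(net, x, prev_hidden=None)
        _, y2 = nn.forward(net, x, prev_hidden=rng.random(8))
        np.testing.assert_array_equal(y1, y2)

    def test_matches_scalar_oracle(self, rng):
        net = nn.init_network(2, recurrent=True, seed=3)
        x = rng.random(64)
        h_prev = rng.random(2)
        h, y = nn.forward(net, x, prev_hidden=h_prev)
        oh, oy = forward_oracle(net.w_in.tolist(), net.b_hidden.tolist(),
                                net.w_out.tolist(), net.b_out.tolist(),
                                x.tolist(), net.w_rec.tolist(),
                                h_prev.tolist())
        np.testing.assert_allclose(h, oh, rtol=1e-12)
        np.testing.assert_allclose(y, oy, rtol=1e-12)

    def test_activations_stay_in_sigmoid_range(self, rng):
        net = nn.init_network(16, True, seed=4)
        x = rng.random(64)
        h, y = nn.forward(net, x)
        assert np.all((h > 0) & (h < 1))
        assert np.all((y > 0) & (y < 1))
        # extreme weights cannot escape [0, 1] even where float64
        # rounds the sigmoid to its endpoints
        net.w_out *= 1000
        h, y = nn.forward(net, x)
        assert np.all((y >= 0) & (y <= 1))

    def test_length_mismatch_raises(self):
        net = nn.init_network(4, False, seed=0)
        with pytest.raises(ValueError):
            nn.forward(net, np.zeros(63))


class TestEncodeDecode:
    def test_single_block_equals_forward(self, rng):
        net = nn.init_network(8, recurrent=True, seed=5)
        x = rng.random(64)
        codes = nn.encode_blocks(net, x[None, :])
        h, _ = nn.forward(net, x)
        np.testing.assert_allclose(codes[0], h, rtol=1e-12)

    def test_nonrecurrent_codes_are_order_invariant(self, rng):
        net = nn.init_network(8, recurrent=False, seed=6)
        x = rng.random((5, 64))
        perm = rng.permutation(5)
        codes = nn.encode_blocks(net, x)
        codes_p = nn.encode_blocks(net, x[perm])
        np.testing.assert_allclose(codes_p, codes[perm], rtol=1e-12)

    def test_recurrent_threading_matches_chained_forward(self, rng):
        net = nn.init_network(4, recurrent=True, seed=7)
        x = rng.random((3, 64))
        codes = nn.encode_blocks(net, x)
        h = np.zeros(4)
        for i in range(3):
            h, _ = nn.forward(net, x[i], prev_hidden=h)
            np.testing.assert_allclose(codes[i], h, rtol=1e-12)

    def test_decode_copies_template_metadata(self, rng):
        net = nn.init_network(4, recurrent=False, seed=8)
        bs = tile_blocks(rng.random((16, 16)))
        codes = nn.encode_blocks(net, bs)
        out = nn.decode_hidden(net, codes, template=bs)
        assert out.grid_dims == bs.grid_dims
        assert out.source_dims == bs.source_dims

    def test_empty_blocks_raise(self):
        net = nn.init_network(4, False, seed=0)
        with pytest.raises(ValueError):
            nn.encode_blocks(net, np.zeros((0, 64)))


class TestFitness:
    def test_matches_scalar_recomputation(self, rng):
        shape = nn.NetShape(4, False)
        params = rng.uniform(-0.5, 0.5, shape.n_params)
        blocks = rng.random((6, 64))
        got = nn.reconstruction_fitness(params, blocks, shape)
        net = nn.CompressorNet.from_flat(params, shape)
        total = 0.0
        for b in blocks:
            _, y = nn.forward(net, b)
            total += float(np.sum((y - b) ** 2))
        assert got == pytest.approx(total / blocks.size, rel=1e-12)

    def test_invariant_under_flatten_round_trip(self, rng):
        shape = nn.NetShape(8, True)
        params = rng.uniform(-0.5, 0.5, shape.n_params)
        blocks = rng.random((4, 64))
        again = nn.CompressorNet.from_flat(params, shape).flatten()
        assert nn.reconstruction_fitness(params, blocks, shape) == \
            nn.reconstruction_fitness(again, blocks, shape)


def test_training_improves_single_repeated_block():
    """GenPSO training on one repeated block beats the untrained net ≥10×."""
    blocks = np.tile(np.random.default_rng(7).random(64), (4, 1))
    shape = nn.NetShape(8, False)
    untrained = nn.reconstruction_fitness(
        nn.init_network(8, False, seed=3).flatten(), blocks, shape)
    cfg = GenPSOConfig(population_size=10, ga_max_gen=99,
                       stagnation_window=100, mutation_scale=0.3,
                       pso_max_iter=100, node_shape=shape.node_slices(),
                       seed=3)
    result = genpso_optimize(
        lambda p: nn.reconstruction_fitness(p, blocks, shape),
        shape.n_params, cfg)
    assert result.evaluations == 2000
    assert result.best_fitness < untrained / 10
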