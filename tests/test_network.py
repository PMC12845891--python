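"""Network contracts: shapes, GRN closed forms, gradients, checkpoints."""

import numpy as np
import pytest

import ecgseg._autograd as ag
from ecgseg import ModelConfig, ProbMask, UNet1d, build_model, forward, grn
from ecgseg.network import load_checkpoint, save_checkpoint
from ecgseg.training import _dice_loss_op

TINY = ModelConfig(base_filters=4, blocks_per_stage=(1, 1, 1, 1))


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(TINY, seed=0)


class TestShapeContract:
    def test_minimum_length_forward(self, tiny_model):
        mask = forward(tiny_model, np.zeros(400, dtype=np.float32))
        assert mask.probs.shape == (400, 4)
        assert np.allclose(mask.probs.sum(axis=1), 1.0, atol=1e-5)

    def test_below_minimum_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="400"):
            forward(tiny_model, np.zeros(399, dtype=np.float32))

    @pytest.mark.parametrize("L", [401, 415, 432, 2500])
    def test_arbitrary_lengths_map_to_LxC(self, tiny_model, L):
        mask = forward(tiny_model, np.random.default_rng(L).normal(size=L))
        assert mask.probs.shape == (L, 4)

    def test_stage_lengths_for_divisible_input(self, tiny_model):
        capture = {}
        tiny_model.forward_batch(np.zeros((1, 2560), dtype=np.float32),
                                 capture=capture)
        lengths = [capture[f"enc{s}"].data.shape[-1] for s in range(4)]
        assert lengths == [640, 320, 160, 80]

    def test_parameter_count_grows_with_blocks(self):
        small = build_model(ModelConfig(base_filters=4,
                                        blocks_per_stage=(1, 1, 1, 1)))
        big = build_model(ModelConfig(base_filters=4,
                                      blocks_per_stage=(2, 2, 2, 2)))
        assert big.n_parameters() > small.n_parameters()

    def test_padding_invariance_away_from_boundary(self, tiny_model):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=2496).astype(np.float32)
        p1 = tiny_model.predict_proba(sig).probs
        padded = np.concatenate([sig, np.zeros(32, dtype=np.float32)])
        p2 = tiny_model.predict_proba(padded).probs[:2496]
        # compare away from the pad boundary by more than the receptive field
        assert np.allclose(p1[:2000], p2[:2000], atol=1e-4)


class TestGRN:
    def test_zero_parameters_are_identity(self, rng):
        x = rng.normal(size=(50, 8))
        assert np.allclose(grn(x, np.zeros(8), np.zeros(8)), x)

    def test_identical_channels_have_unit_gain(self, rng):
        col = rng.normal(size=50)
        x = np.tile(col[:, None], (1, 6))
        gamma, beta = np.full(6, 0.7), np.zeros(6)
        expected = gamma * x + beta + x  # gain g_c/mean(g) == 1
        assert np.allclose(grn(x, gamma, beta), expected, atol=1e-5)

    def test_single_channel_closed_form(self, rng):
        x = rng.normal(size=(64, 1))
        gamma, beta = np.array([0.3]), np.array([-0.2])
        assert np.allclose(grn(x, gamma, beta), gamma * x + beta + x, atol=1e-5)


class TestGradients:
    def test_primitive_ops_match_finite_differences(self):
        rng = np.random.default_rng(0)

        def fdcheck(make_out, tensors, eps=1e-2, tol=5e-3):
            out = make_out()
            r = rng.standard_normal(out.data.shape).astype(np.float32)
            ag.tsum(ag.mul(out, r)).backward()
            for t in tensors:
                flat = t.data.reshape(-1)
                for i in range(0, flat.size, max(1, flat.size // 8)):
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp = float((make_out().data * r).sum())
                    flat[i] = orig - eps
                    lm = float((make_out().data * r).sum())
                    flat[i] = orig
                    assert abs((lp - lm) / (2 * eps)
                               - t.grad.reshape(-1)[i]) < tol

        x = ag.Tensor(rng.standard_normal((2, 3, 17)), requires_grad=True)
        w = ag.Tensor(0.3 * rng.standard_normal((4, 3, 5)), requires_grad=True)
        b = ag.Tensor(np.zeros(4), requires_grad=True)
        fdcheck(lambda: ag.conv1d(x, w, b, stride=2, padding=(1, 2)), [x, w, b])

        xd = ag.Tensor(rng.standard_normal((2, 3, 12)), requires_grad=True)
        wd = ag.Tensor(rng.standard_normal((3, 7)), requires_grad=True)
        fdcheck(lambda: ag.dwconv1d(xd, wd, padding=(3, 3)), [xd, wd])

        xl = ag.Tensor(rng.standard_normal((2, 4, 9)), requires_grad=True)
        g = ag.Tensor(rng.standard_normal(4), requires_grad=True)
        be = ag.Tensor(rng.standard_normal(4), requires_grad=True)
        fdcheck(lambda: ag.layer_norm(xl, g, be), [xl, g, be])

        xu = ag.Tensor(rng.standard_normal((1, 2, 11)), requires_grad=True)
        fdcheck(lambda: ag.upsample_linear(xu, 4), [xu])

        xg = ag.Tensor(rng.standard_normal((2, 3, 8)), requires_grad=True)
        fdcheck(lambda: ag.gelu(xg), [xg])

    def test_one_step_touches_every_parameter(self, rng):
        from ecgseg.training import AdamW

        model = build_model(TINY, seed=1)
        x = rng.normal(size=(2, 416)).astype(np.float32)
        onehot = np.zeros((2, 4, 416), dtype=np.float32)
        onehot[:, 1, 100:140] = 1
        onehot[:, 0, :] = 1 - onehot[:, 1]
        before = model.state_dict()
        probs = ag.softmax_channels(model.forward_batch(x, build_graph=True))
        loss = _dice_loss_op(probs, onehot, 1.0)
        model.zero_grad()
        loss.backward()
        opt = AdamW(model.parameters())
        opt.step(lr=1e-3)
        after = model.state_dict()
        for name in before:
            assert not np.array_equal(before[name], after[name]), name


def test_checkpoint_round_trip(tmp_path, tiny_model):
    sig = np.random.default_rng(2).normal(size=512).astype(np.float32)
    ref = tiny_model.predict_proba(sig).probs
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, path, metadata={"note": "test"})
    loaded = load_checkpoint(path)
    assert loaded.config == tiny_model.config
    assert np.allclose(loaded.predict_proba(sig).probs, ref)


def test_probmask_validates_rows():
    with pytest.raises(ValueError):
        ProbMask(probs=np.full((10, 4), 0.5), fs=125.0)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        ModelConfig(base_filters=0)
    with pytest.raises(ValueError):
        ModelConfig(blocks_per_stage=(1, 1))
    with pytest.raises(ValueError):
        ModelConfig(decoder_kernel=4)
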