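"""Architecture contracts and the NumPy layer engine's gradients."""

import numpy as np
import pytest
from scipy import signal

from renalscint.models import (
    ArchitectureSpec,
    build_dncnn,
    build_model,
    build_resunet,
    build_win5rb,
    count_convolutions,
    load_model,
    save_model,
)
from renalscint.nn import BatchNorm2d, Conv2d

SMALL = {
    "DnCNN": ArchitectureSpec("DnCNN", n_filters=4, dncnn_units=2),
    "Win5RB": ArchitectureSpec("Win5RB", n_filters=4),
    "ResUnet": ArchitectureSpec("ResUnet", resunet_level_filters=(3, 4, 5), resunet_bridge_filters=6),
}


def _zero_weights(model):
    for _, p in model.named_params():
        p.value[...] = 0.0


class TestConvLayer:
    def test_matches_scipy_correlate(self, rng):
        conv = Conv2d(2, 3, 3, rng=rng)
        x = rng.normal(size=(1, 2, 9, 9))
        y = conv.forward(x)
        w = conv._params["weight"].value
        b = conv._params["bias"].value
        for co in range(3):
            expected = b[co] + sum(
                signal.correlate2d(x[0, ci], w[co, ci], mode="same") for ci in range(2)
            )
            assert np.allclose(y[0, co], expected)

    def test_stride_two_halves_even_sides(self, rng):
        conv = Conv2d(1, 2, 3, stride=2, rng=rng)
        assert conv.forward(np.zeros((1, 1, 16, 12))).shape == (1, 2, 8, 6)


def test_batchnorm_train_output_is_normalized(rng):
    bn = BatchNorm2d(3)
    bn.train()
    y = bn.forward(rng.normal(2.0, 5.0, size=(4, 3, 8, 8)))
    assert np.allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=1e-10)
    assert np.allclose(y.std(axis=(0, 2, 3)), 1.0, atol=1e-3)


@pytest.mark.parametrize("name", list(SMALL))
def test_gradients_match_finite_differences(name, rng):
    """End-to-end reverse-mode gradients of each architecture vs central differences."""
    model = build_model(SMALL[name], seed=1)
    model.train()
    x = rng.normal(size=(2, 1, 8, 8))
    t = rng.normal(size=(2, 1, 8, 8))

    def loss():
        return float(np.mean((model.forward(x) - t) ** 2))

    for p in model.parameters():
        p.grad[...] = 0.0
    pred = model.forward(x)
    model.backward(2 * (pred - t) / pred.size)
    params = model.named_params()
    eps = 1e-6
    for pick in rng.choice(len(params), 6, replace=False):
        _, p = params[pick]
        flat = p.value.ravel()
        for idx in rng.choice(flat.size, min(2, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss()
            flat[idx] = orig - eps
            lm = loss()
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert p.grad.ravel()[idx] == pytest.approx(num, abs=1e-6 * (1 + abs(num)))


class TestDnCNN:
    def test_seventeen_convolutions_at_default_depth(self):
        assert count_convolutions(build_dncnn(ArchitectureSpec("DnCNN"))) == 17

    def test_shape_contract(self, rng):
        m = build_model(SMALL["DnCNN"])
        m.eval()
        assert m.forward(rng.normal(size=(1, 1, 20, 28))).shape == (1, 1, 20, 28)

    def test_zero_weights_give_identity(self, rng):
        m = build_model(SMALL["DnCNN"])
        _zero_weights(m)
        m.eval()
        x = rng.normal(size=(1, 1, 10, 10))
        assert np.array_equal(m.forward(x), x)


class TestWin5RB:
    def test_five_convolutions(self):
        assert count_convolutions(build_win5rb(ArchitectureSpec("Win5RB"))) == 5

    def test_receptive_field_is_31(self):
        """5 stacked 7x7 convolutions: an input pixel beyond 15 px away has no effect."""
        m = build_model(SMALL["Win5RB"], seed=2)
        m.eval()
        x = np.zeros((1, 1, 40, 40))
        y0 = m.forward(x)
        x2 = x.copy()
        x2[0, 0, 20, 36] = 100.0  # 16 columns from (20, 20): outside the field
        y1 = m.forward(x2)
        assert y1[0, 0, 20, 20] == pytest.approx(y0[0, 0, 20, 20])
        x3 = x.copy()
        x3[0, 0, 20, 35] = 100.0  # 15 columns away: inside
        y2 = m.forward(x3)
        assert y2[0, 0, 20, 20] != pytest.approx(y0[0, 0, 20, 20])

    def test_zero_weights_give_identity_via_skip(self, rng):
        m = build_model(SMALL["Win5RB"])
        _zero_weights(m)
        m.eval()
        x = rng.normal(size=(1, 1, 12, 12))
        assert np.array_equal(m.forward(x), x)


class TestResUnet:
    def test_shape_round_trip_64(self, rng):
        m = build_model(SMALL["ResUnet"])
        m.eval()
        assert m.forward(rng.normal(size=(1, 1, 64, 64))).shape == (1, 1, 64, 64)

    def test_feature_sides_halve_per_level(self, rng):
        m = build_model(SMALL["ResUnet"])
        m.eval()
        x = rng.normal(size=(1, 1, 64, 64))
        feats = []
        h = x
        for u in m.enc:
            h = u.forward(h)
            feats.append(h.shape[2])
        bridge = m.bridge.forward(h).shape[2]
        assert feats == [64, 32, 16] and bridge == 8

    def test_indivisible_input_rejected(self):
        m = build_model(SMALL["ResUnet"])
        with pytest.raises(ValueError, match="divisible by 8"):
            m.forward(np.zeros((1, 1, 20, 20)))

    def test_default_capacity_exceeds_dncnn(self):
        ru = build_resunet(ArchitectureSpec("ResUnet"))
        dn = build_dncnn(ArchitectureSpec("DnCNN"))
        assert ru.n_parameters() > dn.n_parameters()


@pytest.mark.parametrize(
    "name, shift, side, margin, rel_tol",
    [
        ("DnCNN", 5, 64, 20, 1e-10),
        ("Win5RB", 5, 64, 20, 1e-10),
        # ResUnet: equivariant only to multiples of its downsampling factor
        # (8 at 3 levels), and its border effects reach far into the image
        # through the bridge, hence the larger frame and looser tolerance.
        ("ResUnet", 8, 128, 48, 1e-3),
    ],
)
def test_translation_equivariance_in_interior(name, shift, side, margin, rel_tol, rng):
    """Shifting the input shifts the output, away from the borders."""
    model = build_model(SMALL[name], seed=3)
    model.eval()
    x = rng.normal(size=(1, 1, side, side))
    y = model.forward(x)
    ys = model.forward(np.roll(x, shift, axis=3))
    inner = np.s_[0, 0, margin:-margin, margin:-margin]
    err = np.abs(np.roll(y, shift, axis=3)[inner] - ys[inner]).max()
    assert err <= rel_tol * np.abs(y).max()


@pytest.mark.parametrize("name", list(SMALL))
def test_checkpoint_round_trip_bit_identical(name, tmp_path, rng):
    model = build_model(SMALL[name], seed=4)
    model.eval()
    x = rng.normal(size=(1, 1, 16, 16))
    y = model.forward(x)
    save_model(model, SMALL[name], tmp_path / "ckpt")
    loaded, spec = load_model(tmp_path / "ckpt")
    loaded.eval()
    assert spec.name == name
    assert np.array_equal(loaded.forward(x), y)


def test_unknown_architecture_rejected():
    with pytest.raises(ValueError, match="unknown architecture"):
        ArchitectureSpec(name="UNet3D")
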