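"""Model assembly, dataset splitting, SGDM and the training loop."""

import re

import numpy as np
import pytest

from oracles import sgdm_trajectory_quadratic
from pectseg import (
    ModelConfig,
    OptimizerState,
    PhantomSpec,
    TrainConfig,
    build_model,
    generate_dataset,
    predict,
    sgdm_step,
    split_dataset,
    train,
)
from pectseg import nn as _nn  # noqa: F401  (re-exported engine)
from pectseg.trainer import to_input_tensor


# -- split ------------------------------------------------------------------

def test_split_reproduces_reference_sizes():
    tr, va, te = split_dataset(1288, (0.7, 0.2, 0.1))
    assert (len(tr), len(va), len(te)) == (902, 258, 128)


def test_split_small_n_rounding():
    tr, va, te = split_dataset(10, (0.7, 0.2, 0.1))
    assert (len(tr), len(va), len(te)) == (7, 2, 1)


def test_split_partitions_disjoint_and_complete():
    tr, va, te = split_dataset(101, seed=5)
    allidx = np.concatenate([tr, va, te])
    assert sorted(allidx) == list(range(101))
    assert np.array_equal(np.concatenate(split_dataset(101, seed=5)), allidx)


def test_degenerate_split_rejected():
    with pytest.raises(ValueError):
        split_dataset(10, (1.0, 0.0, 0.0))
    with pytest.raises(ValueError):
        split_dataset(2, (0.7, 0.2, 0.1))


# -- model ------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_model():
    return build_model(ModelConfig(input_size=(64, 64), backbone="tiny", seed=0))


def test_tiny_model_outputs_normalized_probability_maps(tiny_model):
    x = np.random.default_rng(0).random((2, 1, 64, 64)).astype(np.float32)
    probs = tiny_model.probabilities(x)
    assert probs.shape == (2, 3, 64, 64)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_forward_is_deterministic_in_eval_mode(tiny_model):
    x = np.random.default_rng(1).random((1, 1, 64, 64)).astype(np.float32)
    a = tiny_model.forward(x, train=False)
    b = tiny_model.forward(x, train=False)
    assert np.array_equal(a, b)


def test_full_scale_encoder_has_49_convolutions():
    model = build_model(ModelConfig(input_size=(64, 64), backbone="resnet50", seed=0))
    # enumerate actual main-path convolution weights: the stem plus the
    # three convolutions of every bottleneck (projection shortcuts and
    # decoder/ASPP convs excluded)
    names = {p.name for p in model.params()}
    main_path = [n for n in names
                 if re.fullmatch(r"(stem\.conv|s\d+\.b\d+\.c[123])\.w", n)]
    assert len(main_path) == 49
    assert model.encoder_conv_layer_count() == 49


def test_bad_configs_rejected():
    with pytest.raises(ValueError, match="stride"):
        build_model(ModelConfig(input_size=(60, 60), backbone="tiny"))
    with pytest.raises(ValueError, match="pretrained"):
        build_model(ModelConfig(input_size=(64, 64), backbone="tiny", pretrained=True))
    with pytest.raises(ValueError, match="backbone"):
        ModelConfig(backbone="vgg").validate()


# -- SGDM -------------------------------------------------------------------

def test_sgdm_zero_velocity_single_step():
    state = OptimizerState(weights={"w": np.array([1.0])})
    sgdm_step(state, {"w": np.array([1.0])}, mu=0.9, eta=0.001)
    assert state.velocity["w"] == pytest.approx(-0.001)
    assert state.weights["w"] == pytest.approx(0.999)


def test_sgdm_without_momentum_is_plain_gradient_descent():
    state = OptimizerState(weights={"w": np.array([2.0])})
    for _ in range(3):
        sgdm_step(state, {"w": np.array([0.5])}, mu=0.0, eta=0.1)
    assert state.weights["w"] == pytest.approx(2.0 - 3 * 0.1 * 0.5)


def test_sgdm_two_steps_constant_gradient_closed_form():
    mu, eta, g = 0.7, 0.01, 3.0
    state = OptimizerState(weights={"w": np.array([0.0])})
    sgdm_step(state, {"w": np.array([g])}, mu=mu, eta=eta)
    sgdm_step(state, {"w": np.array([g])}, mu=mu, eta=eta)
    assert state.velocity["w"] == pytest.approx(-eta * g * (1 + mu), abs=1e-15)


def test_sgdm_on_quadratic_matches_matrix_power_recurrence():
    eta, mu, w0 = 0.1, 0.9, 1.0
    expected = sgdm_trajectory_quadratic(w0, eta, mu, steps=100)
    state = OptimizerState(weights={"w": np.array([w0], dtype=np.float64)})
    observed = []
    for _ in range(100):
        grad = {"w": state.weights["w"].copy()}  # dL/dw = w for L = w^2/2
        sgdm_step(state, grad, mu=mu, eta=eta)
        observed.append(float(state.weights["w"][0]))
    assert np.allclose(observed, expected, atol=1e-10)


def test_sgdm_rejects_non_finite_gradients():
    state = OptimizerState(weights={"w": np.array([1.0])})
    with pytest.raises(ValueError, match="non-finite"):
        sgdm_step(state, {"w": np.array([np.nan])}, mu=0.9, eta=0.1)


# -- training loop ----------------------------------------------------------

@pytest.fixture(scope="module")
def small_phantoms():
    spec = PhantomSpec(image_size=(32, 32), n_annotations=0)
    return generate_dataset(20, spec, seed=4)


def small_train(pairs, seed=0, epochs=4, **kw):
    model = build_model(ModelConfig(input_size=(32, 32), backbone="tiny", seed=seed))
    cfg = TrainConfig(learning_rate=0.05, momentum=0.9, epochs=epochs,
                      batch_size=4, seed=seed, **kw)
    return train(model, pairs, cfg)


def test_training_descends(small_phantoms):
    res = small_train(small_phantoms, epochs=5)
    hist = res.history
    assert hist.loss.iloc[-1] < hist.loss.iloc[0]
    assert hist.val_accuracy.iloc[-1] > hist.val_accuracy.iloc[0]
    assert list(hist.columns) == ["epoch", "loss", "accuracy", "val_loss",
                                  "val_accuracy"]


def test_training_is_bit_reproducible(small_phantoms):
    a = small_train(small_phantoms, seed=7, epochs=3)
    b = small_train(small_phantoms, seed=7, epochs=3)
    assert a.history.equals(b.history)


def test_class_weighting_raises_rare_class_gradient_share(small_phantoms):
    """Complement-frequency weighting shifts loss gradient toward muscle."""
    from pectseg import nn
    from pectseg.core import as_pixels
    from pectseg.imbalance import one_vs_rest_class_weights

    masks = [m for _, m in small_phantoms]
    x = to_input_tensor([im for im, _ in small_phantoms[:4]])
    y = np.stack([as_pixels(m) for m in masks[:4]])
    model = build_model(ModelConfig(input_size=(32, 32), backbone="tiny", seed=1))
    logits = model.forward(x, train=False)

    def muscle_share(wvec):
        _, d = nn.weighted_ce_loss_and_grad(logits, y, np.asarray(wvec))
        total = np.abs(d).sum()
        return np.abs(d[:, :, :, :][np.broadcast_to((y == 2)[:, None], d.shape)]).sum() / total

    uniform = muscle_share([1.0, 1.0, 1.0])
    weighted = muscle_share(one_vs_rest_class_weights(masks, lam=1.0).per_class)
    assert weighted > uniform


def test_prediction_masks_are_valid(small_phantoms):
    res = small_train(small_phantoms, epochs=3)
    preds = predict(res.model, [im for im, _ in small_phantoms[:3]])
    for p in preds:
        assert p.shape == (32, 32)
        assert set(np.unique(p.pixels)) <= {0, 1, 2}


def test_loss_weights_use_training_split_only(small_phantoms):
    res = small_train(small_phantoms, epochs=2)
    tr, va, te = res.split
    from pectseg.imbalance import one_vs_rest_class_weights

    masks = [m for _, m in small_phantoms]
    expected = one_vs_rest_class_weights([masks[i] for i in tr], lam=1.0)
    assert res.class_weights.per_class == expected.per_class
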