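"""Band attention head, fusion, classifier and training contracts."""

import numpy as np
import pytest

from eegfuse.attention import (AttentionParams, BandAttention, Classifier,
                               EmotionNet, TrainConfig, attention_map,
                               classify, cross_entropy_smoothed,
                               label_smooth_targets, predict, refine_and_fuse,
                               train_model)
from eegfuse.backbone import BackboneConfig
from eegfuse.nn import Tensor
from eegfuse.synthetic import LabeledFeatureSpec, generate_labeled_features


def _head(n_bands=5, d=62, seed=0):
    params = AttentionParams(n_bands=n_bands, feature_dim=d)
    return BandAttention(params, np.random.default_rng(seed)), params


# ----------------------------------------------------------- attention map

def test_single_band_attention_is_one():
    head, _ = _head(n_bands=1, d=4)
    a = attention_map(np.random.default_rng(0).standard_normal((1, 4)), head)
    assert np.allclose(a, [[1.0]])


def test_identical_band_rows_give_uniform_attention(rng):
    head, _ = _head(n_bands=5, d=8)
    x = np.tile(rng.standard_normal(8), (5, 1))
    a = attention_map(x, head)
    assert np.allclose(a, 0.2, atol=1e-6)


def test_attention_rows_sum_to_one_many_inputs(rng):
    head, _ = _head(n_bands=5, d=16)
    for _ in range(200):
        a = attention_map(rng.standard_normal((5, 16)) * 3, head)
        assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-6)
        # strictly inside (0,1) mathematically; float64 may round a
        # saturated entry to exactly 1.0
        assert np.all((a > 0) & (a <= 1.0))


def test_attention_matches_explicit_loop_oracle(rng):
    d, dk = 12, 8
    params = AttentionParams(n_bands=5, feature_dim=d, d_k=dk, d_v=dk)
    head = BandAttention(params, np.random.default_rng(3))
    x = rng.standard_normal((5, d))
    a = attention_map(x, head)

    q = x @ head.w_query.data.astype(float)
    k = x @ head.w_key.data.astype(float)
    oracle = np.empty((5, 5))
    for i in range(5):
        scores = np.array([np.dot(q[i], k[j]) / np.sqrt(dk) for j in range(5)])
        e = np.exp(scores - scores.max())
        oracle[i] = e / e.sum()
    assert np.allclose(a, oracle, atol=1e-10)


# ------------------------------------------------------------------ fusion

def test_fused_length_is_nb_d_plus_d(rng):
    head, params = _head(n_bands=5, d=62)
    x = rng.standard_normal((5, 62))
    z = refine_and_fuse(x, attention_map(x, head), head)
    assert z.shape == (5 * 62 + 62,)
    assert params.fused_dim == 372


def test_identity_wiring_recovers_input(rng):
    """A = I with identity value/output projections: X' = X, F_global = mean."""
    d = 6
    params = AttentionParams(n_bands=3, feature_dim=d)
    head = BandAttention(params, np.random.default_rng(0))
    head.w_value.data = np.eye(d, dtype=np.float32)
    head.out_proj.weight.data = np.eye(d, dtype=np.float32)
    head.out_proj.bias.data[:] = 0.0
    x = rng.standard_normal((3, d))
    z = refine_and_fuse(x, np.eye(3), head)
    assert np.allclose(z[: 3 * d], x.ravel(), atol=1e-6)
    assert np.allclose(z[3 * d :], x.mean(axis=0), atol=1e-6)


def test_global_feature_is_band_mean(rng):
    head, _ = _head(n_bands=4, d=10)
    x = rng.standard_normal((4, 10))
    a = attention_map(x, head)
    z = refine_and_fuse(x, a, head)
    # recompute X' explicitly and compare the mean-pooled tail
    v = x @ head.w_value.data.astype(float)
    x_ref = (a @ v) @ head.out_proj.weight.data.astype(float) \
        + head.out_proj.bias.data.astype(float)
    manual = sum(x_ref[i] for i in range(4)) / 4.0
    assert np.allclose(z[40:], manual, atol=1e-10)


def test_fusion_shape_mismatch_rejected(rng):
    head, _ = _head(n_bands=3, d=5)
    with pytest.raises(ValueError):
        refine_and_fuse(rng.standard_normal((3, 5)),
                        np.eye(4), head)


def test_single_head_parameter_census():
    """Exactly one (W_Q, W_K, W_V) triple in the band-attention head."""
    model = EmotionNet(n_classes=3,
                       backbone_config=BackboneConfig(n_nodes=8, top_k=4,
                                                      filter_sizes=(4, 8, 16),
                                                      graph_dim=4),
                       attention_params=AttentionParams(feature_dim=8))
    names = [n for n, _ in model.named_parameters()]
    assert sum("band_attention.w_query" in n for n in names) == 1
    assert sum("band_attention.w_key" in n for n in names) == 1
    assert sum("band_attention.w_value" in n for n in names) == 1


# -------------------------------------------------------------- classifier

def test_classifier_softmax_normalizes(rng):
    clf = Classifier(12, 3, np.random.default_rng(0))
    logits, labels = classify(rng.standard_normal((7, 12)), clf)
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert labels.shape == (7,)


def test_classifier_rejects_single_class():
    with pytest.raises(ValueError):
        Classifier(10, 1, np.random.default_rng(0))


def test_label_smoothing_convention():
    """target = (1 - eps) * onehot + eps / C."""
    t = label_smooth_targets(np.array([0, 2]), 3, epsilon=0.1)
    expected_on = 0.9 + 0.1 / 3
    expected_off = 0.1 / 3
    assert t[0, 0] == pytest.approx(expected_on)
    assert t[0, 1] == pytest.approx(expected_off)
    assert t[1, 2] == pytest.approx(expected_on)
    assert np.allclose(t.sum(axis=1), 1.0)


def test_cross_entropy_smoothed_matches_manual(rng):
    logits = rng.standard_normal((4, 3))
    targets = label_smooth_targets(np.array([0, 1, 2, 1]), 3, 0.1)
    loss = cross_entropy_smoothed(Tensor(logits), targets)
    logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    manual = -(targets * logp).sum() / 4
    assert float(loss.data) == pytest.approx(manual, abs=1e-10)


# ---------------------------------------------------------------- training

def _tiny_dataset():
    spec = LabeledFeatureSpec(seed=3, n_subjects=2, trials_per_subject=9,
                              n_channels=8, n_frames=8)
    return generate_labeled_features(spec)


def _tiny_model(n_classes=3, seed=0):
    return EmotionNet(
        n_classes=n_classes,
        backbone_config=BackboneConfig(n_nodes=8, top_k=4,
                                       filter_sizes=(4, 8, 16), graph_dim=4),
        attention_params=AttentionParams(feature_dim=8), seed=seed)


def test_training_loss_decreases_from_initialization():
    x, y, _ = _tiny_dataset()
    cfg = TrainConfig(epochs=8, batch_size=6, seed=0)
    _, hist = train_model(x, y, cfg, model=_tiny_model())
    assert hist.loss[-1] < hist.loss[0]


def test_training_deterministic_same_seed():
    x, y, _ = _tiny_dataset()
    cfg = TrainConfig(epochs=3, batch_size=6, seed=4)
    m1, _ = train_model(x, y, cfg, model=_tiny_model(seed=4))
    m2, _ = train_model(x, y, cfg, model=_tiny_model(seed=4))
    s1, s2 = m1.state_dict(), m2.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)


def test_default_train_config_matches_reference_recipe():
    m = TrainConfig().manifest()
    assert m["lr"] == 0.001 and m["batch"] == 64 and m["epochs"] == 200


def test_single_class_data_rejected():
    x, y, _ = _tiny_dataset()
    with pytest.raises(ValueError, match="single class"):
        train_model(x, np.zeros_like(y), TrainConfig(epochs=1))


def test_learns_separable_features_quickly():
    """Strongly separable two-subject set: high training accuracy quickly."""
    x, y, _ = _tiny_dataset()
    cfg = TrainConfig(epochs=20, batch_size=6, seed=1)
    model, hist = train_model(x, y, cfg, model=_tiny_model(seed=1))
    assert (predict(model, x) == y).mean() >= 0.9
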