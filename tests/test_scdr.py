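"""SCDR loss machinery: pairing, similarities, thrust and the contrastive loss."""

import numpy as np
import pytest

from bioumixer import (
    AugmentSpec,
    RegressionSample,
    SCDRConfig,
    classify_pairs,
    feature_similarity,
    label_similarity,
    make_augmented_batch,
    regression_loss,
    scdr_anchor_loss,
    scdr_batch_loss,
    thrust_weight,
    total_loss,
)
from bioumixer.autodiff import Tensor
from bioumixer.scdr import NEGATIVE, POSITIVE, SELF, UNPAIRED


# ---------------------------------------------------------------- reference
def scdr_loss_reference(embeddings, labels, predictions, cfg: SCDRConfig) -> float:
    """Independent nested-loop transcription of the per-anchor loss and its
    batch average, with explicit pair classification."""
    v = np.asarray(embeddings, dtype=np.float64)
    if cfg.normalize_embeddings:
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
    n = len(labels)
    total = 0.0
    for j in range(n):
        pos = [i for i in range(n) if i != j and abs(labels[i] - labels[j]) <= cfg.omega]
        neg = [q for q in range(n) if q != j and abs(labels[q] - labels[j]) > cfg.omega
               and abs(predictions[q] - predictions[j]) <= cfg.omega]
        if not neg:
            continue  # not an anchor: contributes 0
        num = 0.0
        for i in pos:
            num += np.exp(v[j] @ v[i] / cfg.tau)
        num /= len(pos)
        den = 0.0
        for p in pos:
            den += np.exp(v[j] @ v[p] / cfg.tau)
        for q in neg:
            sim_l = np.exp(-abs(labels[j] - labels[q]) / cfg.sigma_l)
            cos = v[j] @ v[q] / (np.linalg.norm(v[j]) * np.linalg.norm(v[q]))
            sim_f = max((1 + cos) / 2, cfg.eps_f)
            s = min(cfg.eta / (sim_l * sim_f), cfg.s_max)
            den += s * np.exp(v[j] @ v[q] / cfg.tau)
        total += -np.log(num / den)
    return total / n


def random_batch(seed, n_views=16, d_emb=16, label_range=(0.0, 100.0)):
    r = np.random.default_rng(seed)
    emb = r.normal(size=(n_views, d_emb))
    labels = np.repeat(r.uniform(*label_range, size=n_views // 2), 2)
    preds = labels + r.normal(0, 20.0, size=n_views)
    return emb, labels, preds


# ------------------------------------------------------------------ pairing
def test_sibling_views_are_positive_regardless_of_predictions():
    pairs = classify_pairs([10.0, 10.0], [0.0, 99.0], omega=1.0)
    assert pairs.status[0, 1] == POSITIVE
    assert not pairs.anchor_flags.any()


def test_dissimilar_labels_similar_predictions_are_negative_anchors():
    pairs = classify_pairs([0.0, 100.0], [50.0, 52.0], omega=5.0)
    assert pairs.status[0, 1] == NEGATIVE
    assert pairs.anchor_flags.all()


def test_dissimilar_labels_and_predictions_are_unpaired():
    labels = np.array([0.0, 100.0])
    preds = np.array([0.0, 100.0])
    pairs = classify_pairs(labels, preds, omega=5.0)
    assert pairs.status[0, 1] == UNPAIRED
    assert not pairs.anchor_flags.any()
    cfg = SCDRConfig(omega=5.0, sigma_l=10.0)
    loss, per_anchor, _ = scdr_batch_loss(Tensor(np.eye(2)), labels, preds, cfg)
    assert loss.data == 0.0 and (per_anchor == 0).all()


def test_pair_matrix_is_symmetric_with_self_diagonal():
    _, labels, preds = random_batch(3)
    pairs = classify_pairs(labels, preds, omega=10.0)
    assert (pairs.status == pairs.status.T).all()
    assert (np.diag(pairs.status) == SELF).all()
    for j in range(len(labels)):  # P+ and P- never overlap
        assert not set(pairs.positives[j]) & set(pairs.negatives[j])


@pytest.mark.parametrize("bad", [([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
                                 ([1.0, np.nan], [1.0, 2.0])])
def test_classify_pairs_rejects_odd_and_nan_input(bad):
    with pytest.raises(ValueError):
        classify_pairs(bad[0], bad[1], omega=1.0)


# ------------------------------------------------------------- similarities
def test_label_similarity_kernel():
    assert label_similarity(5.0, 5.0, sigma_l=2.0) == 1.0
    assert label_similarity(0.0, 2.0, sigma_l=2.0) == pytest.approx(np.exp(-1), rel=1e-12)
    assert label_similarity(0.0, 50.0, sigma_l=1e12) == pytest.approx(1.0, abs=1e-9)
    # strictly decreasing in the label gap
    gaps = [label_similarity(0.0, d, sigma_l=3.0) for d in (0.5, 1.0, 2.0, 4.0)]
    assert all(a > b for a, b in zip(gaps, gaps[1:]))
    with pytest.raises(ValueError):
        label_similarity(1.0, 2.0, sigma_l=0.0)


def test_feature_similarity_shifted_cosine():
    u = np.array([1.0, 2.0, 3.0])
    assert feature_similarity(u, 2 * u, eps_f=0.05) == pytest.approx(1.0)
    assert feature_similarity([1, 0], [0, 1], eps_f=0.05) == pytest.approx(0.5)
    assert feature_similarity(u, -u, eps_f=0.05) == pytest.approx(0.05)  # floored
    assert feature_similarity(u, -u, eps_f=0.05) == feature_similarity(-u, u, eps_f=0.05)
    with pytest.raises(ValueError):
        feature_similarity(np.zeros(3), u, eps_f=0.05)


def test_thrust_weight_form_and_cap():
    assert thrust_weight(0.0, 0.5, 0.5, s_max=100.0) == 0.0
    assert thrust_weight(0.01, 1.0, 1.0, s_max=100.0) == pytest.approx(0.01)
    assert thrust_weight(0.01, 0.5, 0.5, s_max=100.0) == pytest.approx(0.04)
    assert thrust_weight(10.0, 0.01, 0.01, s_max=100.0) == 100.0  # capped
    with pytest.raises(ValueError):
        thrust_weight(0.01, 1.5, 0.5, s_max=100.0)


# -------------------------------------------------------------------- loss
def test_anchor_loss_hand_case():
    """τ=1, one positive at dot 1, one negative at dot 0 with S=1:
    loss = −log(e/(e+1))."""
    emb = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    labels = np.array([0.0, 0.0, 100.0, 100.0])
    preds = np.array([50.0, 50.0, 50.0, 500.0])  # only view 2 is view 0's negative
    pairs = classify_pairs(labels, preds, omega=5.0)
    assert list(pairs.positives[0]) == [1] and list(pairs.negatives[0]) == [2]
    S = np.zeros((4, 4))
    S[pairs.status == NEGATIVE] = 1.0
    got = scdr_anchor_loss(0, emb, pairs, S, tau=1.0)
    assert got == pytest.approx(-np.log(np.e / (np.e + 1.0)), abs=1e-9)
    assert got == pytest.approx(0.31326168751822286, abs=1e-9)


def test_anchor_loss_zero_cases():
    emb, labels, preds = random_batch(5)
    pairs = classify_pairs(labels, preds, omega=200.0)  # everything positive
    S = np.zeros((16, 16))
    assert all(scdr_anchor_loss(j, emb, pairs, S, tau=0.5) == 0.0 for j in range(16))
    # a negative erased by zero thrust: -log(e^s / e^s) = 0
    emb2 = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    pairs2 = classify_pairs([0.0, 0.0, 9.0, 9.0], [1.0, 1.0, 1.0, 1.0], omega=2.0)
    got = scdr_anchor_loss(0, emb2, pairs2, np.zeros((4, 4)), tau=1.0)
    assert got == pytest.approx(0.0, abs=1e-12)


def test_batch_loss_matches_nested_loop_oracle():
    cfg = SCDRConfig(omega=10.0, sigma_l=25.0, tau=0.2, eta=0.01)
    for seed in range(20):
        n_views = int(np.random.default_rng(seed).integers(2, 17)) * 2
        emb, labels, preds = random_batch(seed, n_views=n_views, d_emb=16)
        loss, per_anchor, pairs = scdr_batch_loss(Tensor(emb), labels, preds, cfg)
        expect = scdr_loss_reference(emb, labels, preds, cfg)
        assert loss.data == pytest.approx(expect, rel=1e-9, abs=1e-12)
        # batch loss is exactly the mean of the per-view losses
        assert loss.data == pytest.approx(per_anchor.mean(), rel=1e-12)
        assert (per_anchor[~pairs.anchor_flags] == 0).all()
        assert (per_anchor >= -1e-12).all()


def test_zero_anchor_law_and_degenerate_batch():
    cfg = SCDRConfig(omega=50.0, sigma_l=10.0)
    emb = np.random.default_rng(0).normal(size=(6, 8))
    labels = np.array([10.0, 10.0, 20.0, 20.0, 30.0, 30.0])  # all within omega
    loss, per_anchor, _ = scdr_batch_loss(Tensor(emb), labels, labels, cfg)
    assert loss.data == 0.0 and (per_anchor == 0).all()
    # N=1: the two sibling views form one positive pair, no negatives
    loss1, _, _ = scdr_batch_loss(Tensor(emb[:2]), labels[:2], labels[:2], cfg)
    assert loss1.data == 0.0


def test_thrust_monotonicity_and_eta_zero_independence():
    cfg = SCDRConfig(omega=10.0, sigma_l=25.0, eta=0.01)
    emb, labels, preds = random_batch(8)
    base, _, pairs = scdr_batch_loss(Tensor(emb), labels, preds, cfg)
    assert pairs.anchor_flags.any()
    stronger = SCDRConfig(omega=10.0, sigma_l=25.0, eta=0.1)  # scales all S up
    more, _, _ = scdr_batch_loss(Tensor(emb), labels, preds, stronger)
    assert more.data >= base.data
    # eta = 0: loss ignores negative-pair embeddings entirely
    off = SCDRConfig(omega=10.0, sigma_l=25.0, eta=0.0)
    neg_views = {q for j in range(len(labels)) for q in pairs.negatives[j]}
    emb2 = emb.copy()
    for q in neg_views:
        emb2[q] += np.random.default_rng(1).normal(0, 0.5, emb.shape[1])
    # anchors whose own embedding moved change too, so compare per-view losses
    # of the views that are not negatives themselves
    _, pa0, _ = scdr_batch_loss(Tensor(emb), labels, preds, off)
    _, pa2, _ = scdr_batch_loss(Tensor(emb2), labels, preds, off)
    untouched = [j for j in range(len(labels)) if j not in neg_views]
    assert np.allclose(pa0[untouched], pa2[untouched])


def test_gradient_step_moves_pairs_as_intended():
    """One gradient step pulls the positive pair together and pushes the
    S-weighted negative pair apart (4-view toy batch)."""
    emb = np.array([[1.0, 0.2, 0.0], [0.9, 0.3, 0.1], [0.2, 1.0, 0.3], [0.1, 0.9, 0.2]])
    labels = np.array([10.0, 10.0, 500.0, 500.0])
    preds = np.array([100.0, 100.0, 101.0, 101.0])
    cfg = SCDRConfig(omega=50.0, sigma_l=100.0, tau=0.5, eta=1.0)

    def cosines(e):
        u = e / np.linalg.norm(e, axis=1, keepdims=True)
        return u[0] @ u[1], u[0] @ u[2]

    t = Tensor(emb, requires_grad=True)
    loss, _, pairs = scdr_batch_loss(t, labels, preds, cfg)
    assert pairs.status[0, 1] == POSITIVE and pairs.status[0, 2] == NEGATIVE
    loss.backward()
    stepped = emb - 0.05 * t.grad
    pos_before, neg_before = cosines(emb)
    pos_after, neg_after = cosines(stepped)
    assert pos_after > pos_before
    assert neg_after < neg_before


# -------------------------------------------------------- regression/total
def test_regression_loss_kinds():
    y = np.array([10.0, 20.0])
    assert regression_loss(y, y, "l1").data == 0.0
    assert regression_loss(y, y, "focal_l1").data == 0.0
    assert regression_loss(np.array([12.0, 18.0]), y, "l1").data == pytest.approx(2.0)
    with pytest.raises(ValueError):
        regression_loss(y, y, "huber")
    # focal/l1 ratio grows with the error magnitude (sigmoid weight ≥ 0.5)
    ratios = []
    for e in (0.1, 0.5, 1.0, 2.0, 5.0):
        pred = y + e
        ratios.append(float(regression_loss(pred, y, "focal_l1").data
                            / regression_loss(pred, y, "l1").data))
    assert all(b >= a for a, b in zip(ratios, ratios[1:]))
    assert all(0.5 <= r <= 1.0 for r in ratios)


def test_total_loss_weighting():
    assert total_loss(2.0, 0.5, alpha=1.0, beta=3.0) == pytest.approx(3.5)
    assert total_loss(2.0, 123.0, alpha=1.0, beta=0.0) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        total_loss(1.0, 1.0, alpha=-1.0, beta=0.0)


def test_config_validation():
    with pytest.raises(ValueError):
        SCDRConfig(tau=0.0)
    with pytest.raises(ValueError):
        SCDRConfig(eps_f=1.5)
    cfg = SCDRConfig().resolved(label_std=100.0)
    assert cfg.omega == pytest.approx(10.0)
    assert cfg.sigma_l == pytest.approx(25.0)


# ------------------------------------------------------------- augmentation
def _samples(n, seed=0):
    r = np.random.default_rng(seed)
    return [RegressionSample(image=r.random((72, 72, 3)), label=float(100 + 50 * i),
                             name=f"s{i}") for i in range(n)]


def test_augmented_batch_structure_and_determinism():
    spec = AugmentSpec(out_size=64)
    batch = make_augmented_batch(_samples(3), spec, rng_seed=9)
    assert batch.views.shape == (6, 3, 64, 64)
    np.testing.assert_array_equal(batch.source_index, [0, 0, 1, 1, 2, 2])
    np.testing.assert_array_equal(batch.labels, [100, 100, 150, 150, 200, 200])
    again = make_augmented_batch(_samples(3), spec, rng_seed=9)
    np.testing.assert_array_equal(batch.views, again.views)
    other = make_augmented_batch(_samples(3), spec, rng_seed=10)
    assert not np.array_equal(batch.views, other.views)
    # the two views of one source are distinct augmentations
    assert not np.array_equal(batch.views[0], batch.views[1])


def test_augmentation_rejects_bad_input():
    spec = AugmentSpec(out_size=64)
    with pytest.raises(ValueError):
        make_augmented_batch([], spec, rng_seed=0)
    small = [RegressionSample(image=np.random.default_rng(0).random((32, 32, 3)),
                              label=10.0)]
    with pytest.raises(ValueError):
        make_augmented_batch(small, spec, rng_seed=0)


def test_sibling_guarantee_after_augment_and_classify():
    spec = AugmentSpec(out_size=64)
    batch = make_augmented_batch(_samples(4, seed=3), spec, rng_seed=1)
    pairs = classify_pairs(batch.labels, np.zeros(8), omega=1.0)
    assert all(len(p) >= 1 for p in pairs.positives)
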