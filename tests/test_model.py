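"""Network forward pass, weighted loss, gradients, pretraining, training."""

import numpy as np
import pytest

from epifine.blocks import SplitAssignment
from epifine.features import generate_control_blocks
from epifine.model import (
    ModelConfig,
    ModelParams,
    compute_loss,
    evaluate,
    forward,
    init_params,
    loss_and_gradients,
    predict_snp_scores,
    pretrain_autoencoder,
    reconstruction_loss,
    train,
)

from .conftest import make_tensor


def small_config(m=6, k=3, **kw):
    return ModelConfig(feature_dim=m, n_filters=k, n_slots=4, **kw)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestInitParams:
    def test_deterministic_given_seed(self):
        cfg = small_config()
        a, b = init_params(cfg, 5), init_params(cfg, 5)
        assert np.array_equal(a.filter_bank, b.filter_bank)
        assert np.array_equal(a.combiner, b.combiner)

    def test_different_seeds_differ(self):
        cfg = small_config()
        assert not np.array_equal(init_params(cfg, 1).filter_bank, init_params(cfg, 2).filter_bank)

    def test_shapes_and_zero_biases(self):
        cfg = small_config(m=11, k=7)
        p = init_params(cfg)
        assert p.filter_bank.shape == (7, 11)
        assert p.combiner.shape == (7,)
        assert (p.filter_bias == 0).all() and p.combiner_bias == 0.0


class TestForward:
    def test_zero_combiner_gives_half(self):
        p = ModelParams(np.ones((2, 3)), np.zeros(2), np.zeros(2), 0.0)
        res = forward(p, np.ones((1, 2, 3)), np.ones((1, 2), dtype=bool))
        assert np.allclose(res.per_snp_scores, 0.5)
        assert res.per_block_score[0] == 0.5

    def test_hand_computed_score(self):
        # filters pick out features 0 and 1; x = [1,1,0] activates both,
        # combiner sums them: score = sigmoid(2)
        p = ModelParams(np.array([[1.0, 0, 0], [0, 1.0, 0]]), np.zeros(2),
                        np.array([1.0, 1.0]), 0.0)
        res = forward(p, np.array([[[1.0, 1.0, 0.0]]]), np.ones((1, 1), dtype=bool))
        assert res.per_block_score[0] == pytest.approx(sigmoid(2.0), abs=1e-12)
        assert res.per_block_score[0] == pytest.approx(0.8808, abs=5e-5)

    def test_masked_slot_is_inert(self):
        p = ModelParams(np.ones((2, 3)), np.zeros(2), np.array([5.0, 5.0]), 0.0)
        x1 = np.array([[[1, 0, 0]]], dtype=float)
        x2 = np.array([[[1, 0, 0], [0, 0, 0]]], dtype=float)
        r1 = forward(p, x1, np.array([[True]]))
        r2 = forward(p, x2, np.array([[True, False]]))
        assert r1.per_block_score[0] == r2.per_block_score[0]
        assert np.isnan(r2.per_snp_scores[0, 1])

    def test_block_score_is_max_over_unmasked(self):
        p = ModelParams(np.eye(3), np.zeros(3), np.array([4.0, 2.0, 1.0]), 0.0)
        x = np.eye(3)[None]  # three one-hot SNPs
        res = forward(p, x, np.ones((1, 3), dtype=bool))
        assert res.per_block_score[0] == res.per_snp_scores[0].max()
        assert res.per_block_score[0] == pytest.approx(sigmoid(4.0))

    def test_dimension_mismatch(self):
        p = ModelParams(np.ones((2, 3)), np.zeros(2), np.zeros(2), 0.0)
        with pytest.raises(ValueError):
            forward(p, np.ones((1, 2, 5)), np.ones((1, 2), dtype=bool))


class TestComputeLoss:
    def test_weighted_hand_case(self):
        # one true case at f = 0.5 with W = 10 and no penalty: 10 * ln 2
        cfg = small_config(m=3, k=2, lambda1=0.0, lambda2=0.0)
        p = ModelParams(np.zeros((2, 3)), np.zeros(2), np.zeros(2), 0.0)
        loss = compute_loss(p, np.ones((1, 1, 3)), np.ones((1, 1), dtype=bool),
                            np.array([1]), np.array([10.0]), cfg)
        assert loss == pytest.approx(10 * np.log(2), abs=1e-9)

    def test_confident_correct_prediction_loss_near_zero(self):
        cfg = small_config(m=2, k=1, lambda1=0.0, lambda2=0.0)
        p = ModelParams(np.full((1, 2), 20.0), np.zeros(1), np.array([20.0]), 0.0)
        loss = compute_loss(p, np.ones((1, 1, 2)), np.ones((1, 1), dtype=bool),
                            np.array([1]), np.array([10.0]), cfg)
        assert loss < 1e-5

    def test_l1_penalty_isolation(self):
        cfg0 = small_config(m=3, k=2, lambda1=0.0, lambda2=0.0)
        cfg1 = small_config(m=3, k=2, lambda1=1.0, lambda2=0.0)
        rng = np.random.default_rng(0)
        p = ModelParams(rng.normal(size=(2, 3)), rng.normal(size=2), rng.normal(size=2), 0.3)
        x, m = np.ones((1, 1, 3)), np.ones((1, 1), dtype=bool)
        y, w = np.array([1]), np.array([2.0])
        diff = compute_loss(p, x, m, y, w, cfg1) - compute_loss(p, x, m, y, w, cfg0)
        assert diff == pytest.approx(np.abs(p.filter_bank).sum() + np.abs(p.combiner).sum(), abs=1e-12)

    def test_extreme_scores_clamped_never_nan(self):
        cfg = small_config(m=2, k=1, lambda1=0.0, lambda2=0.0)
        p = ModelParams(np.full((1, 2), 500.0), np.zeros(1), np.array([500.0]), 0.0)
        loss = compute_loss(p, np.ones((1, 1, 2)), np.ones((1, 1), dtype=bool),
                            np.array([0]), np.array([2.0]), cfg)
        assert np.isfinite(loss)

    def test_larger_weight_increases_contribution(self):
        cfg = small_config(m=2, k=1, lambda1=0.0, lambda2=0.0)
        p = ModelParams(np.ones((1, 2)) * 0.2, np.zeros(1), np.array([0.5]), 0.0)
        x, m = np.ones((1, 1, 2)), np.ones((1, 1), dtype=bool)
        low = compute_loss(p, x, m, np.array([1]), np.array([2.0]), cfg)
        high = compute_loss(p, x, m, np.array([1]), np.array([10.0]), cfg)
        assert high > low


def finite_difference_grads(params, x, mask, y, w, cfg, h=1e-6):
    grads = ModelParams(np.zeros_like(params.filter_bank), np.zeros_like(params.filter_bias),
                        np.zeros_like(params.combiner), 0.0)

    def loss_with(p):
        return compute_loss(p, x, mask, y, w, cfg)

    for arr, garr in ((params.filter_bank, grads.filter_bank),
                      (params.filter_bias, grads.filter_bias),
                      (params.combiner, grads.combiner)):
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + h
            up = loss_with(params)
            arr[i] = orig - h
            down = loss_with(params)
            arr[i] = orig
            garr[i] = (up - down) / (2 * h)
    orig = params.combiner_bias
    params.combiner_bias = orig + h
    up = loss_with(params)
    params.combiner_bias = orig - h
    down = loss_with(params)
    params.combiner_bias = orig
    grads.combiner_bias = (up - down) / (2 * h)
    return grads


def assert_grads_close(analytic, numeric, rtol=1e-5):
    for a, n in ((analytic.filter_bank, numeric.filter_bank),
                 (analytic.filter_bias, numeric.filter_bias),
                 (analytic.combiner, numeric.combiner)):
        denom = np.maximum(np.abs(n), 1e-4)
        assert (np.abs(a - n) / denom).max() < rtol
    assert abs(analytic.combiner_bias - numeric.combiner_bias) < rtol * max(
        abs(numeric.combiner_bias), 1e-4
    )


@pytest.mark.parametrize("seed", range(5))
def test_analytic_gradients_match_finite_differences(seed):
    """Backprop through max-pool/ReLU/sigmoid against central differences."""
    rng = np.random.default_rng(seed)
    k, m, n, b = rng.integers(1, 6), rng.integers(2, 21), rng.integers(1, 5), rng.integers(1, 6)
    cfg = ModelConfig(feature_dim=int(m), n_filters=int(k), n_slots=int(n),
                      lambda1=float(rng.choice([0.0, 1e-3])), lambda2=float(rng.choice([0.0, 1e-3])))
    params = ModelParams(rng.normal(0, 0.5, (k, m)), rng.normal(0, 0.2, k),
                         rng.normal(0, 0.5, k), float(rng.normal(0, 0.2)))
    x = (rng.random((b, n, m)) < 0.5).astype(float)
    mask = np.ones((b, n), dtype=bool)
    for i in range(b):
        mask[i, rng.integers(1, n + 1):] = False
    y = rng.integers(0, 2, b)
    w = rng.choice([2.0, 4.0, 6.0, 8.0, 10.0], b)
    loss, analytic = loss_and_gradients(params, x, mask, y, w, cfg)
    assert loss == pytest.approx(compute_loss(params, x, mask, y, w, cfg), rel=1e-12)
    numeric = finite_difference_grads(params, x, mask, y, w, cfg)
    assert_grads_close(analytic, numeric)


class TestAutoencoder:
    def test_reconstruction_improves_on_low_rank_data(self, rng):
        # 20 binary vectors spanning 3 patterns, K = 3 filters: the DAE
        # must cut reconstruction loss by at least 10x from its random init
        patterns = (rng.random((3, 12)) < 0.5).astype(float)
        data = patterns[rng.integers(0, 3, 20)]
        cfg = ModelConfig(feature_dim=12, n_filters=3, ae_corruption=0.0,
                          ae_epochs=800, learning_rate=0.5, seed=3)
        w0 = init_params(cfg).filter_bank
        w = pretrain_autoencoder(data, cfg)
        assert reconstruction_loss(w, data) < reconstruction_loss(w0, data) / 10

    def test_deterministic_and_shaped(self, rng):
        data = (rng.random((15, 8)) < 0.4).astype(float)
        cfg = ModelConfig(feature_dim=8, n_filters=4, ae_epochs=5, seed=11)
        a, b = pretrain_autoencoder(data, cfg), pretrain_autoencoder(data, cfg)
        assert a.shape == (4, 8)
        assert np.array_equal(a, b)

    def test_empty_input_rejected(self):
        cfg = ModelConfig(feature_dim=8, n_filters=4)
        with pytest.raises(ValueError):
            pretrain_autoencoder(np.empty((0, 8)), cfg)


def planted_dataset(rng, n_blocks=12, n_snps=6, n_feat=20, n_causal=5):
    """Tiny planted-signal tensors: one feature-dense SNP per true block."""
    values = (rng.random((n_blocks, n_snps, n_feat)) < 0.05).astype(np.uint8)
    for b in range(n_blocks):
        slot = rng.integers(n_snps)
        values[b, slot, :n_causal] = rng.random(n_causal) < 0.9
    # spread over training (1-10) and validation (15-22) chromosomes
    chroms = [str(b % 8 + 1) if b % 3 else str(b % 8 + 15) for b in range(n_blocks)]
    tensor = make_tensor(values, chroms=chroms, weights=np.full(n_blocks, 10.0))
    ctrl = generate_control_blocks(tensor, ratio=5, seed=int(rng.integers(2**31)))
    return tensor, ctrl


class TestTrain:
    def test_loss_decreases_on_planted_signal(self, rng):
        tensor, ctrl = planted_dataset(rng)
        cfg = ModelConfig(feature_dim=tensor.n_features, n_filters=8, max_epochs=60,
                          patience=60, n_restarts=1, seed=2)
        params, report = train(tensor, ctrl, cfg)
        assert report.train_losses[-1] < report.train_losses[0]
        assert report.stopped_epoch <= cfg.max_epochs
        assert report.best_epoch <= report.stopped_epoch

    def test_deterministic_given_config(self, rng):
        tensor, ctrl = planted_dataset(rng)
        cfg = ModelConfig(feature_dim=tensor.n_features, n_filters=6, max_epochs=15,
                          patience=15, n_restarts=2, seed=5)
        p1, r1 = train(tensor, ctrl, cfg)
        p2, r2 = train(tensor, ctrl, cfg)
        assert np.array_equal(p1.filter_bank, p2.filter_bank)
        assert r1.train_losses == r2.train_losses
        assert r1.best_val_loss == r2.best_val_loss

    def test_empty_split_rejected(self, rng):
        tensor, ctrl = planted_dataset(rng, n_blocks=2)  # chroms 1-2 only
        cfg = ModelConfig(feature_dim=tensor.n_features, n_filters=4)
        with pytest.raises(ValueError, match="nonempty"):
            train(tensor, ctrl, cfg,
                  SplitAssignment(train=frozenset({"1", "2"}),
                                  validation=frozenset({"21"}),
                                  test=frozenset({"22"})))


class TestEvaluate:
    def _tensor_with_scores(self, params_score_pairs):
        pass

    def test_perfect_separation(self):
        # single feature drives the score; true blocks carry it, controls not
        p = ModelParams(np.array([[8.0]]), np.zeros(1), np.array([8.0]), -4.0)
        values = np.array([[[1]], [[1]], [[0]], [[0]]], dtype=np.uint8)
        tensor = make_tensor(values, labels=np.array([1, 1, 0, 0]))
        metrics = evaluate(p, tensor)
        assert metrics["auc"] == 1.0 and metrics["f1"] == 1.0

    def test_identical_scores_auc_half(self):
        p = ModelParams(np.zeros((1, 1)), np.zeros(1), np.zeros(1), 0.0)
        values = np.zeros((4, 1, 1), dtype=np.uint8)
        tensor = make_tensor(values, labels=np.array([1, 1, 0, 0]))
        assert evaluate(p, tensor)["auc"] == 0.5

    def test_single_class_rejected(self):
        p = ModelParams(np.zeros((1, 1)), np.zeros(1), np.zeros(1), 0.0)
        tensor = make_tensor(np.zeros((2, 1, 1), dtype=np.uint8), labels=np.array([1, 1]))
        with pytest.raises(ValueError):
            evaluate(p, tensor)


class TestPredictSnpScores:
    def test_scores_match_forward_and_max(self, random_tensor):
        cfg = ModelConfig(feature_dim=random_tensor.n_features, n_filters=4)
        params = init_params(cfg, 9)
        df = predict_snp_scores(params, random_tensor)
        assert len(df) == int(random_tensor.mask.sum())
        res = forward(params, random_tensor.values, random_tensor.mask)
        per_block_max = df.groupby("block_id", sort=False).score.max()
        for i, bid in enumerate(random_tensor.block_ids):
            assert per_block_max[bid] == pytest.approx(res.per_block_score[i], abs=1e-12)

    def test_empty_tensor(self):
        tensor = make_tensor(np.zeros((0, 3, 2), dtype=np.uint8))
        cfg = ModelConfig(feature_dim=2, n_filters=2)
        assert predict_snp_scores(init_params(cfg, 0), tensor).empty

    def test_invariant_to_block_order(self, random_tensor):
        cfg = ModelConfig(feature_dim=random_tensor.n_features, n_filters=4)
        params = init_params(cfg, 9)
        shuffled = random_tensor.select_blocks(list(range(random_tensor.n_blocks))[::-1])
        a = predict_snp_scores(params, random_tensor).set_index(["block_id", "snp_id"]).score
        b = predict_snp_scores(params, shuffled).set_index(["block_id", "snp_id"]).score
        assert a.sort_index().equals(b.sort_index())

    def test_feature_axis_mismatch(self, random_tensor):
        cfg = ModelConfig(feature_dim=random_tensor.n_features + 1, n_filters=4)
        with pytest.raises(ValueError, match="features"):
            predict_snp_scores(init_params(cfg, 0), random_tensor)
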