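"""Row-scoring U-Net: contracts, training behaviour, CV selection, persistence."""

from dataclasses import replace

import numpy as np
import pytest

from pulmotrunk import PhantomParams, generate_cohort
from pulmotrunk.geometry import ScoutImage
from pulmotrunk.localizer import (
    NetConfig,
    build_network,
    cross_validate_lr,
    load_model,
    predict,
    save_model,
    slice_hit_accuracy,
    train,
)
from pulmotrunk import _nn

TINY = NetConfig(depth=3, base_channels=4, epochs=2, seed=1)


class TestBuild:
    def test_output_is_one_score_per_row(self, rng):
        model = build_network(NetConfig(seed=0), 128, 64)
        x = rng.random((3, 1, 128, 64)).astype(np.float32)
        z = model.net.forward(x)
        assert z.shape == (3, 128)

    def test_scores_strictly_inside_unit_interval(self, rng, default_params):
        from pulmotrunk.phantom import generate_phantom

        model = build_network(NetConfig(seed=0), 128, 64)
        case = generate_phantom(default_params, seed=8)
        pred = predict(model, case.image)
        assert np.all(pred.scores > 0.0) and np.all(pred.scores < 1.0)

    def test_equal_seed_gives_identical_initial_weights(self):
        a = build_network(NetConfig(seed=5), 64, 32)
        b = build_network(NetConfig(seed=5), 64, 32)
        for pa, pb in zip(a.net.params, b.net.params):
            assert np.array_equal(pa, pb)

    def test_indivisible_dimensions_rejected(self):
        with pytest.raises(ValueError):
            build_network(NetConfig(depth=3), 100, 64)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetConfig(epochs=0)
        with pytest.raises(ValueError):
            NetConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            NetConfig(threshold=1.5)


class TestBackprop:
    def test_analytic_gradients_match_finite_differences(self, rng):
        """Directional derivatives along random directions vs backprop.

        Aggregate directional checks keep the signal well above float32
        finite-difference noise, and jittering the parameters away from
        zero keeps preactivations off the ReLU kink, where the loss is
        genuinely non-differentiable and finite differences would see
        subgradient noise.
        """
        cfg = NetConfig(seed=3, depth=2, base_channels=4)
        model = build_network(cfg, 16, 8)
        for p in model.net.params:
            jitter = rng.uniform(0.05, 0.3, p.shape) * np.sign(rng.standard_normal(p.shape))
            p += jitter.astype(np.float32)
        x = rng.random((2, 1, 16, 8)).astype(np.float32)
        y = (rng.random((2, 16)) > 0.7).astype(np.float64)
        z = model.net.forward(x.copy())
        _, dz = _nn.bce_with_logits(z, y)
        model.net.backward(dz)
        grads = [g.copy() for g in model.net.grads]
        params = model.net.params

        def loss_at():
            zz = model.net.forward(x.copy())
            return _nn.bce_with_logits(zz, y)[0]

        eps = 1e-3
        for _ in range(5):
            dirs = [rng.standard_normal(p.shape).astype(np.float32) for p in params]
            norm = np.sqrt(sum(float((d**2).sum()) for d in dirs))
            dirs = [d / norm for d in dirs]
            for p, d in zip(params, dirs):
                p += eps * d
            lp = loss_at()
            for p, d in zip(params, dirs):
                p -= 2 * eps * d
            lm = loss_at()
            for p, d in zip(params, dirs):
                p += eps * d
            numeric = (lp - lm) / (2 * eps)
            analytic = sum(float((g * d).sum()) for g, d in zip(grads, dirs))
            assert numeric == pytest.approx(analytic, rel=0.05, abs=2e-4)


class TestTrain:
    def test_history_length_equals_epochs(self, small_cohort):
        cfg = replace(TINY, epochs=1)
        model = train(build_network(cfg, 128, 64), small_cohort[:8], cfg)
        assert len(model.history) == 1

    def test_empty_cohort_rejected(self):
        cfg = TINY
        with pytest.raises(ValueError):
            train(build_network(cfg, 128, 64), [], cfg)

    def test_loss_decreases_over_training(self, small_cohort):
        cfg = replace(TINY, epochs=8, seed=2)
        model = train(build_network(cfg, 128, 64), small_cohort, cfg)
        assert model.history[-1] < model.history[0]

    def test_fixed_seed_reproduces_loss_history(self, small_cohort):
        cfg = replace(TINY, epochs=2, seed=9)
        h1 = train(build_network(cfg, 128, 64), small_cohort[:12], cfg).history
        h2 = train(build_network(cfg, 128, 64), small_cohort[:12], cfg).history
        assert h1 == h2

    def test_case_order_does_not_change_the_contract(self, default_params):
        """Reversing cohort order leaves held-out accuracy within tolerance (0.25)."""
        cohort = generate_cohort(default_params, 60, seed=31)
        heldout = generate_cohort(default_params, 30, seed=32)
        cfg = replace(TINY, base_channels=8, epochs=10, seed=4)
        acc_fwd = slice_hit_accuracy(train(build_network(cfg, 128, 64), cohort, cfg), heldout)
        acc_rev = slice_hit_accuracy(
            train(build_network(cfg, 128, 64), cohort[::-1], cfg), heldout
        )
        assert abs(acc_fwd - acc_rev) <= 0.25


class TestPredict:
    def test_inference_is_deterministic(self, small_cohort):
        cfg = replace(TINY, epochs=1)
        model = train(build_network(cfg, 128, 64), small_cohort[:8], cfg)
        p1 = predict(model, small_cohort[0].image)
        p2 = predict(model, small_cohort[0].image)
        assert np.array_equal(p1.scores, p2.scores)
        assert p1.region == p2.region and p1.center_row == p2.center_row

    def test_prediction_satisfies_band_invariants(self, small_cohort, rng):
        model = build_network(NetConfig(seed=1), 128, 64)
        img = ScoutImage(rng.random((128, 64)).astype(np.float32))
        pred = predict(model, img)  # RegionPrediction validates derivability
        assert pred.region.contains(pred.center_row)

    def test_dimension_mismatch_rejected(self, rng):
        model = build_network(NetConfig(seed=1), 128, 64)
        with pytest.raises(ValueError):
            predict(model, ScoutImage(rng.random((64, 64)).astype(np.float32)))


class TestCrossValidation:
    def test_single_candidate_is_selected(self, tiny_cohort):
        cfg = NetConfig(depth=2, base_channels=4, epochs=1, seed=1)
        report = cross_validate_lr(tiny_cohort, [3e-4], k=2, config=cfg, seed=0)
        assert report.selected_lr == 3e-4

    def test_folds_are_balanced_and_disjoint(self, tiny_cohort):
        # 16 cases, 5 folds -> sizes 4,3,3,3,3
        indices = np.random.default_rng(0).permutation(16)
        folds = np.array_split(indices, 5)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds)) == list(range(16))

    def test_pathological_learning_rate_is_not_selected(self, tiny_cohort):
        cfg = NetConfig(depth=2, base_channels=8, epochs=12, seed=1,
                        max_shift_rows=2, batch_size=8)
        report = cross_validate_lr(tiny_cohort, [10.0, 1e-3], k=2, config=cfg, seed=3)
        assert report.selected_lr == 1e-3

    def test_fewer_cases_than_folds_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            cross_validate_lr(tiny_cohort[:3], [1e-3], k=5, config=TINY, seed=0)
        with pytest.raises(ValueError):
            cross_validate_lr(tiny_cohort, [], k=2, config=TINY, seed=0)


class TestPersistence:
    def test_checkpoint_round_trip_preserves_predictions(self, small_cohort, tmp_path):
        cfg = replace(TINY, epochs=1)
        model = train(build_network(cfg, 128, 64), small_cohort[:8], cfg)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.history == model.history
        assert loaded.config == model.config
        p1 = predict(model, small_cohort[0].image)
        p2 = predict(loaded, small_cohort[0].image)
        assert np.array_equal(p1.scores, p2.scores)
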