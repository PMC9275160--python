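import numpy as np
import pytest
from dataclasses import replace

from jointcal import (TrainConfig, classification_metrics,
                      in_batch_cross_validation, predict, train_joint)
from jointcal.losses import (KernelConfig, LossWeights, calibration_loss_grad,
                             discrimination_loss_grad, reconstruction_loss_grad)
from jointcal.networks import init_model
from jointcal.training import train_config_from_yaml


def params_of(model):
    return [p.copy() for s in model.stacks() for _, _, p in s.parameters()]


class TestJointTrainingStep:
    def test_full_objective_gradient_matches_finite_differences(self, rng):
        """The hand-derived backward pass of the entire joint objective
        (batch norm through calibrator, both decoders, classifier, MMD)
        agrees with central finite differences."""
        import jointcal as jc

        d = 4
        model = init_model(d, 3)
        X1 = rng.normal(1.0, 1.0, (6, d))
        X2 = rng.normal(0.5, 1.2, (5, d))
        y1 = rng.integers(0, 2, 6).astype(float)
        kernel = KernelConfig(bandwidths=(0.7, 2.3))
        w = LossWeights(0.7, 1.3, 0.9)
        model.calibrator.layers[0].momentum = 0.0  # freeze buffers for FD

        def objective():
            Z1, _ = model.calibrator.forward(X1, training=True)
            Z2, _ = model.calibrator.forward(X2, training=True)
            X1p, _ = model.reconstructor_1.forward(Z1)
            X2p, _ = model.reconstructor_2.forward(Z2)
            p, _ = model.discriminator.forward(Z1)
            p = np.clip(p.ravel(), 1e-12, 1 - 1e-12)
            lr = jc.reconstruction_loss(X1, X1p) + jc.reconstruction_loss(X2, X2p)
            return w.alpha * lr + w.beta * jc.calibration_loss(Z1, Z2, kernel) \
                + w.gamma * jc.discrimination_loss(p, y1)

        for s in model.stacks():
            s.zero_grad()
        Z1, c1 = model.calibrator.forward(X1, training=True)
        Z2, c2 = model.calibrator.forward(X2, training=True)
        X1p, r1c = model.reconstructor_1.forward(Z1)
        X2p, r2c = model.reconstructor_2.forward(Z2)
        p_raw, dc = model.discriminator.forward(Z1)
        p = np.clip(p_raw.ravel(), 1e-12, 1 - 1e-12)
        _, gX1p = reconstruction_loss_grad(X1, X1p)
        _, gX2p = reconstruction_loss_grad(X2, X2p)
        _, gZ1c, gZ2c = calibration_loss_grad(Z1, Z2, kernel)
        _, gp = discrimination_loss_grad(p, y1)
        gZ1 = w.beta * gZ1c + model.reconstructor_1.backward(r1c, w.alpha * gX1p)
        gZ2 = w.beta * gZ2c + model.reconstructor_2.backward(r2c, w.alpha * gX2p)
        gZ1 += model.discriminator.backward(dc, (w.gamma * gp).reshape(p_raw.shape))
        model.calibrator.backward(c1, gZ1)
        model.calibrator.backward(c2, gZ2)

        eps = 1e-6
        checked = 0
        fd_rng = np.random.default_rng(0)
        for stack in model.stacks():
            for layer in stack.layers:
                for name, P in layer.params.items():
                    flat = P.reshape(-1)
                    G = layer.grads[name].reshape(-1)
                    for idx in fd_rng.choice(flat.size, size=min(4, flat.size),
                                             replace=False):
                        old = flat[idx]
                        flat[idx] = old + eps
                        up = objective()
                        flat[idx] = old - eps
                        dn = objective()
                        flat[idx] = old
                        assert G[idx] == pytest.approx((up - dn) / (2 * eps),
                                                       rel=1e-4, abs=1e-7)
                        checked += 1
        assert checked > 30


class TestTrainJoint:
    def test_loss_decreases_and_trace_is_finite(self, tiny_sim, fast_cfg):
        source, target, _ = tiny_sim
        cfg = replace(fast_cfg, epochs=40)
        model, report = train_joint(source, target.without_labels(), cfg)
        trace = report.trace
        assert len(trace) == cfg.epochs
        assert np.isfinite(trace[["loss_r", "loss_c", "loss_d"]].to_numpy()).all()
        assert trace["loss_total"].iloc[-1] < trace["loss_total"].iloc[0]

    def test_bitwise_reproducible_under_seed(self, tiny_sim, fast_cfg):
        source, target, _ = tiny_sim
        m1, r1 = train_joint(source, target.without_labels(), fast_cfg)
        m2, r2 = train_joint(source, target.without_labels(), fast_cfg)
        for p1, p2 in zip(params_of(m1), params_of(m2)):
            np.testing.assert_array_equal(p1, p2)
        assert r1.trace.equals(r2.trace)

    def test_target_labels_never_consumed(self, tiny_sim, fast_cfg):
        source, target, _ = tiny_sim
        m1, _ = train_joint(source, target, fast_cfg)            # labels present
        m2, _ = train_joint(source, target.without_labels(), fast_cfg)
        for p1, p2 in zip(params_of(m1), params_of(m2)):
            np.testing.assert_array_equal(p1, p2)

    def test_gamma_zero_total_excludes_classifier_term(self, tiny_sim, fast_cfg):
        source, target, _ = tiny_sim
        cfg = replace(fast_cfg, epochs=3,
                      weights=LossWeights(1.0, 1.0, 0.0))
        _, report = train_joint(source, target.without_labels(), cfg)
        t = report.trace
        assert (t["loss_d"] > 0).all()  # still recorded
        np.testing.assert_allclose(t["loss_total"], t["loss_r"] + t["loss_c"],
                                   rtol=1e-12)

    def test_classifier_only_training_ignores_target_values(self, tiny_sim, fast_cfg):
        """With alpha=beta=0 the unlabeled batch cannot influence the
        learned parameters (supervised-classifier degeneration)."""
        source, target, _ = tiny_sim
        cfg = replace(fast_cfg, epochs=5, weights=LossWeights(0.0, 0.0, 1.0))
        perturbed = target.without_labels()
        m1, _ = train_joint(source, perturbed, cfg)
        shifted = replace_values(perturbed, perturbed.values + 37.0)
        m2, _ = train_joint(source, shifted, cfg)
        for p1, p2 in zip(params_of(m1), params_of(m2)):
            np.testing.assert_array_equal(p1, p2)

    def test_feature_mismatch_and_missing_labels_rejected(self, tiny_sim, fast_cfg):
        source, target, _ = tiny_sim
        with pytest.raises(ValueError, match="labels"):
            train_joint(source.without_labels(), target, fast_cfg)
        narrower = source.subset(np.arange(source.n_samples))
        narrower.values = narrower.values[:, :-1]
        narrower.feature_ids = narrower.feature_ids[:-1]
        with pytest.raises(ValueError, match="feature"):
            train_joint(source, narrower, fast_cfg)


def replace_values(table, new_values):
    from jointcal import FeatureTable
    return FeatureTable(new_values, table.feature_ids, table.sample_ids,
                        table.subject_ids, table.batch_id, table.labels)


class TestPredict:
    def test_thresholding(self, rng):
        model = init_model(4, 0)
        X = rng.normal(size=(20, 4))
        p, labels = predict(model, X, threshold=0.5)
        np.testing.assert_array_equal(labels, (p >= 0.5).astype(int))
        _, strict = predict(model, X, threshold=1.0 - 1e-12)
        assert strict.sum() == 0  # sigmoid never reaches 1 exactly

    def test_row_permutation_equivariance(self, rng):
        model = init_model(4, 1)
        X = rng.normal(size=(15, 4))
        perm = rng.permutation(15)
        p, _ = predict(model, X)
        p_perm, _ = predict(model, X[perm])
        np.testing.assert_allclose(p_perm, p[perm], rtol=1e-12)


class TestCrossValidation:
    def test_separable_batch_scores_high(self, fast_cfg):
        from jointcal import SimConfig, generate_two_batches
        cfg_sim = SimConfig(n_features=8, n_subjects_per_batch=60,
                            replicates_per_subject=(1, 1), signal_fraction=0.5,
                            class_effect=3.0, batch_shift=0.0, batch_scale=0.0,
                            nonlinear_warp=0.0, noise_sd=0.3, subject_sd=0.2,
                            seed=11)
        batch, _, _ = generate_two_batches(cfg_sim)
        cfg = replace(fast_cfg, epochs=150)
        report = in_batch_cross_validation(batch, folds=3, cfg=cfg)
        assert report.acc >= 0.95
        assert report.n == batch.n_samples

    def test_fold_count_and_seed_determinism(self, tiny_sim, fast_cfg):
        source, _, _ = tiny_sim
        cfg = replace(fast_cfg, epochs=2)
        r1 = in_batch_cross_validation(source, folds=2, cfg=cfg)
        r2 = in_batch_cross_validation(source, folds=2, cfg=cfg)
        assert r1 == r2

    def test_invalid_folds(self, tiny_sim, fast_cfg):
        source, _, _ = tiny_sim
        with pytest.raises(ValueError):
            in_batch_cross_validation(source, folds=1, cfg=fast_cfg)


class TestTrainConfig:
    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "weights: {alpha: 0.5, beta: 2.0, gamma: 1.0}\n"
            "kernel: {kind: multiscale_gaussian, bandwidth_multipliers: [1.0, 4.0]}\n"
            "epochs: 7\nminibatch_size: 16\nlearning_rate: 0.01\nseed: 9\n")
        cfg = train_config_from_yaml(p)
        assert cfg.weights == LossWeights(0.5, 2.0, 1.0)
        assert cfg.kernel.bandwidth_multipliers == (1.0, 4.0)
        assert (cfg.epochs, cfg.minibatch_size, cfg.seed) == (7, 16, 9)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(minibatch_size=1)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(decision_threshold=1.5)
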