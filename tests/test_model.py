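import numpy as np
import pytest

from jpresskit.model import (JpressNet, ModelConfig, receptive_field_extent)
from jpresskit.training import composite_loss


def tiny_config(**kw):
    defaults = dict(n_te=4, n_points=64, feature_dim=6, dilation_depth=3,
                    pab_window=8, n_blocks=2, n_components=3)
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_model():
    return JpressNet(tiny_config(), seed=0)


def random_input(cfg, batch=2, seed=1):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((batch, cfg.n_te, cfg.n_points, 2)).astype(np.float32)


class TestConfig:
    def test_full_size_defaults(self):
        cfg = ModelConfig()
        assert cfg.max_dilation == 256
        assert cfg.pab_window == 64
        assert cfg.n_components == 12
        assert (cfg.n_te, cfg.n_points, cfg.feature_dim) == (32, 2048, 128)
        assert cfg.dilations == [2, 4, 8, 16, 32, 64, 128, 256]

    def test_pab_window_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(pab_window=0)
        with pytest.raises(ValueError):
            ModelConfig(pab_window=4096)


class TestEncoder:
    def test_wavenet_preserves_sequence_length(self, tiny_model):
        cfg = tiny_model.cfg
        x = np.random.default_rng(0).standard_normal(
            (cfg.n_points, 2)).astype(np.float32)
        feats = tiny_model.wavenet_features(x)
        assert feats.shape == (cfg.n_points, cfg.feature_dim)

    def test_wavenet_rejects_wrong_length(self, tiny_model):
        with pytest.raises(ValueError, match="length"):
            tiny_model.wavenet_features(np.zeros((10, 2), dtype=np.float32))

    def test_gru_fuse_preserves_shape_and_order_matters(self, tiny_model):
        cfg = tiny_model.cfg
        rng = np.random.default_rng(1)
        feats = rng.standard_normal(
            (cfg.n_te, cfg.n_points, cfg.feature_dim)).astype(np.float32)
        out = tiny_model.gru_fuse(feats)
        assert out.shape == feats.shape
        out_perm = tiny_model.gru_fuse(feats[::-1].copy())
        assert not np.allclose(out[-1], out_perm[0])

    def test_gru_fuse_rejects_unsorted_te(self, tiny_model):
        feats = np.zeros((4, 64, 6), dtype=np.float32)
        with pytest.raises(ValueError, match="ascending"):
            tiny_model.gru_fuse(feats, te_values=np.array([0.05, 0.04, 0.06, 0.07]))

    def test_pab_examples(self, tiny_model):
        f = tiny_model.cfg.feature_dim
        const = np.full((64, f), 3.25, dtype=np.float32)
        np.testing.assert_allclose(tiny_model.pab(const), 3.25, rtol=1e-6)
        zeros_then_junk = np.zeros((64, f), dtype=np.float32)
        zeros_then_junk[8:] = 99.0
        np.testing.assert_array_equal(tiny_model.pab(zeros_then_junk), 0.0)

    def test_pab_full_window_is_global_average(self, tiny_model):
        rng = np.random.default_rng(2)
        feats = rng.standard_normal((64, 6)).astype(np.float32)
        np.testing.assert_allclose(tiny_model.pab(feats, window=64),
                                   feats.mean(axis=0), rtol=1e-5)

    def test_pab_window_validation(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.pab(np.zeros((64, 6)), window=0)
        with pytest.raises(ValueError):
            tiny_model.pab(np.zeros((64, 6)), window=65)

    def test_encode_shapes_and_jpress_is_mean(self, tiny_model):
        cfg = tiny_model.cfg
        te_reps, jpress = tiny_model.encode(random_input(cfg))
        assert te_reps.shape == (2, cfg.n_te, cfg.feature_dim)
        assert jpress.shape == (2, cfg.feature_dim)
        np.testing.assert_allclose(jpress, te_reps.mean(axis=1), atol=1e-6)

    def test_receptive_field_locality(self):
        """Samples beyond pab_window + receptive-field extent cannot reach
        the representations."""
        cfg = tiny_config(n_points=128, dilation_depth=3, n_blocks=2,
                          pab_window=8)
        model = JpressNet(cfg, seed=3)
        extent = receptive_field_extent(cfg)   # 2 blocks x (2+4+8) = 28
        boundary = cfg.pab_window + extent
        assert boundary < cfg.n_points
        x = random_input(cfg, batch=1, seed=4)
        reps, jp = model.encode(x)
        x2 = x.copy()
        x2[:, :, boundary:, :] += 5.0
        reps2, jp2 = model.encode(x2)
        np.testing.assert_array_equal(reps, reps2)
        np.testing.assert_array_equal(jp, jp2)
        # control: perturbing inside the window does change them
        x3 = x.copy()
        x3[:, :, 0, :] += 5.0
        reps3, _ = model.encode(x3)
        assert np.any(reps3 != reps)


class TestHeadsAndDecoder:
    def test_head_shapes(self, tiny_model):
        cfg = tiny_model.cfg
        rng = np.random.default_rng(5)
        te_reps = rng.standard_normal((2, cfg.n_te, cfg.feature_dim)).astype(np.float32)
        jpress = te_reps.mean(axis=1)
        conc, t2, amp = tiny_model.heads(te_reps, jpress)
        assert conc.shape == (2, cfg.n_components)
        assert t2.shape == (2, cfg.n_components)
        assert amp.shape == (2, cfg.n_te, cfg.n_components)

    def test_amplitude_head_is_per_te_local(self, tiny_model):
        cfg = tiny_model.cfg
        rng = np.random.default_rng(6)
        te_reps = rng.standard_normal((1, cfg.n_te, cfg.feature_dim)).astype(np.float32)
        jpress = te_reps.mean(axis=1)
        _, _, amp = tiny_model.heads(te_reps, jpress)
        te_reps2 = te_reps.copy()
        te_reps2[:, 1, :] += 1.0
        _, _, amp2 = tiny_model.heads(te_reps2, jpress)
        np.testing.assert_array_equal(amp[:, 0], amp2[:, 0])
        np.testing.assert_array_equal(amp[:, 2:], amp2[:, 2:])
        assert np.any(amp[:, 1] != amp2[:, 1])

    def test_decoder_output_shape_and_missing_skip_error(self, tiny_model):
        cfg = tiny_model.cfg
        x = random_input(cfg, batch=1)
        rng = np.random.default_rng(7)
        blocks = [rng.standard_normal(
            (1, cfg.n_te, cfg.n_points, cfg.feature_dim)).astype(np.float32)
            for _ in range(cfg.n_blocks)]
        te_reps = rng.standard_normal(
            (1, cfg.n_te, cfg.feature_dim)).astype(np.float32)
        recon = tiny_model.decode(x, blocks, te_reps)
        assert recon.shape == (1, cfg.n_components, cfg.n_te, cfg.n_points, 2)
        with pytest.raises(ValueError, match="every encoder block"):
            tiny_model.decode(x, blocks[:-1], te_reps)
        with pytest.raises(ValueError, match="TE-specific"):
            tiny_model.decode(x, blocks, None)

    def test_background_estimate_is_always_defined(self, tiny_model):
        from jpresskit.sensitivity import extract_background
        cfg = tiny_model.cfg
        x = random_input(cfg, batch=1)
        pred = tiny_model.predict(x)
        fid = x[0, ..., 0] + 1j * x[0, ..., 1]
        bg = extract_background(fid, pred.reconstructed_fids[0])
        assert bg.shape == (cfg.n_te, cfg.n_points)
        assert np.all(np.isfinite(bg.real)) and np.all(np.isfinite(bg.imag))


class TestPredictions:
    def test_prediction_shapes_and_scaling(self, tiny_model):
        cfg = tiny_model.cfg
        pred = tiny_model.predict(random_input(cfg, batch=3))
        assert pred.concentrations.shape == (3, cfg.n_components)
        assert pred.avg_t2.shape == (3, cfg.n_components)
        assert pred.first_point_amplitudes.shape == (3, cfg.n_te, cfg.n_components)
        assert pred.reconstructed_fids.shape == (3, cfg.n_components, cfg.n_te,
                                                 cfg.n_points)
        assert np.iscomplexobj(pred.reconstructed_fids)

    def test_negative_clipping_at_predict_time(self, tiny_model):
        cfg = tiny_model.cfg
        x = random_input(cfg, batch=4, seed=9)
        clipped = tiny_model.predict(x, clip_negative=True)
        raw = tiny_model.predict(x, clip_negative=False)
        assert np.all(clipped.concentrations >= 0)
        assert np.all(clipped.first_point_amplitudes >= 0)
        np.testing.assert_allclose(np.maximum(raw.concentrations, 0),
                                   clipped.concentrations, rtol=1e-6)

    def test_forward_deterministic(self, tiny_model):
        cfg = tiny_model.cfg
        x = random_input(cfg)
        p1 = tiny_model.predict(x)
        p2 = tiny_model.predict(x)
        np.testing.assert_array_equal(p1.concentrations, p2.concentrations)

    def test_parameter_count_independent_of_batch(self, tiny_model):
        n = tiny_model.n_parameters()
        tiny_model.predict(random_input(tiny_model.cfg, batch=5))
        assert tiny_model.n_parameters() == n
        assert n > 0


class TestPersistence:
    def test_save_load_round_trip(self, tiny_model, tmp_path):
        path = tmp_path / "model.h5"
        tiny_model.save(path)
        back = JpressNet.load(path)
        x = random_input(tiny_model.cfg)
        np.testing.assert_array_equal(tiny_model.predict(x).concentrations,
                                      back.predict(x).concentrations)
        assert back.cfg.n_components == tiny_model.cfg.n_components


class TestEndToEndGradients:
    def test_full_model_gradient_check(self):
        """Directional finite-difference check through the whole network
        with a smooth quadratic objective."""
        cfg = tiny_config()
        model = JpressNet(cfg, seed=0)
        rng = np.random.default_rng(1)
        x = random_input(cfg)

        def loss():
            out = model._forward(x)
            val = 0.5 * sum(float((out[k] ** 2).sum())
                            for k in ("conc", "t2", "amp", "recon"))
            return val, out

        _, out = loss()
        for p in model.params():
            p.zero_grad()
        model._backward({k: out[k].astype(np.float32)
                         for k in ("conc", "t2", "amp", "recon")})
        dirs = [rng.standard_normal(p.v.shape).astype(np.float32) * 0.01
                for p in model.params()]
        analytic = sum(float((p.g * d).sum())
                       for p, d in zip(model.params(), dirs))
        eps = 0.1
        for p, d in zip(model.params(), dirs):
            p.v += eps * d
        lp, _ = loss()
        for p, d in zip(model.params(), dirs):
            p.v -= 2 * eps * d
        lm, _ = loss()
        for p, d in zip(model.params(), dirs):
            p.v += eps * d
        numeric = (lp - lm) / (2 * eps)
        assert numeric == pytest.approx(analytic, rel=2e-3)

    def test_composite_loss_backward_runs(self):
        cfg = tiny_config()
        model = JpressNet(cfg, seed=0)
        x = random_input(cfg)
        rng = np.random.default_rng(3)
        labels = {
            "conc": rng.uniform(0, 1, (2, 3)).astype(np.float32),
            "t2": rng.uniform(0, 1, (2, 3)).astype(np.float32),
            "amp": rng.uniform(0, 1, (2, cfg.n_te, 3)).astype(np.float32),
            "recon": rng.standard_normal(
                (2, 3, cfg.n_te, cfg.n_points, 2)).astype(np.float32),
        }
        out = model._forward(x)
        total, terms, grads = composite_loss(out, labels)
        assert total > 0 and set(terms) == {"conc", "t2", "amp", "recon"}
        model._backward(grads)
        assert any(np.any(p.g != 0) for p in model.params())
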