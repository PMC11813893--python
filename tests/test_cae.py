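import numpy as np
import pytest

from wcos import nn
from wcos.cae import CAE, CAEConfig, reconstruction_loss, train_cae
from wcos.windowing import Sample

TINY = CAEConfig(channels=(2, 3), kernel_size=6, stride=3, padding=2, pooled_steps=2, seed=1)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng, monkeypatch):
        """Analytic gradients of the full encoder-decoder-L1 stack agree with
        central finite differences (float64 for meaningful step sizes)."""
        monkeypatch.setattr(nn, "DTYPE", np.float64)
        model = CAE(TINY, 60)
        model.train_mode(True)
        X = rng.standard_normal((4, 60)) * 0.5

        fm, _ = model.encode(X)
        xhat = model.decode(fm)
        _, grad = nn.l1_loss(X, xhat)
        nn.Adam.zero_grads(model.gradients())
        model._backward(grad)
        analytic = [g.copy() for g in model.gradients()]

        eps, worst = 1e-6, 0.0
        for pi, p in enumerate(model.parameters()):
            flat = p.ravel()
            for ix in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[ix]
                flat[ix] = orig + eps
                lp, _ = nn.l1_loss(X, model.decode(model.encode(X)[0]))
                flat[ix] = orig - eps
                lm, _ = nn.l1_loss(X, model.decode(model.encode(X)[0]))
                flat[ix] = orig
                num = (lp - lm) / (2 * eps)
                ana = analytic[pi].ravel()[ix]
                worst = max(worst, abs(num - ana) / max(1e-8, abs(num) + abs(ana)))
        assert worst < 1e-5


class TestEncodeDecode:
    def test_latent_length_is_pooled_steps_times_channels(self):
        cfg = CAEConfig(channels=(32, 64), seed=0)
        model = CAE(cfg, 20_000)
        _, latent = model.encode(np.zeros(20_000))
        assert latent.shape == (1, 4 * 64)  # T0 x j = 256

    def test_eval_mode_deterministic(self, rng):
        model = CAE(TINY, 100)
        x = rng.standard_normal((3, 100))
        _, a = model.encode(x)
        _, b = model.encode(x)
        np.testing.assert_array_equal(a, b)

    def test_nonzero_input_changes_latent(self, rng):
        model = CAE(TINY, 100)
        _, z0 = model.encode(np.zeros(100))
        _, z1 = model.encode(rng.standard_normal(100))
        assert not np.allclose(z0, z1)

    @pytest.mark.parametrize("length", [100, 101])
    def test_decode_restores_length_and_tanh_range(self, rng, length):
        model = CAE(TINY, length)
        fm, _ = model.encode(rng.standard_normal((2, length)))
        xhat = model.decode(fm)
        assert xhat.shape == (2, length)
        assert np.all(np.abs(xhat) < 1.0)

    def test_incompatible_length_names_padding(self):
        model = CAE(TINY, 100)
        with pytest.raises(ValueError, match="pad input by 3"):
            model.encode(np.zeros(97))

    def test_mismatched_feature_maps_rejected(self, rng):
        model = CAE(TINY, 100)
        with pytest.raises(ValueError, match="feature-map"):
            model.decode(rng.standard_normal((1, 5, 7)))


class TestReconstructionLoss:
    def test_identity_constant_offset_and_nonnegativity(self, rng):
        X = rng.standard_normal((4, 50))
        assert reconstruction_loss(X, X) == 0.0
        c = 0.37
        assert reconstruction_loss(X, X + c) == pytest.approx(c, rel=1e-6)
        assert reconstruction_loss(X, rng.standard_normal((4, 50))) >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 4)), np.zeros((2, 5)))


class TestTrainCAE:
    def test_loss_descends_and_is_reproducible(self, rng):
        X = np.tanh(0.5 * rng.standard_normal((48, 300)))
        cfg = CAEConfig(channels=(2, 4), kernel_size=6, stride=3, padding=2,
                        pooled_steps=2, epochs=8, seed=3)
        _, r1 = train_cae(X, cfg)
        _, r2 = train_cae(X, cfg)
        assert r1.final_loss < r1.epoch_losses[0]
        assert r1.epoch_losses == r2.epoch_losses

    def test_abnormal_sample_rejected(self):
        bad = Sample(values=np.zeros(300), label="abnormal", record_id="x", start_s=0.0)
        with pytest.raises(ValueError, match="abnormal"):
            train_cae([bad], CAEConfig())

    def test_checkpoint_round_trip(self, rng, tmp_path):
        X = np.tanh(0.5 * rng.standard_normal((16, 300)))
        cfg = CAEConfig(channels=(2, 4), kernel_size=6, stride=3, padding=2,
                        pooled_steps=2, epochs=2, seed=5)
        model, _ = train_cae(X, cfg)
        path = tmp_path / "cae.npz"
        model.save(path)
        loaded = CAE.load(path)
        _, a = model.encode(X)
        _, b = loaded.encode(X)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(model.reconstruct(X), loaded.reconstruct(X))


class TestSeparation:
    def test_abnormal_windows_reconstruct_worse(self, tiny_windows):
        """Trained on normal windows only, mean reconstruction error on held-out
        abnormal windows exceeds that on held-out normal windows."""
        _, normal, abnormal = tiny_windows
        train, held_normal = normal[:-6], normal[-6:]
        cfg = CAEConfig(channels=(4, 8), epochs=10, seed=2)
        model, _ = train_cae(train, cfg)
        err = lambda group: np.mean(
            [reconstruction_loss(s.values[None], model.reconstruct(s.values)) for s in group]
        )
        assert err(abnormal[:6]) > err(held_normal)
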