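"""NT-Xent loss, fusion, and contrastive training."""

import math

import numpy as np
import pytest

from mscontab.autodiff import Tensor
from mscontab.contrastive import (
    TrainConfig,
    _nt_xent_loss_tensor,
    cosine_similarity,
    fuse_embeddings,
    nt_xent_anchor_loss,
    nt_xent_batch_loss,
    train_ms_contab,
)


def brute_force_anchor_loss(i, Z, tau, denominator="anchor"):
    """Independent scalar-arithmetic double loop over the batch."""
    two_n = Z.shape[0]
    j = (i + two_n // 2) % two_n

    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    excl = i if denominator == "anchor" else j
    num = math.exp(cos(Z[i], Z[j]) / tau)
    den = sum(math.exp(cos(Z[i], Z[k]) / tau)
              for k in range(two_n) if k != excl)
    return -math.log(num / den)


def brute_force_batch_loss(Zg, Zc, tau):
    Z = np.vstack([Zg, Zc])
    return float(np.mean([brute_force_anchor_loss(i, Z, tau)
                          for i in range(Z.shape[0])]))


class TestCosineSimilarity:
    def test_canonical_values(self):
        u = np.array([0.3, -1.2, 4.0])
        assert cosine_similarity(u, u) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 0], [-1, 0]) == pytest.approx(-1.0)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])


class TestNtXent:
    def test_single_pair_identical_views_zero_loss(self):
        z = np.array([[0.6, 0.8]])
        batch = np.vstack([z, z])
        assert nt_xent_anchor_loss(0, batch, tau=0.5) == pytest.approx(0.0)

    def test_worked_two_pair_fixture(self):
        # two cohorts with perfectly aligned orthogonal views:
        # L = -log(e^2 / (e^2 + 2)) for every anchor at tau = 0.5
        Zg = np.array([[1.0, 0.0], [0.0, 1.0]])
        Zc = Zg.copy()
        expected = -math.log(math.exp(2) / (math.exp(2) + 2))
        assert expected == pytest.approx(0.2395, abs=5e-5)
        batch = np.vstack([Zg, Zc])
        for i in range(4):
            assert nt_xent_anchor_loss(i, batch, 0.5) == pytest.approx(expected)
        assert nt_xent_batch_loss(Zg, Zc, 0.5) == pytest.approx(expected)

    def test_identical_embeddings_give_uniform_softmax(self):
        # all 2N similarities equal -> loss = log(2N - 1); N = 4 -> log 7
        u = np.array([0.6, 0.8])
        Z = np.tile(u, (4, 1))
        assert nt_xent_batch_loss(Z, Z, 0.5) == pytest.approx(math.log(7))

    def test_vectorized_equals_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            d = int(rng.choice([2, 64]))
            Zg = rng.normal(size=(n, d))
            Zc = rng.normal(size=(n, d))
            expected = brute_force_batch_loss(Zg, Zc, 0.5)
            assert nt_xent_batch_loss(Zg, Zc, 0.5) == pytest.approx(
                expected, abs=1e-6)
            tensor_loss = float(_nt_xent_loss_tensor(
                Tensor(Zg), Tensor(Zc), 0.5).data)
            assert tensor_loss == pytest.approx(expected, abs=1e-6)

    def test_printed_denominator_variant(self, rng):
        Z = rng.normal(size=(6, 4))
        Zg, Zc = Z[:3], Z[3:]
        batch = np.vstack([Zg, Zc])
        for i in range(6):
            assert nt_xent_anchor_loss(
                i, batch, 0.5, denominator="positive") == pytest.approx(
                brute_force_anchor_loss(i, batch, 0.5, "positive"), abs=1e-9)

    def test_batch_loss_permutation_invariant(self, rng):
        Zg = rng.normal(size=(5, 8))
        Zc = rng.normal(size=(5, 8))
        perm = rng.permutation(5)
        assert nt_xent_batch_loss(Zg, Zc, 0.5) == pytest.approx(
            nt_xent_batch_loss(Zg[perm], Zc[perm], 0.5))

    def test_raising_negative_similarity_raises_loss(self):
        base = np.array([[1.0, 0.0], [0.0, 1.0]])
        Zc = base.copy()
        loose = nt_xent_batch_loss(base, Zc, 0.5)
        # move cohort 2 toward cohort 1: its views become harder negatives
        tight_g = np.array([[1.0, 0.0], [0.5, np.sqrt(0.75)]])
        tight = nt_xent_batch_loss(tight_g, Zc, 0.5)
        assert tight > loose
        i_loss_before = nt_xent_anchor_loss(0, np.vstack([base, Zc]), 0.5)
        i_loss_after = nt_xent_anchor_loss(0, np.vstack([tight_g, Zc]), 0.5)
        assert i_loss_after > i_loss_before

    def test_temperature_limit(self, rng):
        Zg = rng.normal(size=(4, 6))
        Zc = rng.normal(size=(4, 6))
        assert nt_xent_batch_loss(Zg, Zc, 1e8) == pytest.approx(
            math.log(7), abs=1e-6)

    def test_anchor_loss_nonnegative(self, rng):
        Zg = rng.normal(size=(4, 5))
        Zc = rng.normal(size=(4, 5))
        batch = np.vstack([Zg, Zc])
        assert all(nt_xent_anchor_loss(i, batch, 0.5) >= 0 for i in range(8))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nt_xent_anchor_loss(0, np.ones((4, 2)), tau=0.0)
        with pytest.raises(ValueError):
            nt_xent_batch_loss(np.ones((3, 2)), np.ones((4, 2)))

    def test_tensor_loss_gradient_matches_finite_differences(self, rng):
        Zg0 = rng.normal(size=(3, 4))
        Zc = Tensor(rng.normal(size=(3, 4)))
        t = Tensor(Zg0.copy(), requires_grad=True)
        loss = _nt_xent_loss_tensor(t, Zc, 0.5)
        loss.backward()
        eps = 1e-6
        num = np.zeros_like(Zg0)
        for i in range(3):
            for j in range(4):
                for s, sign in ((eps, 1), (-eps, -1)):
                    Zp = Zg0.copy()
                    Zp[i, j] += s
                    num[i, j] += sign * float(
                        _nt_xent_loss_tensor(Tensor(Zp), Zc, 0.5).data)
        np.testing.assert_allclose(t.grad, num / (2 * eps), atol=1e-5)


class TestFusion:
    def test_identical_views_mean_mode(self):
        u = np.array([[3.0, 4.0]])
        np.testing.assert_allclose(fuse_embeddings(u, u, "mean"),
                                   [[0.6, 0.8]])

    def test_orthogonal_views_mean_mode(self):
        u = np.array([[1.0, 0.0]])
        v = np.array([[0.0, 1.0]])
        np.testing.assert_allclose(fuse_embeddings(u, v, "mean"),
                                   [[1 / np.sqrt(2), 1 / np.sqrt(2)]])

    def test_concat_mode_dimension(self, rng):
        Zg = rng.normal(size=(5, 64))
        Zc = rng.normal(size=(5, 64))
        assert fuse_embeddings(Zg, Zc, "concat").shape == (5, 128)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            fuse_embeddings(np.ones((2, 2)), np.ones((2, 2)), "max")


class TestTraining:
    def test_loss_decreases_and_embeddings_shapes(self, small_views):
        cfg = TrainConfig(epochs=30, seed=42)
        model, emb = train_ms_contab(small_views, cfg=cfg)
        n = small_views.n_cohorts
        assert emb.Zg.shape == (n, 64) and emb.Zc.shape == (n, 64)
        assert emb.Z_fused.shape == (n, 64)
        np.testing.assert_allclose(np.linalg.norm(emb.Z_fused, axis=1), 1.0)
        assert len(emb.loss_history) == 30
        assert emb.loss_history[-1] < emb.loss_history[0]

    def test_seeded_reproducibility_bit_identical(self, small_views):
        cfg = TrainConfig(epochs=5, seed=42)
        _, e1 = train_ms_contab(small_views, cfg=cfg)
        _, e2 = train_ms_contab(small_views, cfg=cfg)
        np.testing.assert_array_equal(e1.Z_fused, e2.Z_fused)
        assert e1.loss_history == e2.loss_history

    def test_too_few_cohorts_raises(self, small_views):
        import dataclasses

        tiny = dataclasses.replace(
            small_views, cohorts=small_views.cohorts[:2],
            Xg=small_views.Xg[:2], Xc=small_views.Xc[:2])
        with pytest.raises(ValueError):
            train_ms_contab(tiny)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(temperature=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=1)

    def test_checkpoint_roundtrip(self, small_views, tmp_path):
        from mscontab.contrastive import MsConTabModel

        cfg = TrainConfig(epochs=2, seed=0)
        model, emb = train_ms_contab(small_views, cfg=cfg)
        model.save(tmp_path / "ckpt")
        again = MsConTabModel.load(tmp_path / "ckpt")
        emb2 = again.embed(small_views)
        np.testing.assert_array_equal(emb.Z_fused, emb2.Z_fused)
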