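"""Augmentation determinism, the NT-Xent loss against a brute-force oracle,
and desk-scale encoder training on two-texture data."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from gasmil.contrastive import (AugmentationPolicy, ContrastiveError, EncoderConfig,
                                Encoder, embed, load_encoder, make_views, nt_xent_loss,
                                save_embeddings, load_embeddings, save_encoder,
                                train_encoder)
from gasmil.tiling import Patch, TileRef


def nt_xent_oracle(z, tau):
    """Direct double-loop NT-Xent summation (independent of the implementation)."""
    z = np.asarray(z, float)
    two_n = len(z)
    n = two_n // 2
    zn = z / np.linalg.norm(z, axis=1, keepdims=True)
    total = 0.0
    for i in range(two_n):
        pos = i + n if i < n else i - n
        num = np.exp(zn[i] @ zn[pos] / tau)
        den = sum(np.exp(zn[i] @ zn[j] / tau) for j in range(two_n) if j != i)
        total += -np.log(num / den)
    return total / two_n


IDENTITY = AugmentationPolicy(rotation_choices=(0,), rotation_jitter_deg=0,
                              brightness=0, contrast=0, saturation=0, hue=0,
                              crop_scale=(1.0, 1.0), flip_prob=0)


def texture_patch(seed, kind, mpp=0.5):
    rng = np.random.default_rng(seed)
    if kind == "stripes":
        base = (np.sin(np.arange(224) / 4.0)[None, :, None] * 60 + 150)
        px = np.clip(base + rng.normal(0, 10, (224, 224, 3)), 0, 255)
        px[..., 2] *= 0.6
    else:
        px = np.clip(rng.normal(200, 8, (224, 224, 3)), 0, 255)
        px[..., 1] *= 0.8
    return Patch(TileRef(f"p{seed}", mpp, 0, 0), px.astype(np.uint8))


class TestMakeViews:
    def test_identity_policy_returns_patch(self):
        p = texture_patch(0, "stripes")
        a, b = make_views(p, IDENTITY, seed=1)
        assert np.array_equal(a, p.pixels)
        assert np.array_equal(b, p.pixels)

    def test_same_seed_same_pair(self):
        p = texture_patch(1, "plain")
        pol = AugmentationPolicy()
        a1, b1 = make_views(p, pol, seed=9)
        a2, b2 = make_views(p, pol, seed=9)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)
        a3, _ = make_views(p, pol, seed=10)
        assert not np.array_equal(a1, a3)

    def test_pure_90_degree_rotation_is_exact(self):
        p = texture_patch(2, "stripes")
        pol = AugmentationPolicy(rotation_choices=(90,), rotation_jitter_deg=0,
                                 brightness=0, contrast=0, saturation=0, hue=0,
                                 crop_scale=(1.0, 1.0), flip_prob=0)
        a, _ = make_views(p, pol, seed=0)
        assert np.array_equal(a, np.rot90(p.pixels))


class TestNTXent:
    def test_identical_projections_give_ln3(self):
        assert nt_xent_loss(np.ones((4, 8)), 0.5) == pytest.approx(np.log(3), abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            z = rng.normal(size=(16, 12))
            assert nt_xent_loss(z, 0.5) == pytest.approx(nt_xent_oracle(z, 0.5), abs=1e-6)

    def test_colinear_positives_orthogonal_negatives_small_tau(self):
        z = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], float)
        assert nt_xent_loss(z, 0.01) < 1e-6

    def test_invariant_under_global_rotation(self, rng):
        z = rng.normal(size=(8, 6))
        q = ortho_group.rvs(6, random_state=0)
        assert nt_xent_loss(z @ q, 0.5) == pytest.approx(nt_xent_loss(z, 0.5), abs=1e-9)

    def test_invariant_under_pair_permutation(self, rng):
        z = rng.normal(size=(8, 6))
        perm = rng.permutation(4)
        zp = np.concatenate([z[:4][perm], z[4:][perm]])
        assert nt_xent_loss(zp, 0.5) == pytest.approx(nt_xent_loss(z, 0.5), abs=1e-9)

    def test_zero_norm_vector_rejected(self):
        z = np.ones((4, 3))
        z[1] = 0
        with pytest.raises(ContrastiveError, match="zero-norm"):
            nt_xent_loss(z, 0.5)

    def test_small_batch_rejected(self):
        with pytest.raises(ContrastiveError):
            nt_xent_loss(np.ones((2, 3)), 0.5)


@pytest.fixture(scope="module")
def trained_encoder():
    patches = [texture_patch(i, "stripes" if i % 2 else "plain") for i in range(24)]
    cfg = EncoderConfig(backbone="small-cnn", embed_dim=16, projection_dim=8, mpp=0.5)
    policy = AugmentationPolicy(rotation_jitter_deg=0, crop_scale=(0.8, 1.0))
    enc, log = train_encoder(patches, cfg, policy, epochs=4, batch_size=8, seed=0)
    return patches, enc, log


class TestTrainEncoder:
    def test_loss_decreases_on_easy_textures(self, trained_encoder):
        _, _, log = trained_encoder
        assert len(log) == 4
        assert log[-1] < log[0]

    def test_epochs_zero_returns_init_and_empty_log(self):
        patches = [texture_patch(i, "plain") for i in range(8)]
        cfg = EncoderConfig(backbone="small-cnn", embed_dim=8, projection_dim=4, mpp=0.5)
        enc, log = train_encoder(patches, cfg, IDENTITY, epochs=0, batch_size=4, seed=5)
        ref = Encoder(cfg, seed=5)
        assert log == []
        assert all(np.array_equal(enc.state_dict()[k], ref.state_dict()[k])
                   for k in enc.state_dict())

    def test_same_seed_same_trajectory(self):
        patches = [texture_patch(i, "stripes" if i % 2 else "plain") for i in range(8)]
        cfg = EncoderConfig(backbone="small-cnn", embed_dim=8, projection_dim=4, mpp=0.5)
        pol = AugmentationPolicy(rotation_jitter_deg=0)
        _, log1 = train_encoder(patches, cfg, pol, epochs=2, batch_size=4, seed=3)
        _, log2 = train_encoder(patches, cfg, pol, epochs=2, batch_size=4, seed=3)
        assert log1 == log2

    def test_tiny_batch_rejected(self):
        patches = [texture_patch(i, "plain") for i in range(8)]
        cfg = EncoderConfig(backbone="small-cnn", embed_dim=8, projection_dim=4, mpp=0.5)
        with pytest.raises(ContrastiveError, match="batch_size"):
            train_encoder(patches, cfg, IDENTITY, epochs=1, batch_size=2)


class TestEmbed:
    def test_shape_and_determinism(self, trained_encoder):
        patches, enc, _ = trained_encoder
        recs = embed(patches[:3] + patches[:1], enc)
        assert len(recs) == 4
        assert all(r.vector.shape == (16,) for r in recs)
        assert np.array_equal(recs[0].vector, recs[3].vector)

    def test_within_class_similarity_beats_between(self, trained_encoder):
        patches, enc, _ = trained_encoder
        recs = embed(patches, enc)
        v = np.stack([r.vector for r in recs])
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        sim = v @ v.T
        stripe = np.arange(len(patches)) % 2 == 1
        within = (sim[np.ix_(stripe, stripe)].mean() + sim[np.ix_(~stripe, ~stripe)].mean()) / 2
        between = sim[np.ix_(stripe, ~stripe)].mean()
        assert within > between

    def test_mpp_mismatch_rejected(self, trained_encoder):
        _, enc, _ = trained_encoder
        with pytest.raises(ContrastiveError, match="MPP"):
            embed([texture_patch(0, "plain", mpp=2.0)], enc)

    def test_embedding_storage_roundtrip(self, trained_encoder, tmp_path):
        patches, enc, _ = trained_encoder
        recs = embed(patches[:4], enc)
        save_embeddings(tmp_path / "e", recs)
        back = load_embeddings(tmp_path / "e")
        assert all(np.array_equal(a.vector, b.vector) for a, b in zip(recs, back))
        assert all(a.ref == b.ref for a, b in zip(recs, back))

    def test_encoder_storage_roundtrip(self, trained_encoder, tmp_path):
        patches, enc, _ = trained_encoder
        save_encoder(tmp_path / "enc", enc)
        enc2 = load_encoder(tmp_path / "enc")
        r1 = embed(patches[:2], enc)
        r2 = embed(patches[:2], enc2)
        assert np.array_equal(r1[0].vector, r2[0].vector)
        assert enc.encoder_id == enc2.encoder_id
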