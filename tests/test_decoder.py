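"""Image-level causal mask, masked attention, decoder causality, head."""

import math

import numpy as np
import pytest

from icseg.datamodel import BinaryMask, EpisodeSequence, ImageSlice
from icseg.decoder import (
    ProbabilityMap,
    SegmentationModel,
    binarize,
    build_image_level_mask,
    build_token_level_mask,
    masked_attention,
)
from icseg.encoder import ModelConfig


def brute_force_mask(image_count: int, s: int) -> np.ndarray:
    """Entrywise evaluation of the 1-based rule M[i,j] = 1 iff j <= ceil(i/s)*s."""
    S = image_count * s
    M = np.zeros((S, S), dtype=np.uint8)
    for i in range(1, S + 1):
        for j in range(1, S + 1):
            if j <= math.ceil(i / s) * s:
                M[i - 1, j - 1] = 1
    return M


class TestImageLevelMask:
    @pytest.mark.parametrize("image_count", range(1, 7))
    @pytest.mark.parametrize("s", [1, 2, 3, 4, 9, 16])
    def test_matches_brute_force(self, image_count, s):
        M = build_image_level_mask(image_count, s).M
        assert (M == brute_force_mask(image_count, s)).all()

    def test_s1_is_standard_causal_triangle(self):
        M = build_image_level_mask(3, 1).M
        assert (M == np.array([[1, 0, 0], [1, 1, 0], [1, 1, 1]])).all()

    def test_s2_two_images_visibility(self):
        M = build_image_level_mask(2, 2).M
        assert (M == np.array([[1, 1, 0, 0], [1, 1, 0, 0], [1, 1, 1, 1], [1, 1, 1, 1]])).all()

    def test_diagonal_always_visible(self):
        for ic, s in [(1, 5), (4, 3), (6, 16)]:
            M = build_image_level_mask(ic, s).M
            assert (np.diag(M) == 1).all()

    def test_blocks_are_saturated(self):
        """(a,b) image-blocks are all-ones iff b <= a, all-zeros otherwise."""
        s, ic = 4, 5
        M = build_image_level_mask(ic, s).M
        for a in range(ic):
            for b in range(ic):
                block = M[a * s : (a + 1) * s, b * s : (b + 1) * s]
                assert (block == (1 if b <= a else 0)).all()

    def test_token_level_mask_breaks_within_image_visibility(self):
        """The strict token-causal triangle hides same-image tokens j > i that
        the image-level mask exposes — the structural premise of replacing one
        with the other."""
        s, ic = 4, 3
        image_level = build_image_level_mask(ic, s).M
        token_level = build_token_level_mask(ic * s)
        broken = (image_level == 1) & (token_level == 0)
        img = np.arange(ic * s) // s
        same_image = img[:, None] == img[None, :]
        assert broken.any()
        assert (broken <= same_image).all()  # only within-image visibility is lost


class TestMaskedAttention:
    def test_all_ones_equals_unmasked(self, rng):
        Q, K, V = rng.normal(size=(3, 6, 4))
        out = masked_attention(Q, K, V, np.ones((6, 6), dtype=np.uint8))
        scores = Q @ K.T / 2.0
        e = np.exp(scores - scores.max(-1, keepdims=True))
        expected = e / e.sum(-1, keepdims=True) @ V
        assert np.allclose(out, expected)

    def test_uniform_scores_prefix_averages(self):
        """s=1, zero Q/K: row i is the running mean of visible V rows."""
        V = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        Z = np.zeros((3, 2))
        M = build_image_level_mask(3, 1)
        out = masked_attention(Z, Z, V, M)
        expected = np.array([V[0], (V[0] + V[1]) / 2, (V[0] + V[1] + V[2]) / 3])
        assert np.allclose(out, expected)

    def test_attention_tensor_bundle_call_form(self, rng):
        from icseg.decoder import AttentionTensors

        Q, K, V = rng.normal(size=(3, 5, 4))
        M = build_image_level_mask(5, 1)
        direct = masked_attention(Q, K, V, M)
        bundled = masked_attention(AttentionTensors(Q=Q, K=K, V=V), M)
        assert (direct == bundled).all()

    def test_masked_positions_carry_exactly_zero_weight(self, rng):
        Q, K, V = rng.normal(size=(3, 4, 8))
        M = build_image_level_mask(2, 2).M
        base = masked_attention(Q, K, V, M)
        K2, V2 = K.copy(), V.copy()
        K2[2:] += rng.normal(size=(2, 8)) * 100  # only visible to rows 2,3
        V2[2:] -= 7.0
        out = masked_attention(Q, K2, V2, M)
        assert (out[:2] == base[:2]).all()  # bit-identical on masked rows


@pytest.fixture(scope="module")
def tiny_trained_free_model():
    return SegmentationModel(ModelConfig.tiny(), seed=11)


def make_episode(cfg, n_pairs, mode, seed=0):
    rng = np.random.default_rng(seed)
    size = cfg.image_size
    pairs = []
    for _ in range(n_pairs):
        img = ImageSlice(rng.uniform(0, 1, (size, size)).astype(np.float32))
        mask = BinaryMask((rng.uniform(0, 1, (size, size)) > 0.7).astype(np.uint8))
        pairs.append((img, mask))
    query = None
    if mode == "infer":
        query = ImageSlice(rng.uniform(0, 1, (size, size)).astype(np.float32))
    return EpisodeSequence(pairs=pairs, class_id=1, mode=mode, query=query)


class TestSequenceAssembly:
    def test_token_counts(self, tiny_trained_free_model):
        model = tiny_trained_free_model
        s = model.config.tokens_per_image
        ep_inf = make_episode(model.config, 2, "infer")
        seq = model.assemble_token_sequence(ep_inf)
        assert seq.image_count == 5 and seq.S == 5 * s
        ep_tr = make_episode(model.config, 3, "train")
        seq_tr = model.assemble_token_sequence(ep_tr)
        assert seq_tr.image_count == 6 and seq_tr.S == 6 * s

    def test_reference_sequence_length(self):
        # 16x16 grid, 7 prompt pairs + query -> 256 * 15 = 3840 tokens
        cfg = ModelConfig()
        assert cfg.tokens_per_image * (2 * 7 + 1) == 3840

    def test_episode_longer_than_budget_rejected(self, tiny_trained_free_model):
        model = tiny_trained_free_model
        ep = make_episode(model.config, model.config.n_max + 1, "infer")
        with pytest.raises(ValueError, match="n_max|pairs"):
            model.predict_query(ep)


class TestCausality:
    def test_train_predictions_ignore_later_pairs(self):
        """Features at supervised position i are bit-identical when every pair
        j > i is replaced by random noise — for every i (image 32, patch 8,
        2+2-layer random-weight miniature)."""
        cfg = ModelConfig.tiny()
        model = SegmentationModel(cfg, seed=3)
        n_plus_1 = 4
        base_ep = make_episode(cfg, n_plus_1, "train", seed=5)
        base_preds = [p.data.copy() for p in model.forward_train(base_ep)]
        rng = np.random.default_rng(99)
        size = cfg.image_size
        for i in range(2, n_plus_1 + 1):  # supervised positions
            pairs = list(base_ep.pairs)
            for j in range(i, n_plus_1):  # 0-based pairs j+1 > i
                noise_img = ImageSlice(rng.uniform(0, 1, (size, size)).astype(np.float32))
                noise_msk = BinaryMask((rng.uniform(0, 1, (size, size)) > 0.5).astype(np.uint8))
                pairs[j] = (noise_img, noise_msk)
            perturbed = EpisodeSequence(pairs=pairs, class_id=1, mode="train")
            pert_preds = model.forward_train(perturbed)
            # prediction at position i depends only on pairs 1..i-1 and x_i
            assert (pert_preds[i - 2].data == base_preds[i - 2]).all(), f"position {i}"

    def test_query_prediction_pure_function_of_episode(self):
        cfg = ModelConfig.tiny()
        model = SegmentationModel(cfg, seed=3)
        ep = make_episode(cfg, 2, "infer", seed=8)
        p1 = model.predict_query(ep)
        p2 = model.predict_query(ep)
        assert (p1.fg_prob == p2.fg_prob).all()

    def test_single_image_sequence_fully_visible(self):
        M = build_image_level_mask(1, 9).M
        assert (M == 1).all()


class TestHeadAndBinarize:
    def test_zero_head_gives_half_probability(self):
        cfg = ModelConfig.tiny()
        model = SegmentationModel(cfg, seed=1)
        model.head.weight.data[:] = 0
        model.head.bias.data[:] = 0
        ep = make_episode(cfg, 2, "infer", seed=2)
        p = model.predict_query(ep)
        assert p.fg_prob.shape == (cfg.image_size, cfg.image_size)
        assert np.allclose(p.fg_prob, 0.5)

    def test_probabilities_complementary(self):
        cfg = ModelConfig.tiny()
        model = SegmentationModel(cfg, seed=1)
        ep = make_episode(cfg, 1, "infer", seed=4)
        seq = model.assemble_token_sequence(ep)
        feats = model.decode_sequence(seq)
        s = seq.s
        import icseg.autodiff as ad

        probs = model.segmentation_head(
            ad.reshape(feats[:, 2 * s : 3 * s, :], (s, cfg.dec_dim))
        ).data
        assert np.allclose(probs.sum(-1), 1.0, atol=1e-6)
        assert probs.shape == (cfg.image_size, cfg.image_size, 2)

    def test_binarize_rules(self):
        p = ProbabilityMap(np.full((4, 4), 0.5, np.float32))
        assert (binarize(p).labels == 1).all()  # >= tie-break
        ind = np.zeros((4, 4), np.float32)
        ind[1, 2] = 1.0
        assert (binarize(ProbabilityMap(ind)).labels == ind).all()
        probs = ProbabilityMap(np.random.default_rng(0).uniform(0, 1, (8, 8)).astype(np.float32))
        low = binarize(probs, 0.3).labels
        high = binarize(probs, 0.7).labels
        assert (high <= low).all()  # monotone in threshold


class TestCheckpointRoundtrip:
    def test_save_load_preserves_predictions(self, tmp_path):
        from icseg.engine import load_checkpoint, save_checkpoint

        cfg = ModelConfig.tiny()
        model = SegmentationModel(cfg, seed=21)
        ep = make_episode(cfg, 2, "infer", seed=1)
        before = model.predict_query(ep).fg_prob
        save_checkpoint(model, tmp_path / "m.npz")
        loaded = load_checkpoint(tmp_path / "m.npz")
        after = loaded.predict_query(ep).fg_prob
        assert (before == after).all()

    def test_missing_checkpoint_errors(self, tmp_path):
        from icseg.engine import load_checkpoint

        with pytest.raises(FileNotFoundError):
            load_checkpoint(tmp_path / "nope.npz")
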