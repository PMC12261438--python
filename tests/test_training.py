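"""Target matrices, the masked N-pair + L2 loss (values and gradients),
cropping, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from near.model import EmbeddingModel, ModelConfig
from near.sequences import ProteinSequence
from near.training import (
    AlignedPair,
    TrainConfig,
    alignment_to_columns,
    build_target_matrix,
    make_training_example,
    npair_masked_loss,
    train,
)


def identity_pair(seq: str, sid="a", tid="b") -> AlignedPair:
    s = ProteinSequence(sid, seq)
    t = ProteinSequence(tid, seq)
    return AlignedPair(s, t, tuple((i, i) for i in range(len(seq))))


class TestTargetMatrix:
    def test_self_alignment_is_identity(self):
        t = build_target_matrix(identity_pair("ACDEF"))
        np.testing.assert_array_equal(t, np.eye(5, dtype=np.int8))

    def test_empty_columns(self):
        pair = AlignedPair(ProteinSequence("a", "ACD"), ProteinSequence("b", "WYVK"), ())
        assert build_target_matrix(pair).sum() == 0

    def test_direct_construction(self):
        pair = AlignedPair(
            ProteinSequence("a", "ACD"), ProteinSequence("b", "WYVK"),
            ((0, 1), (2, 3)),
        )
        t = build_target_matrix(pair)
        assert t[0, 1] == 1 and t[2, 3] == 1 and t.sum() == 2
        np.testing.assert_array_equal(t.sum(axis=1), [1, 0, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            AlignedPair(ProteinSequence("a", "AC"), ProteinSequence("b", "AC"), ((0, 5),))

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            AlignedPair(ProteinSequence("a", "ACD"), ProteinSequence("b", "ACD"),
                        ((0, 2), (1, 1)))


class TestAlignmentToColumns:
    @pytest.mark.parametrize(
        "ga,gb,expected",
        [
            ("AC-D", "A-GD", {(0, 0), (2, 2)}),
            ("ACD", "ACD", {(0, 0), (1, 1), (2, 2)}),
            ("----WYVK", "WYVK----", set()),
        ],
    )
    def test_column_walk(self, ga, gb, expected):
        assert alignment_to_columns(ga, gb) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            alignment_to_columns("AC", "ACD")

    def test_gap_gap_column_rejected(self):
        with pytest.raises(ValueError):
            alignment_to_columns("A-C", "A-C")

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_roundtrip_through_gapped_strings(self, data):
        from near.io import _gapped_from_columns

        la = data.draw(st.integers(2, 12))
        lb = data.draw(st.integers(2, 12))
        n_cols = data.draw(st.integers(0, min(la, lb)))
        i_idx = sorted(data.draw(st.sets(st.integers(0, la - 1),
                                         min_size=n_cols, max_size=n_cols)))
        j_idx = sorted(data.draw(st.sets(st.integers(0, lb - 1),
                                         min_size=n_cols, max_size=n_cols)))
        cols = tuple(zip(i_idx, j_idx))
        pair = AlignedPair(ProteinSequence("a", "A" * la),
                           ProteinSequence("b", "C" * lb), cols)
        ga, gb = _gapped_from_columns(pair)
        assert alignment_to_columns(ga, gb) == set(cols)


class TestNPairLoss:
    def test_single_column_softmax_is_one(self):
        emb = np.ones((1, 3))
        loss = npair_masked_loss(np.array([[4.2]]), np.array([[1]]),
                                 [1], [1], 0.0, emb, emb)
        assert loss.npair_term == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_targets_leave_only_l2(self, rng):
        ea, eb = rng.standard_normal((3, 4)), rng.standard_normal((5, 4))
        d = ea @ eb.T
        loss = npair_masked_loss(d, np.zeros((3, 5)), np.ones(3), np.ones(5),
                                 0.01, ea, eb)
        assert loss.npair_term == 0.0
        assert loss.total == pytest.approx(loss.l2_term)
        expected_l2 = 0.01 / 3 * ((ea**2).sum() + (eb**2).sum())
        assert loss.l2_term == pytest.approx(expected_l2)

    def test_two_by_two_scalar_oracle(self):
        # D=[[2,0],[0,2]], T=I: per row -log(e^2/(e^2+1)) = log(1+e^-2)
        d = np.array([[2.0, 0.0], [0.0, 2.0]])
        emb = np.zeros((2, 2))
        loss = npair_masked_loss(d, np.eye(2), [1, 1], [1, 1], 0.0, emb, emb)
        assert loss.npair_term == pytest.approx(2 * np.log(1 + np.exp(-2)), rel=1e-12)
        assert loss.npair_term == pytest.approx(0.2538, abs=1e-4)

    def test_masked_row_contributes_nothing(self, rng):
        ea, eb = rng.standard_normal((2, 3)), rng.standard_normal((2, 3))
        d = ea @ eb.T
        t = np.eye(2)
        full = npair_masked_loss(d, t, [1, 1], [1, 1], 0.0, ea, eb)
        masked, ga, gb = npair_masked_loss(d, t, [0, 1], [1, 1], 0.0, ea, eb,
                                           with_grads=True)
        assert masked.npair_term < full.npair_term
        np.testing.assert_allclose(ga[0], 0.0, atol=1e-15)

    def test_non_binary_mask_rejected(self, rng):
        ea = rng.standard_normal((2, 3))
        with pytest.raises(ValueError):
            npair_masked_loss(ea @ ea.T, np.eye(2), [0.5, 1], [1, 1], 0.0, ea, ea)

    def test_non_finite_dot_matrix_rejected(self, rng):
        ea = rng.standard_normal((2, 3))
        d = ea @ ea.T
        d[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            npair_masked_loss(d, np.eye(2), [1, 1], [1, 1], 0.0, ea, ea)

    @pytest.mark.parametrize("gamma", [0.0, 5e-3])
    def test_gradient_matches_finite_differences(self, rng, gamma):
        na, nb, dd = 5, 7, 4
        ea, eb = rng.standard_normal((na, dd)), rng.standard_normal((nb, dd))
        t = np.zeros((na, nb)); t[0, 1] = t[2, 4] = t[4, 6] = 1
        ra = np.array([1, 1, 1, 0, 1]); rb = np.ones(nb, dtype=int)

        def f(a, b):
            return npair_masked_loss(a @ b.T, t, ra, rb, gamma, a, b, n=na).total

        _, ga, gb = npair_masked_loss(ea @ eb.T, t, ra, rb, gamma, ea, eb,
                                      n=na, with_grads=True)
        eps = 1e-6
        for emb, grad, which in ((ea, ga, "a"), (eb, gb, "b")):
            for idx in np.ndindex(emb.shape):
                orig = emb[idx]
                emb[idx] = orig + eps; up = f(ea, eb)
                emb[idx] = orig - eps; dn = f(ea, eb)
                emb[idx] = orig
                fd = (up - dn) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8), (which, idx)


class TestCropping:
    def test_short_pairs_unchanged(self, rng):
        pair = identity_pair("ACDEFGHIK")
        assert make_training_example(pair, 256, rng) is pair

    def test_identity_pair_crop_keeps_matched_offsets(self, rng):
        pair = identity_pair("ACDEFGHIKLMNPQRSTVWY" * 26)  # length 520
        crop = make_training_example(pair, 256, rng)
        assert len(crop.seq_a) == len(crop.seq_b) == 256
        assert crop.columns == tuple((i, i) for i in range(256))

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10_000), length=st.integers(30, 400),
           crop=st.integers(10, 120))
    def test_crop_always_retains_an_aligned_column(self, seed, length, crop):
        rng = np.random.default_rng(seed)
        pair = identity_pair("ACDEFGHIKLMNPQRSTVWY" * (length // 20 + 1))
        out = make_training_example(pair, crop, rng)
        assert len(out.seq_a) <= crop and len(out.seq_b) <= crop
        assert len(out.columns) >= 1
        # re-indexed columns are in range (validated by the constructor too)
        assert max(i for i, _ in out.columns) < len(out.seq_a)


@pytest.fixture(scope="module")
def identity_pairs():
    rng = np.random.default_rng(99)
    from near.simulate import ROBINSON_FREQS, _random_sequence
    pairs = []
    for i in range(50):
        s = _random_sequence(64, ROBINSON_FREQS, rng)
        pairs.append(AlignedPair(ProteinSequence(f"p{i}", s),
                                 ProteinSequence(f"q{i}", s),
                                 tuple((k, k) for k in range(64))))
    return pairs


def _train_tiny(identity_pairs, steps=200, gamma=5e-3, seed=11):
    model = EmbeddingModel(ModelConfig(embed_dim=16, n_blocks=2, kernel_size=5),
                           seed=seed)
    cfg = TrainConfig(steps=steps, batch_size=4, crop_length=64,
                      learning_rate=1e-3, l2_factor=gamma, seed=seed)
    return train(model, identity_pairs, cfg)


class TestTrainLoop:
    def test_training_decreases_npair_loss(self, identity_pairs):
        res = _train_tiny(identity_pairs)
        first = np.mean([r[1] for r in res.trace[:20]])
        last = np.mean([r[1] for r in res.trace[-20:]])
        assert last < first

    def test_l2_factor_shrinks_embedding_norms(self, identity_pairs):
        res0 = _train_tiny(identity_pairs, gamma=0.0)
        resg = _train_tiny(identity_pairs, gamma=5e-3)
        def mean_sq_norm(model):
            return np.mean([
                (model.embed(p.seq_a) ** 2).sum(axis=1).mean()
                for p in identity_pairs[:10]
            ])
        assert mean_sq_norm(res0.model) > mean_sq_norm(resg.model)

    def test_fixed_seed_reproduces_loss_trace(self, identity_pairs):
        r1 = _train_tiny(identity_pairs, steps=30)
        r2 = _train_tiny(identity_pairs, steps=30)
        assert r1.trace == r2.trace

    def test_aligned_pairs_separate_from_random_after_training(self, identity_pairs):
        """Trained embeddings: aligned residue pairs beat random residue pairs."""
        res = _train_tiny(identity_pairs)
        model = res.model
        rng = np.random.default_rng(0)
        aligned_sims, random_sims = [], []
        for p in identity_pairs[:10]:
            ea, eb = model.embed(p.seq_a), model.embed(p.seq_b)
            na = ea / np.linalg.norm(ea, axis=1, keepdims=True)
            nb = eb / np.linalg.norm(eb, axis=1, keepdims=True)
            sims = na @ nb.T
            aligned_sims.append(np.mean([sims[i, j] for i, j in p.columns]))
            perm = rng.permutation(len(p.seq_b))
            random_sims.append(np.mean([sims[i, perm[i]] for i, _ in p.columns]))
        assert np.mean(aligned_sims) > np.mean(random_sims) + 0.2

    def test_empty_pair_stream_rejected(self):
        model = EmbeddingModel(ModelConfig(embed_dim=8, n_blocks=1, kernel_size=3))
        with pytest.raises(ValueError):
            train(model, [], TrainConfig(steps=1, batch_size=1))
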