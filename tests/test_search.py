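"""Noise gate, score accumulation, the end-to-end pipeline, and the gate's
statistical calibration."""

import numpy as np
import pytest

from near.masking import combined_mask, mask_from_lowercase
from near.model import EmbeddingModel, ModelConfig
from near.search import (
    Hit,
    SearchConfig,
    accumulate,
    noise_gate,
    noise_tail_fraction,
    random_cosine_similarities,
    search_pipeline,
)
from near.sequences import ProteinSequence


class TestNoiseGate:
    def test_boundary_is_zero(self):
        assert noise_gate(3 / np.sqrt(256), 3.0, 256) == 0.0

    def test_printed_arithmetic(self):
        assert noise_gate(1.0, 3.0, 256) == pytest.approx(1 - 3 / 16)
        assert noise_gate(1.0, 3.0, 256) == pytest.approx(0.8125)

    @pytest.mark.parametrize("delta", [0.0, 1.0, 3.0])
    def test_negative_cosines_clamped(self, delta):
        assert noise_gate(-0.5, delta, 64) == 0.0


class TestAccumulate:
    def test_no_matches_absent_from_output(self):
        assert accumulate([], 3.0, 256) == []

    def test_sum_and_zero_drop(self):
        gate = 3 / np.sqrt(256)
        matches = [
            ("q", 0, "t", 5, gate + 0.5),
            ("q", 1, "t", 9, gate + 0.3),
            ("q", 2, "t", 11, gate),  # gates to exactly zero -> dropped
        ]
        hits = accumulate(matches, 3.0, 256)
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(0.8)
        assert hits[0].n_matches == 2

    def test_duplicate_residue_pairs_counted_once(self):
        gate = 3 / np.sqrt(256)
        matches = [("q", 0, "t", 5, gate + 0.5)] * 3
        hits = accumulate(matches, 3.0, 256)
        assert hits[0].n_matches == 1
        assert hits[0].score == pytest.approx(0.5)

    def test_adding_gated_match_never_decreases_score(self):
        gate = 3 / np.sqrt(64)
        base = [("q", 0, "t", 0, gate + 0.2)]
        more = base + [("q", 1, "t", 3, gate + 0.1)]
        assert accumulate(more, 3.0, 64)[0].score >= accumulate(base, 3.0, 64)[0].score

    def test_sorted_descending_with_tie_break(self):
        gate = 0.0
        matches = [("q", 0, "tb", 0, 0.5), ("q", 0, "ta", 1, 0.5),
                   ("q", 0, "tc", 2, 0.9)]
        hits = accumulate(matches, 0.0, 4)
        assert [h.target_id for h in hits] == ["tc", "ta", "tb"]


def brute_force_hits(queries, targets, model, masker, k, delta):
    """Independent pipeline oracle: embed, mask, all-pairs cosine, top-k per
    query residue over the pooled target residues, gate, sum."""
    d = model.config.embed_dim
    pool = []  # (target_id, position, unit vector)
    for t in targets:
        emb = model.embed(t)
        keep = masker(t).r if masker else np.ones(len(t), np.int8)
        for pos in np.flatnonzero(keep):
            v = emb[pos]
            pool.append((t.id, pos, v / np.linalg.norm(v)))
    scores: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for q in queries:
        emb = model.embed(q)
        keep = masker(q).r if masker else np.ones(len(q), np.int8)
        for pos in np.flatnonzero(keep):
            v = emb[pos]
            v = v / np.linalg.norm(v)
            sims = sorted(
                ((tid, tpos, float(u @ v)) for tid, tpos, u in pool),
                key=lambda r: (-r[2], r[0], r[1]),
            )[:k]
            for tid, tpos, sim in sims:
                f = max(0.0, sim - delta / np.sqrt(d))
                if f > 0:
                    scores[(q.id, tid)] = scores.get((q.id, tid), 0.0) + f
                    counts[(q.id, tid)] = counts.get((q.id, tid), 0) + 1
    hits = [Hit(qid, tid, s, counts[(qid, tid)]) for (qid, tid), s in scores.items()]
    hits.sort(key=lambda h: (-h.score, h.query_id, h.target_id))
    return hits


class TestPipeline:
    def test_matches_brute_force_oracle(self, random_proteins):
        model = EmbeddingModel(ModelConfig(embed_dim=8, n_blocks=2, kernel_size=5), seed=3)
        queries = random_proteins(3, lo=15, hi=30, prefix="q")
        targets = random_proteins(6, lo=15, hi=30, prefix="t")
        cfg = SearchConfig(k=5, delta=1.0, backend="exact")
        got = search_pipeline(queries, targets, model, masker=combined_mask, cfg=cfg)
        expected = brute_force_hits(queries, targets, model, combined_mask, 5, 1.0)
        assert [(h.query_id, h.target_id, h.n_matches) for h in got] == \
               [(h.query_id, h.target_id, h.n_matches) for h in expected]
        np.testing.assert_allclose([h.score for h in got],
                                   [h.score for h in expected], atol=1e-5)

    def test_query_finds_itself_first(self, tiny_model, random_proteins):
        targets = random_proteins(5, lo=30, hi=50, prefix="t")
        query = ProteinSequence("q0", targets[2].residues)
        hits = search_pipeline([query], targets, tiny_model, masker=None,
                               cfg=SearchConfig(k=10, delta=2.0))
        assert hits[0].target_id == targets[2].id

    def test_fully_masked_query_yields_no_hits(self, tiny_model, random_proteins):
        targets = random_proteins(3, prefix="t")
        query = ProteinSequence("q", targets[0].residues.lower())
        hits = search_pipeline([query], targets, tiny_model,
                               masker=mask_from_lowercase,
                               cfg=SearchConfig(k=5, delta=0.0))
        assert hits == []

    def test_empty_inputs_yield_empty_hits(self, tiny_model, random_proteins):
        assert search_pipeline([], random_proteins(2), tiny_model) == []
        assert search_pipeline(random_proteins(2), [], tiny_model) == []

    def test_orientations_agree_when_k_untruncating(self, tiny_model, random_proteins):
        queries = random_proteins(3, lo=10, hi=20, prefix="q")
        targets = random_proteins(4, lo=10, hi=20, prefix="t")
        big_k = sum(len(s) for s in queries + targets)  # no truncation either way
        std = search_pipeline(queries, targets, tiny_model, masker=None,
                              cfg=SearchConfig(k=big_k, delta=2.0, orientation="standard"))
        rev = search_pipeline(queries, targets, tiny_model, masker=None,
                              cfg=SearchConfig(k=big_k, delta=2.0, orientation="reversed"))
        as_set = lambda hits: {(h.query_id, h.target_id, round(h.score, 5), h.n_matches)
                               for h in hits}
        assert as_set(std) == as_set(rev)

    def test_deterministic_rerun(self, tiny_model, random_proteins):
        queries = random_proteins(2, prefix="q")
        targets = random_proteins(3, prefix="t")
        h1 = search_pipeline(queries, targets, tiny_model, cfg=SearchConfig(k=5))
        h2 = search_pipeline(queries, targets, tiny_model, cfg=SearchConfig(k=5))
        assert h1 == h2
        assert all(h.score >= 0 for h in h1)
        assert all(h1[i].score >= h1[i + 1].score for i in range(len(h1) - 1))


class TestGateCalibration:
    def test_gate_removes_nearly_all_noise(self):
        rng = np.random.default_rng(0)
        for d in (64, 256, 1024):
            frac = noise_tail_fraction(200_000, d, 3.0, rng)
            assert 100 * frac == pytest.approx(99.9, abs=0.05)

    def test_cosine_sd_scales_inverse_sqrt_d(self):
        rng = np.random.default_rng(1)
        scaled = [
            np.std(random_cosine_similarities(100_000, d, rng)) * np.sqrt(d)
            for d in (64, 256, 1024)
        ]
        assert max(scaled) / min(scaled) < 1.05
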