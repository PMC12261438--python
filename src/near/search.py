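"""Noise-gated residue matching and sequence-level score accumulation.

Each query residue retrieves its k nearest target residues by cosine
similarity. Two random d-dimensional vectors produce cosine similarities with
standard deviation ~ 1/sqrt(d), so a noise gate delta/sqrt(d) is subtracted
from every similarity and matches that do not clear it are dropped
(delta = 3 removes an expected ~99.9% of chance similarities at any d):

    f(A_i, B_j) = max(0, cos(a_i, b_j) - delta / sqrt(d))

The score of a candidate pair is the sum of its surviving gated matches,

    score(A, B) = sum over (A_i, B_j) in M_{A,B} of f(A_i, B_j),

which counts (softly) the number of good local alignment seeds between the
two sequences. The search can be run in the standard orientation (index the
targets, query with query residues) or reversed (index the queries, stream
target residues), with (query, target) attribution preserved so hits are
comparable across orientations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .masking import ResidueMask, apply_mask_to_search, combined_mask
from .model import EmbeddingModel
from .index import IndexConfig, build_index
from .sequences import ProteinSequence
from .training import Masker


@dataclass
class SearchConfig:
    k: int = 150
    delta: float = 3.0
    orientation: str = "standard"  # "standard" | "reversed"
    backend: str = "exact"  # index backend
    n_probe: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.orientation not in ("standard", "reversed"):
            raise ValueError("orientation must be 'standard' or 'reversed'")


@dataclass(frozen=True)
class Hit:
    query_id: str
    target_id: str
    score: float
    n_matches: int


def noise_gate(cosine: float, delta: float, d: int) -> float:
    """Gated match score max(0, cosine - delta/sqrt(d))."""
    return max(0.0, cosine - delta / np.sqrt(d))


def accumulate(
    matches: Iterable[tuple[str, int, str, int, float]],
    delta: float,
    d: int,
) -> list[Hit]:
    """Fold residue matches (query_id, i, target_id, j, cosine) into Hits.

    Applies the noise gate, drops zero-gated matches, deduplicates (i, j)
    residue pairs per (query, target) — the match set is a set — and sums.
    Hits are sorted by score descending, ties by (query_id, target_id).
    """
    gate = delta / np.sqrt(d)
    per_pair: dict[tuple[str, str], dict[tuple[int, int], float]] = {}
    for qid, i, tid, j, cosine in matches:
        f = cosine - gate
        if f <= 0.0:
            continue
        per_pair.setdefault((qid, tid), {})[(int(i), int(j))] = float(f)
    hits = [
        Hit(qid, tid, score=float(sum(fs.values())), n_matches=len(fs))
        for (qid, tid), fs in per_pair.items()
    ]
    hits.sort(key=lambda h: (-h.score, h.query_id, h.target_id))
    return hits


def _masked_embeddings(
    seqs: Sequence[ProteinSequence],
    model: EmbeddingModel,
    masker: Masker | None,
) -> list[tuple[str, np.ndarray, ResidueMask | None]]:
    embs = model.embed_many(seqs)
    out = []
    for s in seqs:
        mask = masker(s) if masker is not None else None
        out.append((s.id, embs[s.id], mask))
    return out


def search_pipeline(
    queries: Sequence[ProteinSequence],
    targets: Sequence[ProteinSequence],
    model: EmbeddingModel,
    masker: Masker | None = combined_mask,
    cfg: SearchConfig | None = None,
) -> list[Hit]:
    """Embed, mask, index, retrieve, gate, and accumulate.

    Standard orientation indexes the target residues and queries with query
    residues; reversed indexes the queries and streams target residues
    (useful when the target side is too large to index). Masking is applied
    on both sides before anything enters the index or the query set. Empty
    inputs yield an empty hit list.
    """
    cfg = cfg or SearchConfig()
    if not queries or not targets:
        return []
    d = model.config.embed_dim
    icfg = IndexConfig(backend=cfg.backend, n_probe=cfg.n_probe, seed=cfg.seed)

    q_embs = _masked_embeddings(queries, model, masker)
    t_embs = _masked_embeddings(targets, model, masker)
    indexed, probed = (t_embs, q_embs) if cfg.orientation == "standard" else (q_embs, t_embs)

    index = build_index(indexed, icfg)
    matches: list[tuple[str, int, str, int, float]] = []
    for seq_id, emb, mask in probed:
        kept, index_map = (
            apply_mask_to_search(emb, mask) if mask is not None
            else (emb, np.arange(emb.shape[0]))
        )
        if kept.shape[0] == 0:
            continue
        for row, neighbors in enumerate(index.knn(kept, k=cfg.k)):
            pos = int(index_map[row])
            for other_id, other_pos, cosine in neighbors:
                if cfg.orientation == "standard":
                    matches.append((seq_id, pos, other_id, other_pos, cosine))
                else:  # probed side is the target set
                    matches.append((other_id, other_pos, seq_id, pos, cosine))
    return accumulate(matches, cfg.delta, d)


# ----------------------------------------------------------- gate statistics

def random_cosine_similarities(
    n_pairs: int, d: int, rng: np.random.Generator
) -> np.ndarray:
    """Cosine similarities of n_pairs independent standard-normal vector pairs."""
    a = rng.standard_normal((n_pairs, d))
    b = rng.standard_normal((n_pairs, d))
    num = (a * b).sum(axis=1)
    return num / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))


def noise_tail_fraction(
    n_pairs: int, d: int, delta: float, rng: np.random.Generator
) -> float:
    """Fraction of random-pair cosines at or below the gate delta/sqrt(d).

    This is the share of chance similarities the gate removes; at delta = 3
    it is ~99.9% for any d (the cosine of random d-dimensional vectors is
    approximately N(0, 1/d)).
    """
    cos = random_cosine_similarities(n_pairs, d, rng)
    return float(np.mean(cos <= delta / np.sqrt(d)))
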