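"""Residue-level vector index with exact and IVF-PQ backends.

Vectors are L2-normalized on insertion and query, so maximum-inner-product
retrieval equals cosine retrieval. The ``exact`` backend stores the full
matrix and is the ground truth; the ``ivf_pq`` backend combines an inverted
file (coarse k-means partition, probe the ``n_probe`` nearest lists) with
product quantization of the residual vectors for compact approximate scoring.
ADC (asymmetric distance computation) scores shortlist candidates, which are
then re-ranked with the stored full-precision vectors so returned
similarities are exact cosines; only the candidate retrieval is approximate.

At desk scale the full-scale defaults (5000 lists, 32 PQ segments) exceed
the available training points, in which case the list count auto-shrinks to
ceil(sqrt(N)) with a logged warning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .masking import ResidueMask, apply_mask_to_search

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class IndexConfig:
    backend: str = "exact"  # "exact" | "ivf_pq"
    n_lists: int = 5000
    pq_segments: int = 32
    n_probe: int = 32  # unstated upstream; package default, see docs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("exact", "ivf_pq"):
            raise ValueError("backend must be 'exact' or 'ivf_pq'")
        if self.n_lists < 1 or self.n_probe < 1 or self.pq_segments < 1:
            raise ValueError("index parameters must be positive")


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float32)
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    return v / np.maximum(norms, _EPS)


@dataclass
class ResidueIndex:
    """Index over unmasked residue embeddings, each labelled (seq_id, position)."""

    cfg: IndexConfig
    d: int
    seq_ids: list[str] = field(default_factory=list)  # id table
    labels_seq: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    labels_pos: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    vectors: np.ndarray | None = None  # (N, d) normalized, full precision
    # ivf_pq state
    coarse_centroids: np.ndarray | None = None  # (n_lists, d)
    assignments: np.ndarray | None = None  # (N,)
    codebooks: np.ndarray | None = None  # (m, ksub, d/m)
    codes: np.ndarray | None = None  # (N, m) uint8/uint16

    def __len__(self) -> int:
        return len(self.labels_pos)

    # ------------------------------------------------------------------ build

    def _train_quantizer(self) -> None:
        n = len(self)
        cfg = self.cfg
        n_lists = cfg.n_lists
        if n < n_lists:
            n_lists = max(1, math.ceil(math.sqrt(n)))
            logger.warning(
                "auto-shrinking n_lists from %d to %d (%d vectors)",
                cfg.n_lists, n_lists, n,
            )
        if self.d % cfg.pq_segments != 0:
            raise ValueError(
                f"pq_segments={cfg.pq_segments} must divide d={self.d}"
            )
        v = self.vectors
        km = KMeans(n_clusters=n_lists, n_init=3, random_state=cfg.seed)
        self.assignments = km.fit_predict(v).astype(np.int64)
        self.coarse_centroids = km.cluster_centers_.astype(np.float32)
        resid = v - self.coarse_centroids[self.assignments]
        m = cfg.pq_segments
        sub = self.d // m
        ksub = int(min(256, max(2, n // 4)))
        self.codebooks = np.zeros((m, ksub, sub), dtype=np.float32)
        self.codes = np.zeros((n, m), dtype=np.uint16)
        for s in range(m):
            seg = resid[:, s * sub : (s + 1) * sub]
            km_s = KMeans(n_clusters=ksub, n_init=1, random_state=cfg.seed + 1 + s)
            self.codes[:, s] = km_s.fit_predict(seg).astype(np.uint16)
            self.codebooks[s] = km_s.cluster_centers_.astype(np.float32)

    # ------------------------------------------------------------------ query

    def knn(self, query_vectors: np.ndarray, k: int = 150
            ) -> list[list[tuple[str, int, float]]]:
        """Top-k neighbors per query row as (target_seq_id, position, cosine).

        Exact backend returns the true top-k; ivf_pq retrieves an ADC-scored
        candidate pool from the probed lists and re-ranks it exactly. Ties are
        broken by (seq_id, position), stable. k caps the result size; fewer
        results appear only when fewer candidates exist. An empty index
        yields empty lists.
        """
        q = np.atleast_2d(np.asarray(query_vectors))
        if len(self) == 0:
            return [[] for _ in range(q.shape[0])]
        if q.shape[1] != self.d:
            raise ValueError(f"query dimension {q.shape[1]} != index dimension {self.d}")
        if k < 1:
            raise ValueError("k must be >= 1")
        qn = _normalize(q)
        if self.cfg.backend == "exact":
            return self._knn_exact(qn, k)
        return self._knn_ivfpq(qn, k)

    def _top_from_sims(self, sims: np.ndarray, cand: np.ndarray, k: int
                       ) -> list[tuple[str, int, float]]:
        # sort by similarity desc, ties by (seq_id, position) ascending;
        # tie order uses the lexicographic rank of the id string, not
        # insertion order
        rank = np.argsort(np.argsort(np.array(self.seq_ids)))
        seq = self.labels_seq[cand]
        pos = self.labels_pos[cand]
        order = np.lexsort((pos, rank[seq], -sims.astype(np.float64)))[:k]
        return [
            (self.seq_ids[seq[o]], int(pos[o]), float(sims[o]))
            for o in order
        ]

    def _knn_exact(self, qn: np.ndarray, k: int) -> list[list[tuple[str, int, float]]]:
        sims_all = qn @ self.vectors.T  # (nq, N)
        cand = np.arange(len(self))
        return [self._top_from_sims(sims_all[r], cand, k) for r in range(qn.shape[0])]

    def _knn_ivfpq(self, qn: np.ndarray, k: int) -> list[list[tuple[str, int, float]]]:
        n_lists = self.coarse_centroids.shape[0]
        n_probe = min(self.cfg.n_probe, n_lists)
        m, ksub, sub = self.codebooks.shape
        list_members = [np.flatnonzero(self.assignments == l) for l in range(n_lists)]
        out = []
        coarse_sims = qn @ self.coarse_centroids.T  # (nq, n_lists)
        for r in range(qn.shape[0]):
            probe = np.argsort(-coarse_sims[r])[:n_probe]
            cand = np.concatenate([list_members[l] for l in probe]) if len(probe) else np.zeros(0, dtype=np.int64)
            if cand.size == 0:
                out.append([])
                continue
            # ADC: q.x ~ q.c(list(x)) + sum_s LUT[s, code_s(x)]
            q_segs = qn[r].reshape(m, sub)
            tables = np.stack([self.codebooks[s] @ q_segs[s] for s in range(m)])
            adc = coarse_sims[r][self.assignments[cand]].astype(np.float64)
            for s in range(m):
                adc += tables[s][self.codes[cand, s]]
            pool = cand[np.argsort(-adc)[: max(4 * k, k)]]
            sims = self.vectors[pool] @ qn[r]
            out.append(self._top_from_sims(sims, pool, k))
        return out

    # -------------------------------------------------------------- persistence

    def save(self, path) -> None:
        meta = {
            "cfg": self.cfg.__dict__,
            "d": self.d,
            "seq_ids": self.seq_ids,
        }
        payload = {
            "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            "labels_seq": self.labels_seq,
            "labels_pos": self.labels_pos,
            "vectors": self.vectors if self.vectors is not None else np.zeros((0, self.d), np.float32),
        }
        if self.cfg.backend == "ivf_pq" and len(self):
            payload.update(
                coarse_centroids=self.coarse_centroids,
                assignments=self.assignments,
                codebooks=self.codebooks,
                codes=self.codes,
            )
        with open(path, "wb") as fh:
            np.savez(fh, **payload)

    @classmethod
    def load(cls, path) -> "ResidueIndex":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            idx = cls(cfg=IndexConfig(**meta["cfg"]), d=int(meta["d"]))
            idx.seq_ids = list(meta["seq_ids"])
            idx.labels_seq = z["labels_seq"]
            idx.labels_pos = z["labels_pos"]
            idx.vectors = z["vectors"]
            if "coarse_centroids" in z.files:
                idx.coarse_centroids = z["coarse_centroids"]
                idx.assignments = z["assignments"]
                idx.codebooks = z["codebooks"]
                idx.codes = z["codes"]
        return idx


def build_index(
    embeddings: list[tuple[str, np.ndarray, ResidueMask | None]],
    cfg: IndexConfig | None = None,
) -> ResidueIndex:
    """Index the unmasked residue vectors of a set of sequences.

    ``embeddings`` holds (seq_id, (n, d) matrix, mask-or-None) triples; masked
    rows never enter the index, and every stored vector keeps its
    (seq_id, original residue position) label.
    """
    cfg = cfg or IndexConfig()
    dims = {e[1].shape[1] for e in embeddings}
    if len(dims) > 1:
        raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
    d = dims.pop() if dims else 0
    idx = ResidueIndex(cfg=cfg, d=d)
    vecs, lseq, lpos = [], [], []
    for seq_id, emb, mask in embeddings:
        if mask is not None:
            kept, index_map = apply_mask_to_search(emb, mask)
        else:
            kept, index_map = emb, np.arange(emb.shape[0])
        sid = len(idx.seq_ids)
        idx.seq_ids.append(seq_id)
        if kept.shape[0] == 0:
            continue
        vecs.append(_normalize(kept))
        lseq.append(np.full(kept.shape[0], sid, dtype=np.int64))
        lpos.append(index_map.astype(np.int64))
    if vecs:
        idx.vectors = np.vstack(vecs)
        idx.labels_seq = np.concatenate(lseq)
        idx.labels_pos = np.concatenate(lpos)
    else:
        idx.vectors = np.zeros((0, d), dtype=np.float32)
    if cfg.backend == "ivf_pq" and len(idx):
        idx._train_quantizer()
    return idx
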