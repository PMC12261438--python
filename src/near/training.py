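"""Alignment-guided contrastive training.

A trusted pairwise alignment of homologous sequences A and B yields a binary
target matrix T (T_ij = 1 iff residues A_i and B_j share an alignment
column). The network embeds A and B independently; the dot-product matrix
D_ij = a_i . b_j is pushed toward T by a masked N-pair loss

    L = sum_ij -R^a_i R^b_j T_ij log( e^{D_ij} / sum_w e^{D_iw} )
        + (gamma/n) ( sum_i R^a_i ||a_i||^2 + sum_i R^b_i ||b_i||^2 )

where the inner softmax sum runs over all residues w of B (row-wise), R are
repeat masks silencing loss from low-complexity regions, and the L2 term
(normalized by the crop length n) keeps embedding norms bounded. Aligned
residue vectors are driven together while every unaligned pair in an aligned
row is pushed apart through the softmax denominator, so the gradient is dense
even though T is sparse.

Optimization uses AdamW (decoupled weight decay); training examples are
contiguous random crops of the aligned pair, constrained to retain at least
one aligned column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .masking import ResidueMask, combined_mask
from .model import EmbeddingModel
from .sequences import ProteinSequence

Masker = Callable[[ProteinSequence], ResidueMask]


@dataclass
class AlignedPair:
    """Two sequences plus the 0-based aligned column index pairs (i into A,
    j into B). Columns are one-to-one and jointly monotone."""

    seq_a: ProteinSequence
    seq_b: ProteinSequence
    columns: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        cols = tuple(sorted((int(i), int(j)) for i, j in self.columns))
        for i, j in cols:
            if not (0 <= i < len(self.seq_a)) or not (0 <= j < len(self.seq_b)):
                raise ValueError(
                    f"aligned column ({i},{j}) out of range for lengths "
                    f"{len(self.seq_a)}x{len(self.seq_b)}"
                )
        i_seen = [i for i, _ in cols]
        j_seen = [j for _, j in cols]
        if len(set(i_seen)) != len(cols) or len(set(j_seen)) != len(cols):
            raise ValueError("each residue may appear in at most one column")
        if any(b <= a for a, b in zip(j_seen, j_seen[1:])):
            raise ValueError("alignment columns must be monotone in both sequences")
        self.columns = cols


def alignment_to_columns(gapped_a: str, gapped_b: str, gap: str = "-") -> set[tuple[int, int]]:
    """Aligned-column pairs from two equal-length gapped strings.

    Emits (i, j) for every column where both rows carry a residue; i, j are
    0-based ungapped positions. Gap-vs-gap columns are malformed.
    """
    if len(gapped_a) != len(gapped_b):
        raise ValueError(
            f"gapped strings differ in length: {len(gapped_a)} vs {len(gapped_b)}"
        )
    cols: set[tuple[int, int]] = set()
    i = j = 0
    for col, (ca, cb) in enumerate(zip(gapped_a, gapped_b)):
        a_res, b_res = ca != gap, cb != gap
        if not a_res and not b_res:
            raise ValueError(f"gap-vs-gap at alignment column {col}")
        if a_res and b_res:
            cols.add((i, j))
        if a_res:
            i += 1
        if b_res:
            j += 1
    return cols


def pair_from_gapped(
    id_a: str, gapped_a: str, id_b: str, gapped_b: str
) -> AlignedPair:
    """Build an AlignedPair from one aligned-FASTA record pair."""
    cols = alignment_to_columns(gapped_a, gapped_b)
    return AlignedPair(
        ProteinSequence(id_a, gapped_a.replace("-", "")),
        ProteinSequence(id_b, gapped_b.replace("-", "")),
        tuple(cols),
    )


def build_target_matrix(pair: AlignedPair) -> np.ndarray:
    """Binary |A| x |B| matrix with ones exactly at the aligned columns."""
    t = np.zeros((len(pair.seq_a), len(pair.seq_b)), dtype=np.int8)
    for i, j in pair.columns:
        t[i, j] = 1
    return t


@dataclass
class LossValue:
    total: float
    npair_term: float
    l2_term: float


def _check_mask(r: np.ndarray, n: int, name: str) -> np.ndarray:
    r = np.asarray(r)
    if r.shape != (n,):
        raise ValueError(f"{name} has shape {r.shape}, expected ({n},)")
    if not np.isin(r, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return r.astype(np.float64)


def npair_masked_loss(
    d_mat: np.ndarray,
    t: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    gamma: float,
    emb_a: np.ndarray,
    emb_b: np.ndarray,
    n: int | None = None,
    with_grads: bool = False,
):
    """Masked N-pair + L2 loss for one sequence pair.

    ``d_mat`` is |A| x |B| with d_mat[i, j] = a_i . b_j; the softmax for row i
    runs over all residues of B. ``n`` normalizes the L2 term (the training
    crop length; defaults to |A|). With ``with_grads=True`` also returns
    (grad_emb_a, grad_emb_b).
    """
    d_mat = np.asarray(d_mat, dtype=np.float64)
    if not np.isfinite(d_mat).all():
        raise FloatingPointError("non-finite entries in dot-product matrix")
    na, nb = d_mat.shape
    ra = _check_mask(mask_a, na, "mask_a")
    rb = _check_mask(mask_b, nb, "mask_b")
    t = np.asarray(t)
    if t.shape != (na, nb):
        raise ValueError("target matrix shape mismatch")
    if n is None:
        n = na

    # stable row-wise log-softmax
    row_max = d_mat.max(axis=1, keepdims=True)
    shifted = d_mat - row_max
    lse = np.log(np.exp(shifted).sum(axis=1, keepdims=True)) + row_max
    w = ra[:, None] * rb[None, :] * t  # weight of each aligned term
    npair = float((w * (lse - d_mat)).sum())

    ea = np.asarray(emb_a, dtype=np.float64)
    eb = np.asarray(emb_b, dtype=np.float64)
    l2 = float(gamma / n * (ra @ (ea**2).sum(axis=1) + rb @ (eb**2).sum(axis=1)))
    loss = LossValue(total=npair + l2, npair_term=npair, l2_term=l2)
    if not with_grads:
        return loss

    p = np.exp(d_mat - lse)  # row-wise softmax
    c = w.sum(axis=1)  # masked aligned-count per row of A
    g_d = c[:, None] * p - w  # dL_npair / dD
    grad_a = g_d @ eb + (2.0 * gamma / n) * ra[:, None] * ea
    grad_b = g_d.T @ ea + (2.0 * gamma / n) * rb[:, None] * eb
    return loss, grad_a, grad_b


def make_training_example(
    pair: AlignedPair, crop_length: int, rng: np.random.Generator
) -> AlignedPair:
    """Crop both sequences to contiguous windows of at most ``crop_length``.

    When the pair has any aligned column, one column is sampled as an anchor
    and both windows are placed so the anchor survives in each; columns
    falling outside either window are dropped and the rest re-indexed.
    """
    la, lb = len(pair.seq_a), len(pair.seq_b)
    if la <= crop_length and lb <= crop_length:
        return pair
    if pair.columns:
        ci, cj = pair.columns[rng.integers(len(pair.columns))]
        rel = int(rng.integers(crop_length))  # anchor offset inside the window
        off_a = int(np.clip(ci - rel, 0, max(0, la - crop_length)))
        off_b = int(np.clip(cj - rel, 0, max(0, lb - crop_length)))
    else:
        off_a = int(rng.integers(max(1, la - crop_length + 1)))
        off_b = int(rng.integers(max(1, lb - crop_length + 1)))
    end_a, end_b = off_a + crop_length, off_b + crop_length
    new_cols = tuple(
        (i - off_a, j - off_b)
        for i, j in pair.columns
        if off_a <= i < end_a and off_b <= j < end_b
    )
    sub_a = ProteinSequence(pair.seq_a.id, pair.seq_a.residues[off_a:end_a])
    sub_b = ProteinSequence(pair.seq_b.id, pair.seq_b.residues[off_b:end_b])
    return AlignedPair(sub_a, sub_b, new_cols)


@dataclass
class TrainConfig:
    """Optimization hyper-parameters (defaults are the full-scale settings)."""

    steps: int = 24000
    batch_size: int = 512
    crop_length: int = 256
    learning_rate: float = 1e-5
    weight_decay: float = 1e-2
    l2_factor: float = 5e-3  # gamma
    optimizer: str = "AdamW"
    seed: int = 0
    symmetrize: bool = False  # average both softmax directions (off: as printed)

    def __post_init__(self) -> None:
        for name in ("steps", "batch_size", "crop_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.l2_factor < 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive, factors non-negative")
        if self.optimizer != "AdamW":
            raise ValueError("only AdamW is supported")


class AdamW:
    """Adam with decoupled weight decay (biases and the token table included)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 weight_decay: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in params.items():
            g = grads[k].astype(np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            p -= (self.lr * (update + self.wd * p.astype(np.float64))).astype(p.dtype)


def _pair_loss_and_grads(
    emb_a: np.ndarray,
    emb_b: np.ndarray,
    t: np.ndarray,
    ra: np.ndarray,
    rb: np.ndarray,
    gamma: float,
    n: int,
    symmetrize: bool,
):
    d = emb_a.astype(np.float64) @ emb_b.astype(np.float64).T
    loss, ga, gb = npair_masked_loss(
        d, t, ra, rb, gamma, emb_a, emb_b, n=n, with_grads=True
    )
    if symmetrize:
        loss2, gb2, ga2 = npair_masked_loss(
            d.T, t.T, rb, ra, gamma, emb_b, emb_a, n=n, with_grads=True
        )
        loss = LossValue(
            total=0.5 * (loss.total + loss2.total),
            npair_term=0.5 * (loss.npair_term + loss2.npair_term),
            l2_term=0.5 * (loss.l2_term + loss2.l2_term),
        )
        ga = 0.5 * (ga + ga2)
        gb = 0.5 * (gb + gb2)
    return loss, ga, gb


@dataclass
class TrainResult:
    model: EmbeddingModel
    trace: list[tuple[int, float, float, float]] = field(default_factory=list)
    # trace rows: (step, npair, l2, total) — batch means


def train(
    model: EmbeddingModel,
    pairs: Sequence[AlignedPair],
    cfg: TrainConfig,
    masker: Masker | None = None,
) -> TrainResult:
    """Run ``cfg.steps`` AdamW updates over random batches of aligned pairs.

    Masks are computed on the cropped sequences before the loss (default
    masker: lowercase union internal low-complexity detector). Reproducible
    given ``cfg.seed``; aborts with a diagnostic if the loss goes non-finite.
    """
    if len(pairs) == 0:
        raise ValueError("training requires at least one aligned pair")
    masker = masker or combined_mask
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    trace: list[tuple[int, float, float, float]] = []

    for step in range(cfg.steps):
        batch_idx = rng.integers(len(pairs), size=cfg.batch_size)
        batch = [make_training_example(pairs[i], cfg.crop_length, rng) for i in batch_idx]
        seqs: list[ProteinSequence] = []
        for p in batch:
            seqs.extend((p.seq_a, p.seq_b))
        n_max = max(len(s) for s in seqs)
        tokens = np.full((len(seqs), n_max), -1, dtype=np.int64)
        for r, s in enumerate(seqs):
            tokens[r, : len(s)] = s.tokens()
        emb, cache = model.forward_tokens(tokens, want_cache=True)

        grad_out = np.zeros_like(emb)
        np_sum = l2_sum = 0.0
        for b, p in enumerate(batch):
            ea = emb[2 * b, : len(p.seq_a)]
            eb = emb[2 * b + 1, : len(p.seq_b)]
            t = build_target_matrix(p)
            ra = masker(p.seq_a).r
            rb = masker(p.seq_b).r
            loss, ga, gb = _pair_loss_and_grads(
                ea, eb, t, ra, rb, cfg.l2_factor, cfg.crop_length, cfg.symmetrize
            )
            np_sum += loss.npair_term
            l2_sum += loss.l2_term
            grad_out[2 * b, : len(p.seq_a)] = ga / cfg.batch_size
            grad_out[2 * b + 1, : len(p.seq_b)] = gb / cfg.batch_size

        np_mean = np_sum / cfg.batch_size
        l2_mean = l2_sum / cfg.batch_size
        total = np_mean + l2_mean
        if not np.isfinite(total):
            raise RuntimeError(
                f"training diverged at step {step}: loss={total} "
                f"(npair={np_mean}, l2={l2_mean})"
            )
        grads = model.backward(grad_out.astype(model.dtype), cache)
        opt.step(model.params, grads)
        trace.append((step, np_mean, l2_mean, total))

    return TrainResult(model=model, trace=trace)
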