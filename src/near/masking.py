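"""Residue masks for repetitive and low-complexity regions.

Masks silence the training loss in biased regions and exclude residues from
the search pipeline, mirroring the masking hooks of classical alignment
tools. Two sources are supported and combined by union:

* soft-masked FASTA (lowercase letters), for masks produced externally by a
  dedicated repeat masker;
* a lightweight internal detector combining window Shannon entropy and exact
  tandem-period detection. It is deliberately simple — a pluggable stand-in,
  not a reimplementation of a probabilistic tandem-repeat model.

Mask convention: 1 = keep, 0 = repetitive/biased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import ProteinSequence


@dataclass
class ResidueMask:
    seq_id: str
    r: np.ndarray  # binary, length n; 1 = keep

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.int8)
        if self.r.ndim != 1:
            raise ValueError("mask must be a 1D vector")
        if not np.isin(self.r, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")

    def __len__(self) -> int:
        return len(self.r)

    def union(self, other: "ResidueMask") -> "ResidueMask":
        """Combine masks: a residue is masked if either source masks it."""
        if len(self) != len(other):
            raise ValueError("mask length mismatch")
        return ResidueMask(self.seq_id, self.r & other.r)

    def intervals(self) -> list[tuple[int, int]]:
        """Masked runs as 0-based half-open (start, end) intervals."""
        out: list[tuple[int, int]] = []
        start = None
        for i, v in enumerate(self.r):
            if v == 0 and start is None:
                start = i
            elif v == 1 and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(self.r)))
        return out


def mask_from_lowercase(seq: ProteinSequence) -> ResidueMask:
    """Soft-masked FASTA convention: lowercase residues are masked out."""
    r = np.array([0 if c.islower() else 1 for c in seq.residues], dtype=np.int8)
    return ResidueMask(seq.id, r)


def _entropy_mask(up: str, window: int, threshold_bits: float) -> np.ndarray:
    n = len(up)
    keep = np.ones(n, dtype=np.int8)
    if n < window:
        return keep
    codes = np.frombuffer(up.encode("ascii"), dtype=np.uint8)
    # rolling composition over windows [i, i+window)
    counts = np.zeros(26, dtype=np.int64)
    low = np.zeros(n - window + 1)
    for i, c in enumerate(codes[:window]):
        counts[c - 65] += 1
    def ent(cts: np.ndarray) -> float:
        p = cts[cts > 0] / window
        return float(-(p * np.log2(p)).sum())
    low[0] = ent(counts)
    for i in range(1, n - window + 1):
        counts[codes[i - 1] - 65] -= 1
        counts[codes[i + window - 1] - 65] += 1
        low[i] = ent(counts)
    bad_windows = np.flatnonzero(low < threshold_bits)
    for w in bad_windows:
        keep[w : w + window] = 0
    return keep


def _tandem_mask(up: str, max_period: int, min_run: int = 6) -> np.ndarray:
    """Mask maximal runs where the sequence matches itself at period p over at
    least two full periods and at least ``min_run`` residues.

    The min_run floor keeps chance doublets ("..AA..", period 1 over 2
    residues) from masking ~10% of random sequence; a repeat must span enough
    residues to be a credible tandem before it is silenced."""
    n = len(up)
    keep = np.ones(n, dtype=np.int8)
    arr = np.frombuffer(up.encode("ascii"), dtype=np.uint8)
    for p in range(1, min(max_period, n - 1) + 1):
        match = arr[p:] == arr[:-p]  # match[i]: up[i+p] == up[i]
        i = 0
        m = len(match)
        while i < m:
            if match[i]:
                j = i
                while j < m and match[j]:
                    j += 1
                run = (j - i) + p  # residues covered by the repeat
                if run >= max(2 * p, min_run):
                    keep[i : i + run] = 0
                i = j
            else:
                i += 1
    return keep


def mask_low_complexity(
    seq: ProteinSequence,
    window: int = 16,
    entropy_threshold: float = 2.0,
    max_period: int = 5,
    min_run: int = 6,
) -> ResidueMask:
    """Internal repeat/low-complexity detector.

    A residue is masked when (a) any length-``window`` window covering it has
    amino-acid composition entropy below ``entropy_threshold`` bits, or (b) it
    lies in a tandem repeat of period <= ``max_period`` spanning at least two
    full periods and ``min_run`` residues. Deterministic.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    up = seq.upper()
    keep = _entropy_mask(up, window, entropy_threshold) & _tandem_mask(up, max_period, min_run)
    return ResidueMask(seq.id, keep)


def combined_mask(
    seq: ProteinSequence,
    use_lowercase: bool = True,
    use_detector: bool = True,
    **detector_kwargs,
) -> ResidueMask:
    """Union of the soft-mask signal and the internal detector (default masker)."""
    masks = []
    if use_lowercase:
        masks.append(mask_from_lowercase(seq))
    if use_detector:
        masks.append(mask_low_complexity(seq, **detector_kwargs))
    if not masks:
        return ResidueMask(seq.id, np.ones(len(seq), dtype=np.int8))
    out = masks[0]
    for m in masks[1:]:
        out = out.union(m)
    return out


def apply_mask_to_search(
    emb: np.ndarray, mask: ResidueMask
) -> tuple[np.ndarray, np.ndarray]:
    """Drop masked rows from an embedding matrix.

    Returns (kept_rows, index_map) where ``index_map[r]`` is the original
    residue position of kept row ``r``. Removed rows never enter the index or
    the query set.
    """
    if emb.shape[0] != len(mask):
        raise ValueError(
            f"embedding has {emb.shape[0]} rows but mask has {len(mask)}"
        )
    idx = np.flatnonzero(mask.r == 1)
    return emb[idx], idx
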