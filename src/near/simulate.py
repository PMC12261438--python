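"""Synthetic homolog families with ground-truth alignments.

Each family descends from a random ancestor drawn from a background
amino-acid distribution (Robinson-Robinson frequencies by default). Two
homologs are produced by evolving the ancestor independently: every copied
position is substituted with probability ``substitution_rate`` (replacement
drawn from the background excluding the current residue) and indels open per
position with probability ``indel_rate`` (geometric lengths, insertions drawn
from the background). The ground-truth alignment pairs exactly the ancestor
positions that survive un-deleted in both descendants, so training targets
and evaluation labels are known by construction. Optional low-complexity
segments are spliced into descendants to exercise the masking stage, and
shuffled decoys (exact residue permutations of the positive targets) provide
non-homologous pairs for the recall-vs-filtration benchmark.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .sequences import CANONICAL_AA, ProteinSequence
from .training import AlignedPair

# Robinson & Robinson amino-acid background, ordered as CANONICAL_AA
_RR = np.array([
    0.0788, 0.0168, 0.0536, 0.0629, 0.0401, 0.0735, 0.0219, 0.0597, 0.0595,
    0.0934, 0.0236, 0.0448, 0.0483, 0.0403, 0.0512, 0.0716, 0.0585, 0.0661,
    0.0131, 0.0321,
])
ROBINSON_FREQS = _RR / _RR.sum()


@dataclass
class SimConfig:
    n_families: int = 50
    seqs_per_family: int = 3  # 1 query + (seqs_per_family - 1) targets
    length_range: tuple[int, int] = (128, 512)
    substitution_rate: float = 0.3
    indel_rate: float = 0.02
    mean_indel_length: float = 3.0
    lc_insert_prob: float = 0.1
    background_freqs: np.ndarray = field(default_factory=lambda: ROBINSON_FREQS.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must satisfy 1 <= min <= max")
        for name in ("substitution_rate", "indel_rate", "lc_insert_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.seqs_per_family < 2:
            raise ValueError("need at least a query and one target per family")
        f = np.asarray(self.background_freqs, dtype=np.float64)
        if f.shape != (20,) or (f < 0).any() or not np.isclose(f.sum(), 1.0):
            raise ValueError("background_freqs must be a normalized 20-vector")
        self.background_freqs = f / f.sum()


def _random_sequence(length: int, freqs: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=freqs)
    return "".join(CANONICAL_AA[i] for i in idx)


def _geometric_length(mean: float, rng: np.random.Generator) -> int:
    # support {1, 2, ...} with the requested mean
    p = 1.0 / max(mean, 1.0)
    return int(rng.geometric(p))


def _descend(
    ancestor: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, dict[int, int]]:
    """Evolve one descendant; returns (sequence, ancestor_pos -> descendant_pos)."""
    freqs = cfg.background_freqs
    out: list[str] = []
    anc_map: dict[int, int] = {}
    i = 0
    n = len(ancestor)
    while i < n:
        if rng.random() < cfg.indel_rate:
            length = _geometric_length(cfg.mean_indel_length, rng)
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.extend(_random_sequence(length, freqs, rng))  # insertion
        c = ancestor[i]
        if rng.random() < cfg.substitution_rate:
            a = CANONICAL_AA.index(c)
            q = freqs.copy()
            q[a] = 0.0
            q /= q.sum()
            c = CANONICAL_AA[rng.choice(20, p=q)]
        anc_map[i] = len(out)
        out.append(c)
        i += 1
    if not out:  # pathological all-deleted draw; keep one residue
        anc_map[0] = 0
        out.append(ancestor[0])
    return "".join(out), anc_map


def _insert_low_complexity(
    seq: str, anc_map: dict[int, int], cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, dict[int, int]]:
    """Splice a tandem-repeat segment into the sequence, shifting the map."""
    motif = _random_sequence(int(rng.integers(1, 4)), cfg.background_freqs, rng)
    length = int(rng.integers(12, 25))
    segment = (motif * (length // len(motif) + 1))[:length]
    pos = int(rng.integers(len(seq) + 1))
    new_seq = seq[:pos] + segment + seq[pos:]
    new_map = {a: (d if d < pos else d + length) for a, d in anc_map.items()}
    return new_seq, new_map


def _columns_from_maps(
    map_a: dict[int, int], map_b: dict[int, int]
) -> tuple[tuple[int, int], ...]:
    shared = sorted(set(map_a) & set(map_b))
    return tuple((map_a[p], map_b[p]) for p in shared)


def evolve_pair(
    ancestor: ProteinSequence, cfg: SimConfig, rng: np.random.Generator
) -> AlignedPair:
    """Two independent descendants of one ancestor, with ground-truth columns."""
    sa, ma = _descend(ancestor.residues.upper(), cfg, rng)
    sb, mb = _descend(ancestor.residues.upper(), cfg, rng)
    return AlignedPair(
        ProteinSequence(f"{ancestor.id}_a", sa),
        ProteinSequence(f"{ancestor.id}_b", sb),
        _columns_from_maps(ma, mb),
    )


def pair_identity(pair: AlignedPair) -> float:
    """Fraction of aligned columns carrying identical residues."""
    if not pair.columns:
        return 0.0
    a, b = pair.seq_a.upper(), pair.seq_b.upper()
    same = sum(a[i] == b[j] for i, j in pair.columns)
    return same / len(pair.columns)


def expected_column_identity(substitution_rate: float, freqs: np.ndarray) -> float:
    """Closed-form expected identity of an aligned column.

    Both copies unsubstituted: (1-r)^2. One substituted: never identical
    (replacements exclude the current residue). Both substituted: identical
    when the two replacement draws coincide.
    """
    r = substitution_rate
    freqs = np.asarray(freqs, dtype=np.float64)
    comp = 0.0
    for a, fa in enumerate(freqs):
        q = freqs.copy()
        q[a] = 0.0
        q /= q.sum()
        comp += fa * float((q**2).sum())
    return (1 - r) ** 2 + r**2 * comp


def shuffle_decoy(seq: ProteinSequence, rng: np.random.Generator) -> ProteinSequence:
    """Uniform random permutation of the residues; same length and composition."""
    perm = rng.permutation(len(seq))
    shuffled = "".join(seq.residues[i] for i in perm)
    return ProteinSequence(f"{seq.id}_shuf", shuffled)


def split_families(family_ids: list[str], train_fraction: float = 0.8) -> dict[str, str]:
    """Stable 80/20 train/eval split keyed on a hash of the family id, so no
    family ever appears on both sides."""
    out = {}
    for fid in family_ids:
        h = int.from_bytes(hashlib.md5(fid.encode()).digest()[:4], "big")
        out[fid] = "train" if (h / 2**32) < train_fraction else "eval"
    return out


@dataclass
class SimOutput:
    queries: list[ProteinSequence]
    targets_pos: list[ProteinSequence]
    decoys: list[ProteinSequence]
    pairs: list[AlignedPair]  # query-target ground-truth alignments
    positive_pairs: set[tuple[str, str]]
    decoy_pairs: set[tuple[str, str]]
    family_of: dict[str, str]
    decoy_source: dict[str, str]


def make_benchmark(cfg: SimConfig) -> SimOutput:
    """Families of homologs: one query and seqs_per_family-1 positive targets
    per family, a shuffled decoy for every positive target, ground-truth
    query-target alignments, and the label sets for evaluation."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    queries: list[ProteinSequence] = []
    targets: list[ProteinSequence] = []
    pairs: list[AlignedPair] = []
    family_of: dict[str, str] = {}

    for f in range(cfg.n_families):
        fam = f"fam{f:04d}"
        anc = ProteinSequence(fam, _random_sequence(int(rng.integers(lo, hi + 1)),
                                                    cfg.background_freqs, rng))
        members: list[tuple[ProteinSequence, dict[int, int]]] = []
        for m in range(cfg.seqs_per_family):
            s, amap = _descend(anc.residues, cfg, rng)
            if rng.random() < cfg.lc_insert_prob:
                s, amap = _insert_low_complexity(s, amap, cfg, rng)
            sid = f"{fam}_q" if m == 0 else f"{fam}_t{m}"
            members.append((ProteinSequence(sid, s), amap))
            family_of[sid] = fam
        query, qmap = members[0]
        queries.append(query)
        for tseq, tmap in members[1:]:
            targets.append(tseq)
            pairs.append(AlignedPair(query, tseq, _columns_from_maps(qmap, tmap)))

    decoys = [shuffle_decoy(t, rng) for t in targets]
    decoy_source = {d.id: t.id for d, t in zip(decoys, targets)}
    positive_pairs = {(p.seq_a.id, p.seq_b.id) for p in pairs}
    decoy_pairs = {(q.id, d.id) for q in queries for d in decoys}
    return SimOutput(
        queries=queries,
        targets_pos=targets,
        decoys=decoys,
        pairs=pairs,
        positive_pairs=positive_pairs,
        decoy_pairs=decoy_pairs,
        family_of=family_of,
        decoy_source=decoy_source,
    )
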