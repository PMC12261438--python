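"""Recall-vs-filtration evaluation of a pre-filter.

Given sequence-level hit scores and disjoint positive / decoy pair labels,
sweeping a score threshold trades decoy filtration (fraction of decoy pairs
scoring below the threshold) against recall (fraction of positive pairs
scoring at or above it). A pair the filter never returned scores 0 by
convention: a pre-filter that drops a pair has filtered it. Positives may be
stratified (e.g. by alignment E-value tier); recall is then reported within
each stratum separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .search import Hit

Pair = tuple[str, str]


@dataclass
class PairLabels:
    positives: set[Pair]
    decoys: set[Pair]
    strata: dict[str, set[Pair]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.positives & self.decoys
        if overlap:
            raise ValueError(f"labels overlap on {len(overlap)} pairs, e.g. {next(iter(overlap))}")
        for name, s in self.strata.items():
            if not s <= self.positives:
                raise ValueError(f"stratum {name!r} contains non-positive pairs")


def label_pairs(
    positive_list: set[Pair] | list[Pair],
    decoy_mode: str = "shuffled",
    shuffled_decoys: set[Pair] | list[Pair] | None = None,
    evalues: dict[Pair, float] | None = None,
    positive_tiers: tuple[float, ...] = (1e-10, 1e-3),
    decoy_evalue: float = 10.0,
) -> PairLabels:
    """Build disjoint positive/decoy label sets.

    decoy_mode "shuffled": decoys are the supplied (query, shuffled-target)
    pairs. decoy_mode "low_similarity": decoys are pairs whose alignment
    E-value is >= ``decoy_evalue``; positives are additionally stratified at
    each tier in ``positive_tiers`` (pairs between the loosest tier and the
    decoy cutoff stay unlabeled).
    """
    positives = set(positive_list)
    if decoy_mode == "shuffled":
        if shuffled_decoys is None:
            raise ValueError("shuffled decoy mode requires the decoy pair set")
        labels = PairLabels(positives=positives, decoys=set(shuffled_decoys))
    elif decoy_mode == "low_similarity":
        if evalues is None:
            raise ValueError("low_similarity decoy mode requires per-pair E-values")
        decoys = {p for p, e in evalues.items() if e >= decoy_evalue}
        positives = {p for p, e in evalues.items() if e <= max(positive_tiers)}
        labels = PairLabels(positives=positives, decoys=decoys)
    else:
        raise ValueError("decoy_mode must be 'shuffled' or 'low_similarity'")

    if evalues is not None:
        for tier in positive_tiers:
            labels.strata[f"evalue<={tier:g}"] = {
                p for p in labels.positives if evalues.get(p, np.inf) <= tier
            }
    return labels


@dataclass
class RecallFiltrationCurve:
    """Threshold sweep: one (threshold, filtration, recall) point per distinct
    score, plus a +inf sentinel. Filtration is non-decreasing and recall
    non-increasing in the threshold."""

    thresholds: np.ndarray
    filtration: np.ndarray
    recall: np.ndarray
    stratum: str = "all"

    def recall_at_filtration(self, level: float) -> float:
        """Highest recall achievable while filtering at least ``level`` of decoys."""
        ok = self.filtration >= level
        if not ok.any():
            return 0.0
        return float(self.recall[ok].max())

    def mean_recall(self, grid: np.ndarray | None = None) -> float:
        """Recall averaged over a filtration grid (score-monotone-invariant)."""
        grid = np.linspace(0.0, 1.0, 101) if grid is None else grid
        return float(np.mean([self.recall_at_filtration(g) for g in grid]))


def _scores_for(pairs: set[Pair], score_of: dict[Pair, float]) -> np.ndarray:
    return np.array([score_of.get(p, 0.0) for p in sorted(pairs)], dtype=np.float64)


def recall_filtration_curve(
    hits: list[Hit],
    labels: PairLabels,
    stratum: str = "all",
) -> RecallFiltrationCurve:
    """Sweep score thresholds over labelled pairs.

    For each candidate threshold t (every distinct observed score, plus +inf):
    filtration(t) = fraction of decoy pairs with score < t; recall(t) =
    fraction of positive pairs with score >= t. Pairs absent from ``hits``
    score 0. Tied scores share a single point (all-or-none at that
    threshold). ``stratum`` selects a positive stratum ("all" = every
    positive pair).
    """
    positives = labels.positives if stratum == "all" else labels.strata[stratum]
    if not positives:
        raise ValueError(f"no positive pairs in stratum {stratum!r}")
    if not labels.decoys:
        raise ValueError("no decoy pairs: filtration is undefined")
    score_of = {(h.query_id, h.target_id): h.score for h in hits}
    pos = _scores_for(positives, score_of)
    dec = _scores_for(labels.decoys, score_of)
    thresholds = np.unique(np.concatenate([pos, dec, [np.inf]]))
    filtration = np.array([(dec < t).mean() for t in thresholds])
    recall = np.array([(pos >= t).mean() for t in thresholds])
    return RecallFiltrationCurve(thresholds, filtration, recall, stratum=stratum)


def curves_by_stratum(hits: list[Hit], labels: PairLabels) -> dict[str, RecallFiltrationCurve]:
    out = {"all": recall_filtration_curve(hits, labels, "all")}
    for name in labels.strata:
        if labels.strata[name]:
            out[name] = recall_filtration_curve(hits, labels, name)
    return out


def plot_curves(curves: dict[str, RecallFiltrationCurve], path) -> None:
    """Optional rendering of filtration-recall curves to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, c in curves.items():
        order = np.argsort(c.filtration)
        ax.plot(c.filtration[order], c.recall[order], marker=".", label=name)
    ax.set_xlabel("decoy filtration")
    ax.set_ylabel("recall of positives")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
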