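"""Self-contained discrimination benchmark on synthetic families.

Generates a pool of homolog families, splits them by family-id hash into
train and held-out sets (so no family leaks across the split), trains a small
embedding model on the training pairs, runs the full search pipeline on the
held-out queries against held-out positive targets plus their shuffled
decoys, and reports the AUC of pre-filter scores separating positive
(query, target) pairs from decoy pairs. Pairs the filter never returns score
0. This is the desk-scale analog of a recall-vs-filtration benchmark on real
remote homologs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .model import EmbeddingModel, ModelConfig
from .search import Hit, SearchConfig, search_pipeline
from .simulate import SimConfig, SimOutput, make_benchmark, split_families
from .training import TrainConfig, train

TINY_MODEL = ModelConfig(embed_dim=32, n_blocks=2, kernel_size=7)
TINY_TRAIN = TrainConfig(steps=2000, batch_size=8, crop_length=128,
                         learning_rate=1e-3)


@dataclass
class DiscriminationResult:
    auc: float
    n_train_pairs: int
    n_eval_queries: int
    n_positive_pairs: int
    n_decoy_pairs: int
    hits: list[Hit]
    final_loss: float


def split_benchmark(sim: SimOutput) -> tuple[SimOutput, SimOutput]:
    """Partition a simulated benchmark into train/eval halves by family hash."""
    fams = sorted({f for f in sim.family_of.values()})
    side = split_families(fams)

    def subset(which: str) -> SimOutput:
        keep = {f for f in fams if side[f] == which}
        q = [s for s in sim.queries if sim.family_of[s.id] in keep]
        t = [s for s in sim.targets_pos if sim.family_of[s.id] in keep]
        dec = [d for d in sim.decoys if sim.family_of[sim.decoy_source[d.id]] in keep]
        qids = {s.id for s in q}
        dids = {d.id for d in dec}
        return SimOutput(
            queries=q,
            targets_pos=t,
            decoys=dec,
            pairs=[p for p in sim.pairs if sim.family_of[p.seq_a.id] in keep],
            positive_pairs={p for p in sim.positive_pairs if p[0] in qids},
            decoy_pairs={(a, b) for a, b in sim.decoy_pairs
                         if a in qids and b in dids},
            family_of={k: v for k, v in sim.family_of.items() if v in keep},
            decoy_source={d: s for d, s in sim.decoy_source.items() if d in dids},
        )

    return subset("train"), subset("eval")


def family_discrimination_auc(
    seed: int,
    n_families: int = 55,
    substitution_rate: float = 0.3,
    length_range: tuple[int, int] = (128, 256),
    model_cfg: ModelConfig = TINY_MODEL,
    train_cfg: TrainConfig = TINY_TRAIN,
    search_cfg: SearchConfig | None = None,
) -> DiscriminationResult:
    """Train a small model and measure homolog/decoy separation on held-out
    families. All randomness derives from ``seed``."""
    sim = make_benchmark(SimConfig(
        n_families=n_families,
        seqs_per_family=3,
        length_range=length_range,
        substitution_rate=substitution_rate,
        seed=seed,
    ))
    train_sim, eval_sim = split_benchmark(sim)
    model = EmbeddingModel(model_cfg, seed=seed)
    tcfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
    result = train(model, train_sim.pairs, tcfg)

    hits = search_pipeline(
        eval_sim.queries,
        eval_sim.targets_pos + eval_sim.decoys,
        model,
        cfg=search_cfg or SearchConfig(backend="exact"),
    )
    score = {(h.query_id, h.target_id): h.score for h in hits}
    y, s = [], []
    for p in sorted(eval_sim.positive_pairs):
        y.append(1)
        s.append(score.get(p, 0.0))
    for p in sorted(eval_sim.decoy_pairs):
        y.append(0)
        s.append(score.get(p, 0.0))
    return DiscriminationResult(
        auc=float(roc_auc_score(y, s)),
        n_train_pairs=len(train_sim.pairs),
        n_eval_queries=len(eval_sim.queries),
        n_positive_pairs=len(eval_sim.positive_pairs),
        n_decoy_pairs=len(eval_sim.decoy_pairs),
        hits=hits,
        final_loss=result.trace[-1][3],
    )
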