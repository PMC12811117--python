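"""End-to-end orchestration: embed the graph, classify labeled pairs,
rank unlabeled candidates.

Mirrors the downstream protocol: DVGAE embeddings -> concatenated
(anchor, partner) features -> three classifier families under stratified
five-fold CV -> accuracy-based selection -> probability ranking of the
unlabeled pool.  Label edges are excluded from the embedding graph by
default so the classifier never sees the association it is asked to
predict (the leakage control the curated ground truth requires).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dvgae, linkpred
from .graph import KnowledgeGraph, build_graph


@dataclass
class PipelineResult:
    anchor_id: str
    reports: dict[str, linkpred.EvalReport]
    best_family: str
    model: object
    ranked: list[tuple[str, float]]
    embeddings: Mapping[str, np.ndarray]
    train_result: dvgae.TrainResult


def strip_label_edges(kg: KnowledgeGraph, labels: pd.DataFrame) -> KnowledgeGraph:
    """Remove every (partner -> anchor) and (anchor -> partner) edge that
    appears in the label table from the embedding graph."""
    banned = set()
    for row in labels.itertuples(index=False):
        banned.add((row.partner_id, row.anchor_id))
        banned.add((row.anchor_id, row.partner_id))
    edges = [e for e in kg.edges if (e.source_id, e.target_id) not in banned]
    return build_graph(kg.nodes, edges)


def embeddings_as_mapping(result: dvgae.TrainResult) -> dict[str, np.ndarray]:
    emb = result.embeddings
    return {nid: emb.mu[i] for i, nid in enumerate(emb.node_ids)}


def run_link_prediction(
    kg: KnowledgeGraph,
    labels: pd.DataFrame,
    partner_type: str,
    seed: int = 42,
    grid: Sequence[dvgae.EncoderConfig] | None = None,
    families: Sequence[str] = linkpred.FAMILIES,
    top_k: int = 10,
    exclude_label_edges: bool = True,
    refit_full: bool = False,
    train_result: dvgae.TrainResult | None = None,
    embeddings_map: Mapping[str, np.ndarray] | None = None,
) -> PipelineResult:
    """Embed -> cross-validate -> select -> rank for one anchor disease.

    ``labels`` must reference a single anchor.  Partners of ``partner_type``
    absent from the label table form the unlabeled pool that gets ranked.
    A precomputed ``train_result`` (or a plain ``embeddings_map``) can be
    passed to reuse embeddings.
    """
    anchors = labels["anchor_id"].unique()
    if len(anchors) != 1:
        raise ValueError(f"label table must reference one anchor; got {list(anchors)}")
    anchor_id = str(anchors[0])

    if embeddings_map is not None:
        emb = dict(embeddings_map)
    else:
        if train_result is None:
            embed_kg = strip_label_edges(kg, labels) if exclude_label_edges else kg
            train_result = dvgae.train(embed_kg, grid=grid, seed=seed, refit_full=refit_full)
        emb = embeddings_as_mapping(train_result)

    partners = sorted(
        n.node_id for n in kg.nodes if n.node_type == partner_type and n.node_id in emb
    )
    positives = set(labels.loc[labels["label"] == 1, "partner_id"])
    negatives = set(labels.loc[labels["label"] == 0, "partner_id"])
    labeled, unlabeled = linkpred.assign_labels(partners, positives, negatives)
    pair_set = linkpred.build_pair_set(emb, anchor_id, labeled)

    reports = linkpred.crossvalidate(pair_set, families=families, seed=seed)
    best = linkpred.select_best(reports)
    model = linkpred.fit_final_model(pair_set, best, seed=seed)
    ranked = (
        linkpred.rank_unlabeled(model, emb, anchor_id, unlabeled, top_k)
        if unlabeled
        else []
    )
    return PipelineResult(anchor_id, reports, best, model, ranked, emb, train_result)


def score_partners(
    result: PipelineResult, partner_ids: Sequence[str]
) -> np.ndarray:
    """Predicted association probability for arbitrary partners."""
    anchor = np.asarray(result.embeddings[result.anchor_id])
    X = np.stack([
        linkpred.concatenate_pair(anchor, np.asarray(result.embeddings[p]))
        for p in partner_ids
    ])
    return result.model.predict_proba(X)[:, 1]


def recovery_auc(
    result: PipelineResult,
    withheld: Sequence[str],
    decoys: Sequence[str],
) -> float:
    """AUC of withheld true partners against decoy partners, scored by the
    selected classifier — the recovery surrogate for discovery claims."""
    from sklearn.metrics import roc_auc_score

    ids = list(withheld) + list(decoys)
    y = np.array([1] * len(withheld) + [0] * len(decoys))
    return float(roc_auc_score(y, score_partners(result, ids)))
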