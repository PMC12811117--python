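"""Network analytics used to validate predictions.

PageRank node importance, upper-tail hypergeometric gene-set enrichment
with Benjamini-Hochberg FDR control, druggability annotation from curated
drug-gene interactions, cosine-similarity validation of repurposing
candidates, and the with/without-imaging ablation comparison (chi-squared
on pathway counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph import KnowledgeGraph, remove_node_types, to_networkx

#: drug-gene interaction types with clear functional implications; rows of
#: any other type are discarded before the druggability call
DRUGGABLE_INTERACTION_TYPES = frozenset(
    {"agonist", "inhibitor", "modulator", "activator", "antibody"}
)


def pagerank(kg: KnowledgeGraph, damping: float = 0.85, tolerance: float = 1e-10) -> dict[str, float]:
    """Damped random-walk centrality on the directed graph.

    Scores sum to 1; dangling-node mass is spread uniformly.
    """
    if kg.n_nodes == 0:
        raise ValueError("cannot compute PageRank of an empty graph")
    if not (0.0 < damping < 1.0):
        raise ValueError("damping must be in (0, 1)")
    g = to_networkx(kg)
    return nx.pagerank(g, alpha=damping, tol=tolerance, max_iter=1000)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(theta) = A.B / (|A| |B|), in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def drug_cosine_validation(
    embeddings: Mapping[str, np.ndarray],
    predicted: Sequence[str],
    indicated: Sequence[str],
) -> pd.DataFrame:
    """Cosine similarity of each predicted medication to the indicated set.

    Returns one row per predicted drug with its mean and maximum cosine
    similarity to the embeddings of currently indicated medications — the
    graph-based plausibility check for repurposing candidates.
    """
    if not indicated:
        raise ValueError("need at least one indicated medication")
    rows = []
    for drug in predicted:
        sims = [
            cosine_similarity(np.asarray(embeddings[drug]), np.asarray(embeddings[ref]))
            for ref in indicated
        ]
        rows.append((drug, float(np.mean(sims)), float(np.max(sims))))
    return pd.DataFrame(rows, columns=["drug_id", "mean_cosine", "max_cosine"])


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set_id: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p_value: float
    adjusted_p: float


def hypergeometric_enrichment(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Over-representation test of a query gene list in each gene set.

    p = P(X >= overlap) with X ~ Hypergeometric(|universe|, |set ∩ universe|,
    |query|); upper tail, inclusive of the observed overlap.  P values are
    Benjamini-Hochberg adjusted across the tested sets.
    """
    universe = set(universe)
    query = set(query_genes)
    if not query:
        raise ValueError("query gene list is empty")
    if not universe:
        raise ValueError("universe is empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        overlap = len(members & query)
        # P(X >= overlap) = sf(overlap - 1)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append((set_id, len(members), overlap, min(p, 1.0)))
    adjusted = benjamini_hochberg([r[3] for r in rows]) if rows else []
    return [
        EnrichmentResult(set_id, len(universe), set_size, len(query), overlap, p, float(adj))
        for (set_id, set_size, overlap, p), adj in zip(rows, adjusted)
    ]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment; original input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DruggabilityRecord:
    gene_id: str
    drugs: tuple[str, ...]
    interaction_types: tuple[str, ...]
    druggable: bool


def druggability(genes: Sequence[str], interactions: pd.DataFrame) -> list[DruggabilityRecord]:
    """Annotate genes as druggable from a (drug, gene, interaction_type) table.

    Only agonist / inhibitor / modulator / activator / antibody rows are
    retained; a gene is druggable iff it keeps at least one row.  Drug lists
    come back deduplicated and sorted.
    """
    required = ["drug_id", "gene_id", "interaction_type"]
    if list(interactions.columns) != required:
        raise ValueError(f"interactions table must have columns {required}")
    for i, row in enumerate(interactions.itertuples(index=False), start=1):
        if not row.drug_id or not row.gene_id or not row.interaction_type:
            raise ValueError(f"malformed interaction row {i}: {tuple(row)}")
    kept = interactions[interactions["interaction_type"].isin(DRUGGABLE_INTERACTION_TYPES)]
    out = []
    for gene in genes:
        sub = kept[kept["gene_id"] == gene]
        out.append(
            DruggabilityRecord(
                gene_id=gene,
                drugs=tuple(sorted(sub["drug_id"].unique())),
                interaction_types=tuple(sorted(sub["interaction_type"].unique())),
                druggable=len(sub) > 0,
            )
        )
    return out


def compare_pathway_counts(
    relevant_with: int, tested_with: int, relevant_without: int, tested_without: int
) -> tuple[float, float]:
    """Chi-squared test on the 2x2 table (relevant, not-relevant) x
    (with imaging, without imaging); returns (statistic, p)."""
    for name, (r, t) in {
        "with": (relevant_with, tested_with),
        "without": (relevant_without, tested_without),
    }.items():
        if r < 0 or t < 0:
            raise ValueError(f"counts must be non-negative ({name} arm)")
        if r > t:
            raise ValueError(f"relevant count exceeds tested count ({name} arm)")
    table = np.array([
        [relevant_with, tested_with - relevant_with],
        [relevant_without, tested_without - relevant_without],
    ])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate 2x2 table: a margin is zero")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


@dataclass
class AblationResult:
    """Paired full-vs-ablated pipeline outputs."""

    full: object
    ablated: object
    full_top: list[tuple[str, float]]
    ablated_top: list[tuple[str, float]]
    top_k_overlap: int
    removed_types: tuple[str, ...]


def ablation_run(
    kg: KnowledgeGraph,
    types_to_remove: Iterable[str],
    pipeline: Callable[[KnowledgeGraph], tuple[object, list[tuple[str, float]]]],
) -> AblationResult:
    """Run the same downstream pipeline on the full and the ablated graph.

    `pipeline` maps a graph to (report, ranked top-k list) and must hold its
    own seeds fixed so the two runs differ only in the graph.
    """
    types_to_remove = tuple(sorted(set(types_to_remove)))
    ablated_kg = remove_node_types(kg, types_to_remove)
    full_report, full_top = pipeline(kg)
    ablated_report, ablated_top = pipeline(ablated_kg)
    overlap = len({p for p, _ in full_top} & {p for p, _ in ablated_top})
    return AblationResult(full_report, ablated_report, full_top, ablated_top, overlap, types_to_remove)
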