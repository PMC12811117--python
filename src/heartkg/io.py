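"""Plain-text table formats.

Everything on disk is diff-able TSV (JSON only for nested report payloads):

* ``nodes.tsv``        — node_id, node_type, properties (JSON object or ``.``)
* ``edges.tsv``        — source_id, target_id, relation_type, properties
* ``ontology_dict.tsv``— node_type, canonical_label, synonym
* ``measurements.tsv`` — individual_id, trait_name, anatomy_label, value, units
* ``labels.tsv``       — anchor_id, partner_id, label
* ``interactions.tsv`` — drug_id, gene_id, interaction_type
* ``embeddings.tsv``   — node_id, dim_1 .. dim_J
* ``*.gmt``            — standard gene-set format

Floats serialize at 10 significant digits with LF line endings so that a
parse -> serialize round trip is byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import EdgeRecord, KnowledgeGraph, NodeRecord, build_graph
from .ontology import OntologyDictionary

FLOAT_FMT = "%.10g"


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return FLOAT_FMT % v
    return str(v)


def _props_to_json(props: dict) -> str:
    if not props:
        return "."
    return json.dumps(props, sort_keys=True, separators=(",", ":"))


def _props_from_json(cell: str, where: str) -> dict:
    if cell in (".", ""):
        return {}
    try:
        obj = json.loads(cell)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON properties at {where}: {exc}") from exc
    if not isinstance(obj, dict):
        raise ValueError(f"properties at {where} must be a JSON object")
    return obj


def _read_tsv(path: str | Path, expected_cols: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or list(reader.fieldnames) != list(expected_cols):
            raise ValueError(
                f"{path}: expected header {list(expected_cols)}, got {reader.fieldnames}"
            )
        return [dict(row) for row in reader]


def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


# -- nodes / edges ---------------------------------------------------------

def write_nodes(kg_or_nodes, path: str | Path) -> None:
    nodes = kg_or_nodes.nodes if isinstance(kg_or_nodes, KnowledgeGraph) else kg_or_nodes
    _write_tsv(
        path,
        ["node_id", "node_type", "properties"],
        ((n.node_id, n.node_type, _props_to_json(n.properties)) for n in nodes),
    )


def write_edges(kg_or_edges, path: str | Path) -> None:
    edges = kg_or_edges.edges if isinstance(kg_or_edges, KnowledgeGraph) else kg_or_edges
    _write_tsv(
        path,
        ["source_id", "target_id", "relation_type", "properties"],
        (
            (e.source_id, e.target_id, e.relation_type, _props_to_json(e.properties))
            for e in edges
        ),
    )


def read_nodes(path: str | Path) -> list[NodeRecord]:
    rows = _read_tsv(path, ["node_id", "node_type", "properties"])
    out = []
    for i, row in enumerate(rows, start=2):
        props = _props_from_json(row["properties"], f"{path} row {i}, column 'properties'")
        out.append(NodeRecord(row["node_id"], row["node_type"], props))
    return out


def read_edges(path: str | Path) -> list[EdgeRecord]:
    rows = _read_tsv(path, ["source_id", "target_id", "relation_type", "properties"])
    out = []
    for i, row in enumerate(rows, start=2):
        props = _props_from_json(row["properties"], f"{path} row {i}, column 'properties'")
        out.append(EdgeRecord(row["source_id"], row["target_id"], row["relation_type"], props))
    return out


def read_graph(nodes_path: str | Path, edges_path: str | Path) -> KnowledgeGraph:
    return build_graph(read_nodes(nodes_path), read_edges(edges_path))


def write_graph(kg: KnowledgeGraph, nodes_path: str | Path, edges_path: str | Path) -> None:
    write_nodes(kg, nodes_path)
    write_edges(kg, edges_path)


# -- ontology dictionary ---------------------------------------------------

def read_ontology_dict(path: str | Path) -> OntologyDictionary:
    rows = _read_tsv(path, ["node_type", "canonical_label", "synonym"])
    entries: dict[str, dict[str, set[str]]] = {}
    for row in rows:
        entries.setdefault(row["node_type"], {}).setdefault(
            row["canonical_label"], set()
        ).add(row["synonym"])
    return OntologyDictionary(entries)


# -- link-prediction label tables -----------------------------------------

def read_labels(path: str | Path) -> pd.DataFrame:
    rows = _read_tsv(path, ["anchor_id", "partner_id", "label"])
    df = pd.DataFrame(rows)
    if len(df):
        bad = ~df["label"].isin({"0", "1"})
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path} row {i}: label must be 0 or 1")
        df["label"] = df["label"].astype(int)
    else:
        df = pd.DataFrame(columns=["anchor_id", "partner_id", "label"])
    return df


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(
        path,
        ["anchor_id", "partner_id", "label"],
        df[["anchor_id", "partner_id", "label"]].itertuples(index=False),
    )


def write_predictions(ranked: Sequence[tuple[str, float]], path: str | Path) -> None:
    _write_tsv(
        path,
        ["partner_id", "probability", "rank"],
        ((pid, float(p), rank) for rank, (pid, p) in enumerate(ranked, start=1)),
    )


# -- drug-gene interactions ------------------------------------------------

def read_interactions(path: str | Path) -> pd.DataFrame:
    rows = _read_tsv(path, ["drug_id", "gene_id", "interaction_type"])
    for i, row in enumerate(rows, start=2):
        if not row["drug_id"] or not row["gene_id"] or not row["interaction_type"]:
            raise ValueError(f"{path} row {i}: empty field in interaction row")
    return pd.DataFrame(rows, columns=["drug_id", "gene_id", "interaction_type"])


# -- imaging measurements --------------------------------------------------

MEASUREMENT_COLS = ["individual_id", "trait_name", "anatomy_label", "value", "units"]


def read_measurements(path: str | Path) -> pd.DataFrame:
    rows = _read_tsv(path, MEASUREMENT_COLS)
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLS)
    if len(df):
        df["value"] = df["value"].astype(float)
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(path, MEASUREMENT_COLS, df[MEASUREMENT_COLS].itertuples(index=False))


# -- gene sets (GMT) -------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """set_id -> member genes (the description column is ignored)."""
    sets: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {lineno}: GMT rows need id, description, >=1 member")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        for set_id, members in sets.items():
            desc = descriptions.get(set_id, "na")
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


# -- embeddings ------------------------------------------------------------

def write_embeddings(node_ids: Sequence[str], matrix: np.ndarray, path: str | Path) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != len(node_ids):
        raise ValueError("embedding matrix must be (n_nodes, J)")
    header = ["node_id"] + [f"dim_{j + 1}" for j in range(matrix.shape[1])]
    _write_tsv(path, header, ((nid, *row) for nid, row in zip(node_ids, matrix)))


def read_embeddings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str})
    if df.columns[0] != "node_id":
        raise ValueError(f"{path}: first column must be node_id")
    return df.set_index("node_id").astype(float)
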