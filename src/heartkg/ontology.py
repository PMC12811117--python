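"""Label harmonization.

Source databases name the same entity in different ways (e.g. the disease
recorded as "congestive heart disease" or "left ventricular failure" is the
entity "heart failure").  Harmonization normalizes raw labels and matches
them against a per-type synonym dictionary mapping each canonical label to
all of its known surface forms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .graph import NODE_TYPES

_PUNCT = re.compile(r"[^\w\s]|_")
_WS = re.compile(r"\s+")


def normalize_label(raw: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace. Idempotent."""
    s = _PUNCT.sub(" ", raw.lower())
    return _WS.sub(" ", s).strip()


@dataclass(frozen=True)
class Unmapped:
    """A label that matched no synonym; carries the normalized form."""

    normalized: str


class OntologyDictionary:
    """canonical label -> synonym set, partitioned by node type.

    Within one node type no synonym may map to two canonical labels, and a
    canonical label is always a synonym of itself (after normalization).
    """

    def __init__(self, entries: Mapping[str, Mapping[str, Iterable[str]]]):
        # entries: node_type -> canonical -> synonyms
        self._index: dict[str, dict[str, str]] = {}
        self._canon: dict[str, dict[str, set[str]]] = {}
        for node_type, canon_map in entries.items():
            if node_type not in NODE_TYPES:
                raise ValueError(f"unknown node_type {node_type!r} in ontology dictionary")
            idx: dict[str, str] = {}
            cmap: dict[str, set[str]] = {}
            for canonical, synonyms in canon_map.items():
                canonical_n = normalize_label(canonical)
                syns = {normalize_label(s) for s in synonyms} | {canonical_n}
                for s in syns:
                    if s in idx and idx[s] != canonical_n:
                        raise ValueError(
                            f"synonym {s!r} maps to both {idx[s]!r} and "
                            f"{canonical_n!r} within node_type {node_type!r}"
                        )
                    idx[s] = canonical_n
                cmap[canonical_n] = syns
            self._index[node_type] = idx
            self._canon[node_type] = cmap

    def node_types(self) -> set[str]:
        return set(self._index)

    def synonyms(self, node_type: str, canonical: str) -> set[str]:
        return set(self._canon[node_type][normalize_label(canonical)])

    def lookup(self, node_type: str, normalized: str) -> str | None:
        return self._index[node_type].get(normalized)


def harmonize(raw: str, node_type: str, dictionary: OntologyDictionary) -> str | Unmapped:
    """Map a raw label to its canonical form, or report it unmapped."""
    if node_type not in dictionary.node_types():
        raise ValueError(f"ontology dictionary has no entries for node_type {node_type!r}")
    normalized = normalize_label(raw)
    hit = dictionary.lookup(node_type, normalized)
    return hit if hit is not None else Unmapped(normalized)


#: Minimal built-in disease dictionary covering the classic harmonization
#: traps for the cardiovascular entities used throughout the examples.
DEFAULT_DISEASE_SYNONYMS = OntologyDictionary({
    "disease": {
        "heart failure": {
            "congestive heart disease",
            "congestive heart failure",
            "left ventricular failure",
        },
        "myocardial infarction": {"heart attack", "acute myocardial infarction"},
        "atrial fibrillation": {"auricular fibrillation", "af"},
    }
})
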