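"""Seeded generator of toy multimodal knowledge graphs.

The generator emulates the *statistical* shape of a cardiovascular KG — 12
node types at realistic relative magnitudes (genes >> individuals >>
medications >> pathways, at roughly 1/20 scale), schema-legal directed
relations, node and edge properties — not its biological content.

The mechanism is low-rank: every node receives a ground-truth latent
vector, and each schema-legal directed pair becomes an edge when the
sigmoid of the scaled latent dot product clears a per-relation cutoff
calibrated to the edge-density target (i.e. the top-scoring pairs per
relation).  Because edges are literally inner-product threshold events,
an inner-product decoder can reconstruct the graph whenever the encoder
recovers the latents: reconstruction failures indicate implementation
bugs, not an unlearnable target.

Planted structure: one anchor disease gets a cluster of positively
correlated genes (known associations; a stated number withheld from both
the graph and the label table as recovery targets), anti-correlated
negative genes, correlated "bridge" phenotypes that connect the cluster
indirectly, and indicated / contraindicated medications.  A ledger records
every latent and every planted truth for test assertions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import EdgeRecord, KnowledgeGraph, NodeRecord, build_graph
from .imaging import (
    aortic_distensibility,
    biplane_atrial_volume,
    du_bois_bsa,
    index_to_bsa,
    linear_strain,
    lv_mass,
)

#: directed schema: (source type, target type, relation, sampling weight)
SCHEMA: tuple[tuple[str, str, str, float], ...] = (
    ("gene", "disease", "associated_with", 8.0),
    ("gene", "biological_process", "participates_in", 20.0),
    ("gene", "cellular_component", "located_in", 10.0),
    ("gene", "molecular_function", "enables", 10.0),
    ("gene", "pathway", "member_of", 12.0),
    ("phenotype", "gene", "associated_with", 10.0),
    ("phenotype", "disease", "associated_with", 6.0),
    ("phenotype", "pathway", "associated_with", 4.0),
    ("medication", "gene", "targets", 8.0),
    ("medication", "disease", "indicated_for", 4.0),
    ("individual", "disease", "diagnosed_with", 6.0),
    ("individual", "medication", "takes", 5.0),
    ("individual", "cmr", "has_measurement", 5.0),
    ("cmr", "anatomy", "measures", 0.5),
    ("anatomy", "disease", "associated_with", 1.0),
    ("air_pollutant", "disease", "exposure_risk", 0.5),
)

#: node counts mimicking the real KG's relative magnitudes at ~1/20 scale
DEFAULT_NODES_PER_TYPE: dict[str, int] = {
    "gene": 900,
    "individual": 240,
    "medication": 105,
    "phenotype": 60,
    "disease": 40,
    "biological_process": 40,
    "pathway": 35,
    "molecular_function": 25,
    "cmr": 21,
    "cellular_component": 20,
    "anatomy": 8,
    "air_pollutant": 6,
}

ETHNICITIES = ("white", "asian", "black", "mixed", "other")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic KG."""

    seed: int
    nodes_per_type: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_NODES_PER_TYPE))
    latent_dim: int = 50
    target_edges: int = 12000
    planted_pairs: int = 30          # positive gene-disease pairs on the anchor
    withheld_pairs: int = 10         # of those, removed from graph + labels
    negative_genes: int = 30
    indicated_medications: int = 15
    contraindicated_medications: int = 15
    bridge_phenotypes: int = 15      # phenotypes correlated with the anchor cluster
    plant_correlation: float = 0.9   # latent correlation of planted partners
    #: latent correlation of curated negatives; mildly anti-correlated —
    #: "no known association" is weak avoidance, not strong opposite coupling
    negative_correlation: float = -0.3
    #: multiplier on the anchor disease's latent norm: common diseases are
    #: hub nodes, and a longer anchor latent separates genuinely coupled
    #: partners (dot ~ rho * |anchor|^2) from the background dot distribution
    anchor_scale: float = 1.5
    #: e-folding scale of the latent variance spectrum: dimension j carries
    #: weight exp(-j / decay), giving an effective rank of ~2*decay out of
    #: latent_dim — relational data has a fast-decaying spectrum, and a node's
    #: handful of edges can only pin down a handful of latent directions
    spectrum_decay: float = 2.0
    imaging_noise_scale: float = 0.05

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.nodes_per_type.values()):
            raise ValueError("node counts must be non-negative")
        if self.planted_pairs and (
            self.nodes_per_type.get("gene", 0) < self.planted_pairs + self.negative_genes
            or self.nodes_per_type.get("disease", 0) < 1
        ):
            raise ValueError("not enough genes/diseases to plant associations")
        if self.withheld_pairs > self.planted_pairs:
            raise ValueError("cannot withhold more pairs than are planted")


def small_config(seed: int) -> SimulationConfig:
    """~500-node / ~5,000-edge variant (1/3 of the default counts)."""
    return SimulationConfig(
        seed=seed,
        nodes_per_type={t: max(1, c // 3) for t, c in DEFAULT_NODES_PER_TYPE.items()},
        target_edges=5000,
        planted_pairs=15,
        withheld_pairs=5,
        negative_genes=15,
        indicated_medications=8,
        contraindicated_medications=8,
        bridge_phenotypes=8,
    )


def _spectrum(config: SimulationConfig) -> np.ndarray:
    return np.exp(-np.arange(config.latent_dim) / config.spectrum_decay)


def _correlated(
    rng: np.random.Generator, anchor: np.ndarray, rho: float, spectrum: np.ndarray
) -> np.ndarray:
    fresh = rng.standard_normal(anchor.shape) * spectrum
    return rho * anchor + np.sqrt(1.0 - rho**2) * fresh


def generate_kg(config: SimulationConfig) -> tuple[KnowledgeGraph, dict]:
    """Generate a schema-legal directed KG plus its ground-truth ledger."""
    rng = np.random.default_rng(config.seed)
    d = config.latent_dim

    ids_by_type: dict[str, list[str]] = {}
    for t in sorted(config.nodes_per_type):
        ids_by_type[t] = [f"{t}_{i:04d}" for i in range(config.nodes_per_type[t])]
    all_ids = [nid for t in sorted(ids_by_type) for nid in ids_by_type[t]]
    spectrum = _spectrum(config)
    latents = {nid: rng.standard_normal(d) * spectrum for nid in all_ids}

    # --- planted structure ------------------------------------------------
    anchor = ids_by_type["disease"][0] if ids_by_type.get("disease") else None
    planted: list[str] = []
    withheld: list[str] = []
    negatives: list[str] = []
    indicated: list[str] = []
    contraindicated: list[str] = []
    bridges: list[str] = []
    if anchor is not None and config.planted_pairs:
        latents[anchor] = latents[anchor] * config.anchor_scale
        a = latents[anchor]
        rho = config.plant_correlation
        genes = ids_by_type["gene"]
        pool = rng.permutation(len(genes))
        planted = [genes[i] for i in pool[: config.planted_pairs]]
        negatives = [
            genes[i] for i in pool[config.planted_pairs: config.planted_pairs + config.negative_genes]
        ]
        withheld = list(rng.permutation(planted)[: config.withheld_pairs])
        for g in planted:
            latents[g] = _correlated(rng, a, rho, spectrum)
        for g in negatives:
            latents[g] = _correlated(rng, a, config.negative_correlation, spectrum)
        n_bridge = min(config.bridge_phenotypes, len(ids_by_type.get("phenotype", [])))
        bridges = ids_by_type["phenotype"][:n_bridge]
        for ph in bridges:
            latents[ph] = _correlated(rng, a, rho, spectrum)
        meds = ids_by_type.get("medication", [])
        mpool = rng.permutation(len(meds))
        indicated = [meds[i] for i in mpool[: config.indicated_medications]]
        contraindicated = [
            meds[i]
            for i in mpool[
                config.indicated_medications: config.indicated_medications
                + config.contraindicated_medications
            ]
        ]
        for m in indicated:
            latents[m] = _correlated(rng, a, rho, spectrum)
        for m in contraindicated:
            latents[m] = _correlated(rng, a, config.negative_correlation, spectrum)

    # --- edges: top-scoring pairs per relation ----------------------------
    capacity = {
        (s, t, r): config.nodes_per_type.get(s, 0) * config.nodes_per_type.get(t, 0)
        for s, t, r, _ in SCHEMA
    }
    if config.target_edges > sum(capacity.values()):
        raise ValueError(
            f"edge-density target {config.target_edges} exceeds schema capacity "
            f"{sum(capacity.values())}"
        )
    edges: list[EdgeRecord] = []
    seen: set[tuple[str, str]] = set()

    def add_edge(s: str, t: str, rel: str, props: dict | None = None) -> None:
        if (s, t) in seen:
            return
        seen.add((s, t))
        edges.append(EdgeRecord(s, t, rel, props or {}))

    # planted associations are forced present (withheld ones are stripped
    # later by plant_associations)
    for g in planted:
        add_edge(g, anchor, "associated_with")
    for m in indicated:
        add_edge(m, anchor, "indicated_for")

    # weight-proportional budgets with water-filling: capacity-capped
    # relations hand their surplus to relations that still have room
    budgets = {key: 0 for key in capacity}
    remaining = config.target_edges
    open_rels = {
        (s, t, r): w for s, t, r, w in SCHEMA
        if capacity[(s, t, r)] > 0
    }
    while remaining > 0 and open_rels:
        wsum = sum(open_rels.values())
        progress = False
        for key, w in list(open_rels.items()):
            share = max(1, int(round(remaining * w / wsum))) if remaining else 0
            take = min(share, capacity[key] - budgets[key], remaining)
            if take > 0:
                budgets[key] += take
                remaining -= take
                progress = True
            if budgets[key] >= capacity[key]:
                del open_rels[key]
        if not progress:
            break

    for s_type, t_type, relation, weight in SCHEMA:
        src_ids, dst_ids = ids_by_type.get(s_type, []), ids_by_type.get(t_type, [])
        budget = budgets.get((s_type, t_type, relation), 0)
        if budget == 0 or not src_ids or not dst_ids:
            continue
        S = np.stack([latents[i] for i in src_ids])
        T = np.stack([latents[i] for i in dst_ids])
        scores = (S @ T.T) / np.sqrt(d)
        flat = np.argsort(scores, axis=None)[::-1]
        taken = 0
        for k in flat:
            if taken >= budget:
                break
            u, v = divmod(int(k), len(dst_ids))
            s_id, t_id = src_ids[u], dst_ids[v]
            if (s_id, t_id) in seen:
                continue
            add_edge(s_id, t_id, relation)
            taken += 1

    # --- node properties and per-individual CMR edge values ---------------
    nodes: list[NodeRecord] = []
    bsa_by_individual: dict[str, float] = {}
    for t in sorted(ids_by_type):
        for nid in ids_by_type[t]:
            props: dict = {}
            if t == "individual":
                height = float(rng.normal(170, 9))
                weight_kg = float(rng.normal(75, 12))
                height = max(height, 140.0)
                weight_kg = max(weight_kg, 40.0)
                bsa = du_bois_bsa(height, weight_kg)
                props = {
                    "sex": "female" if rng.random() < 0.5 else "male",
                    "age": int(rng.integers(45, 80)),
                    "bmi": round(weight_kg / (height / 100) ** 2, 2),
                    "ethnicity": str(rng.choice(ETHNICITIES)),
                    "bsa": round(bsa, 4),
                }
                bsa_by_individual[nid] = bsa
            elif t == "cmr":
                props = {"trait_name": f"trait_{nid.split('_')[-1]}"}
            nodes.append(NodeRecord(nid, t, props))
    for e in edges:
        if e.relation_type == "has_measurement":
            e.properties["value"] = float(np.round(rng.normal(50, 12), 4))
            e.properties["units"] = "au"

    kg = build_graph(nodes, edges)
    ledger = {
        "seed": config.seed,
        "latent_dim": d,
        "latents": {nid: latents[nid].tolist() for nid in all_ids},
        "anchor_disease": anchor,
        "planted_positive_genes": sorted(planted),
        "withheld_positive_genes": sorted(withheld),
        "negative_genes": sorted(negatives),
        "bridge_phenotypes": sorted(bridges),
        "indicated_medications": sorted(indicated),
        "contraindicated_medications": sorted(contraindicated),
        "bsa_by_individual": {k: round(v, 6) for k, v in bsa_by_individual.items()},
    }
    return kg, ledger


def plant_associations(
    kg: KnowledgeGraph, ledger: dict, config: SimulationConfig
) -> tuple[KnowledgeGraph, pd.DataFrame, pd.DataFrame, dict]:
    """Strip withheld pairs from the graph and emit label tables.

    Returns (graph without withheld edges, gene labels, medication labels,
    held-out truth).  Withheld planted pairs appear in neither the edge set
    nor the labels; they are the recovery targets.
    """
    anchor = ledger["anchor_disease"]
    withheld = set(ledger["withheld_positive_genes"])
    kept_positives = [g for g in ledger["planted_positive_genes"] if g not in withheld]
    if anchor is None:
        empty = pd.DataFrame(columns=["anchor_id", "partner_id", "label"])
        return kg, empty, empty.copy(), {"anchor": None, "withheld": []}

    edges = [
        e for e in kg.edges
        if not (e.target_id == anchor and e.source_id in withheld)
    ]
    stripped = build_graph(kg.nodes, edges)

    gene_rows = [(anchor, g, 1) for g in kept_positives] + [
        (anchor, g, 0) for g in ledger["negative_genes"]
    ]
    gene_labels = pd.DataFrame(gene_rows, columns=["anchor_id", "partner_id", "label"])
    drug_rows = [(anchor, m, 1) for m in ledger["indicated_medications"]] + [
        (anchor, m, 0) for m in ledger["contraindicated_medications"]
    ]
    drug_labels = pd.DataFrame(drug_rows, columns=["anchor_id", "partner_id", "label"])
    heldout = {"anchor": anchor, "withheld": sorted(withheld)}
    return stripped, gene_labels, drug_labels, heldout


#: imaging trait recipes: (trait_name, anatomy label, units)
IMAGING_TRAITS = (
    ("la_volume_biplane", "anatomy_0000", "ml"),
    ("lv_mass", "anatomy_0001", "g"),
    ("lv_circumferential_strain", "anatomy_0001", "ratio"),
    ("lv_circumferential_strain_bsai", "anatomy_0001", "ratio/m2"),
    ("aortic_distensibility", "anatomy_0002", "1e-3/mmHg"),
    ("bsa", "anatomy_0003", "m2"),
)


def generate_imaging_rows(config: SimulationConfig, n_individuals: int | None = None) -> pd.DataFrame:
    """Per-individual plausible-range imaging measurements.

    Raw chamber measurements are drawn from population-plausible normal
    ranges with multiplicative noise at ``imaging_noise_scale``; derived
    traits come from the closed-form phenotype formulas, so every row
    satisfies the formulas' positivity preconditions.
    """
    rng = np.random.default_rng(config.seed + 101)
    n = n_individuals if n_individuals is not None else config.nodes_per_type.get("individual", 0)
    if n <= 0:
        raise ValueError("need at least one individual")
    rows = []
    noise = config.imaging_noise_scale
    for i in range(n):
        ind = f"individual_{i:04d}"
        jitter = lambda x: float(x * (1.0 + noise * rng.standard_normal()))
        a2 = max(jitter(20.0), 5.0)           # cm^2
        a4 = max(jitter(21.0), 5.0)
        length = max(jitter(5.5), 2.0)        # cm
        myo_vol = max(jitter(110.0), 40.0)    # ml
        l_dir, dl = max(jitter(10.0), 4.0), jitter(-2.0)
        a_min = max(jitter(550.0), 200.0)     # mm^2
        a_max = a_min + abs(jitter(60.0))
        pp = max(jitter(45.0), 20.0)          # mmHg
        height = max(jitter(170.0), 140.0)
        weight = max(jitter(75.0), 40.0)
        bsa = du_bois_bsa(height, weight)
        strain = linear_strain(l_dir, dl)
        values = {
            "la_volume_biplane": biplane_atrial_volume(a2, a4, length),
            "lv_mass": lv_mass(myo_vol),
            "lv_circumferential_strain": strain,
            "lv_circumferential_strain_bsai": index_to_bsa(strain, bsa),
            "aortic_distensibility": aortic_distensibility(a_max, a_min, pp),
            "bsa": bsa,
        }
        for trait, anatomy, units in IMAGING_TRAITS:
            rows.append((ind, trait, anatomy, round(values[trait], 6), units))
    return pd.DataFrame(
        rows, columns=["individual_id", "trait_name", "anatomy_label", "value", "units"]
    )


def write_ledger(ledger: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
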