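import numpy as np
import pytest

from heartkg import dvgae, pipeline, simulate
from heartkg.graph import EdgeRecord, NodeRecord, build_graph, remove_node_types


@pytest.fixture
def toy_kg():
    """Hand-built five-node graph exercising all record kinds."""
    nodes = [
        NodeRecord("g1", "gene"),
        NodeRecord("g2", "gene"),
        NodeRecord("d1", "disease"),
        NodeRecord("c1", "cmr", {"trait_name": "lv_mass"}),
        NodeRecord("p1", "individual", {"age": 60, "sex": "female", "bsa": 1.8}),
    ]
    edges = [
        EdgeRecord("g1", "d1", "associated_with"),
        EdgeRecord("g2", "d1", "associated_with"),
        EdgeRecord("p1", "c1", "has_measurement", {"value": 105.0}),
        EdgeRecord("p1", "d1", "diagnosed_with"),
    ]
    return build_graph(nodes, edges)


@pytest.fixture(scope="session")
def tiny_sim():
    """Miniature synthetic KG (fast enough for unit tests)."""
    cfg = simulate.SimulationConfig(
        seed=11,
        nodes_per_type={t: max(1, c // 12) for t, c in simulate.DEFAULT_NODES_PER_TYPE.items()},
        target_edges=1200,
        planted_pairs=6,
        withheld_pairs=2,
        negative_genes=6,
        indicated_medications=3,
        contraindicated_medications=3,
        bridge_phenotypes=3,
    )
    kg, ledger = simulate.generate_kg(cfg)
    return cfg, kg, ledger


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_trained():
    """~500-node synthetic KG trained with the selected configuration
    (lr 0.001, 100 epochs, J=50); shared by reconstruction and held-out
    evaluation tests."""
    cfg = simulate.small_config(7)
    kg, ledger = simulate.generate_kg(cfg)
    kg, gene_labels, drug_labels, heldout = simulate.plant_associations(kg, ledger, cfg)
    grid = [dvgae.EncoderConfig(learning_rate=0.001, epochs=100, latent_dim=50, seed=7)]
    result = dvgae.train(kg, grid=grid, seed=7, refit_full=True)
    return {
        "config": cfg,
        "kg": kg,
        "ledger": ledger,
        "gene_labels": gene_labels,
        "drug_labels": drug_labels,
        "heldout": heldout,
        "result": result,
    }


@pytest.fixture(scope="session")
def default_recovery():
    """Full pipeline on the default-size synthetic KG plus the
    bridge-type ablation rerun; shared by the link-recovery tests."""
    cfg = simulate.SimulationConfig(seed=7)
    kg, ledger = simulate.generate_kg(cfg)
    kg, gene_labels, _drugs, heldout = simulate.plant_associations(kg, ledger, cfg)
    withheld = sorted(heldout["withheld"])
    anchor = heldout["anchor"]
    labeled = set(gene_labels["partner_id"]) | set(withheld)
    anchored = {e.source_id for e in kg.edges if e.target_id == anchor}
    pool = [
        n.node_id for n in kg.nodes
        if n.node_type == "gene" and n.node_id not in labeled and n.node_id not in anchored
    ]
    decoys = list(np.random.default_rng(7).choice(pool, size=100, replace=False))

    full = pipeline.run_link_prediction(kg, gene_labels, "gene", seed=7, top_k=10)
    ablated_kg = remove_node_types(kg, {"phenotype"})
    ablated = pipeline.run_link_prediction(ablated_kg, gene_labels, "gene", seed=7, top_k=10)
    return {
        "kg": kg,
        "gene_labels": gene_labels,
        "withheld": withheld,
        "decoys": decoys,
        "full": full,
        "ablated": ablated,
    }
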