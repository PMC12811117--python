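"""Imaging-derived cardiovascular phenotypes.

Closed-form trait formulas computed from segmented cardiac MR measurements,
plus the bridge that writes each trait into the knowledge graph as a ``cmr``
node linked to its anatomical region, with per-individual values carried as
edge properties.

Units are fixed: areas in cm^2 (aortic areas in mm^2), lengths and height in
cm, volumes in ml, weight in kg, pressures in mmHg.  Aortic distensibility
is reported on the conventional 10^-3 mmHg^-1 scale as relative area change
over central pulse pressure; the inputs are the segmented maximum/minimum
aortic cross-sections and pulse-wave-derived pressure.
"""

from __future__ import annotations

import math

import pandas as pd

from .graph import EdgeRecord, KnowledgeGraph, NodeRecord, build_graph

LV_MYOCARDIAL_DENSITY_G_PER_ML = 1.05
DU_BOIS_COEF = 0.007184


def biplane_atrial_volume(a_2ch: float, a_4ch: float, length: float) -> float:
    """Biplane area-length atrial volume: V = (8 / 3*pi) * A2Ch * A4Ch / L.

    ``a_2ch`` and ``a_4ch`` are the atrial areas (cm^2) in the two- and
    four-chamber cine views; ``length`` is the mean longitudinal diameter
    (cm) across both views.  Returns ml.
    """
    if a_2ch <= 0 or a_4ch <= 0:
        raise ValueError("atrial areas must be strictly positive")
    if length <= 0:
        raise ValueError("longitudinal diameter must be strictly positive")
    return (8.0 / (3.0 * math.pi)) * a_2ch * a_4ch / length


def du_bois_bsa(height_cm: float, weight_kg: float) -> float:
    """Du Bois body surface area (m^2): 0.007184 * h^0.725 * w^0.425."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be strictly positive")
    return DU_BOIS_COEF * height_cm**0.725 * weight_kg**0.425


def lv_mass(myocardial_volume_ml: float) -> float:
    """Left-ventricular mass (g) at myocardial density 1.05 g/ml."""
    if myocardial_volume_ml < 0:
        raise ValueError("myocardial volume must be non-negative")
    return myocardial_volume_ml * LV_MYOCARDIAL_DENSITY_G_PER_ML


def linear_strain(l_dir: float, delta_l_dir: float) -> float:
    """Linear (Lagrangian) strain E = delta_L / L along one direction."""
    if l_dir <= 0:
        raise ValueError("baseline segment length must be strictly positive")
    return delta_l_dir / l_dir


def index_to_bsa(value: float, bsa: float) -> float:
    """Index a measurement to body surface area (value / BSA)."""
    if bsa <= 0:
        raise ValueError("BSA must be strictly positive")
    return value / bsa


def aortic_distensibility(a_max: float, a_min: float, pulse_pressure: float) -> float:
    """Aortic distensibility, 10^-3 mmHg^-1.

    (A_max - A_min) / (A_min * pulse_pressure), scaled by 10^3.
    """
    if a_min <= 0:
        raise ValueError("minimum aortic area must be strictly positive")
    if a_max < a_min:
        raise ValueError("maximum aortic area must be >= minimum area")
    if pulse_pressure <= 0:
        raise ValueError("pulse pressure must be strictly positive")
    return 1e3 * (a_max - a_min) / (a_min * pulse_pressure)


def emit_cmr_nodes(measurements: pd.DataFrame, kg: KnowledgeGraph) -> KnowledgeGraph:
    """Merge imaging traits into the graph as cmr nodes.

    Each distinct trait becomes one ``cmr`` node, connected outward to its
    anatomical region (``cmr -> anatomy``, relation ``measures``) and inward
    from each measured individual (``individual -> cmr``, relation
    ``has_measurement``) with the trait value and units as edge properties.
    The trait value never lives on the cmr node itself.
    """
    if measurements.empty:
        return kg

    anatomy_by_label = {
        n.node_id: n for n in kg.nodes if n.node_type == "anatomy"
    }
    nodes = list(kg.nodes)
    edges = list(kg.edges)
    seen_traits: dict[str, str] = {}

    for row in measurements.itertuples(index=False):
        trait_id = f"cmr:{row.trait_name}"
        if row.anatomy_label not in anatomy_by_label:
            raise ValueError(
                f"measurement of {row.trait_name!r} references unknown anatomy "
                f"{row.anatomy_label!r}"
            )
        if not kg.has_node(row.individual_id):
            raise ValueError(
                f"measurement of {row.trait_name!r} references unknown individual "
                f"{row.individual_id!r}"
            )
        if trait_id not in seen_traits:
            nodes.append(NodeRecord(trait_id, "cmr", {"trait_name": row.trait_name}))
            edges.append(EdgeRecord(trait_id, row.anatomy_label, "measures"))
            seen_traits[trait_id] = row.anatomy_label
        edges.append(
            EdgeRecord(
                row.individual_id,
                trait_id,
                "has_measurement",
                {"value": float(row.value), "units": str(row.units)},
            )
        )
    return build_graph(nodes, edges)
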