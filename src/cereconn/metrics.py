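"""Nodal and network-level graph metrics and the 33-feature table.

Per graph, nodal strength is the sum of absolute incident weights and the
local clustering coefficient is the weighted (Onnela geometric-mean) form on
|w| rescaled by the graph maximum.  Network-level features are the mean
signed weight between every unordered pair of networks (self-pairs
included), the mean signed weight within each network, and each network's
degree (sum of its cross-network means).  A six-network atlas therefore
yields 21 + 6 + 6 = 33 features per subject x condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectomeGraph
from .types import AtlasMap, ValidationError

#: Metadata columns preceding the feature columns in every table.
META_COLUMNS = ["subject_id", "condition", "group"]


def pair_name(k: str, m: str) -> str:
    """Canonical inter-network feature name (alphabetical, e.g. CER-SM)."""
    a, b = sorted((k, m))
    return f"{a}-{b}"


def network_feature_columns(networks: tuple[str, ...] | list[str]) -> list[str]:
    """Stable feature-column order: inter pairs (incl. self), intra, degree."""
    inter = [pair_name(k, m) for k, m in combinations_with_replacement(networks, 2)]
    intra = [f"intra_{k}" for k in networks]
    degree = [f"degree_{k}" for k in networks]
    return inter + intra + degree


def feature_class(name: str) -> str:
    """Classify a network-level feature name as inter / intra / degree."""
    if name.startswith("intra_"):
        return "intra"
    if name.startswith("degree_"):
        return "degree"
    return "inter"


@dataclass
class FeatureTable:
    """Network-level (and optionally nodal) metric tables for a set of graphs.

    ``network`` has one row per (subject_id, condition) with the 33 feature
    columns after the metadata columns.  The nodal companions hold one
    column per ROI.
    """

    network: pd.DataFrame
    feature_columns: list[str]
    nodal_strength: pd.DataFrame | None = None
    nodal_clustering: pd.DataFrame | None = None


def nodal_strength(g: ConnectomeGraph) -> np.ndarray:
    """Weighted degree per ROI: sum of absolute incident weights."""
    return np.abs(g.weights).sum(axis=1)


def local_clustering(g: ConnectomeGraph) -> np.ndarray:
    """Weighted local clustering coefficient per ROI.

    Onnela geometric-mean form on absolute weights rescaled by the graph's
    maximum absolute weight; isolated and degree-1 nodes get 0.
    """
    absw = np.abs(g.weights)
    graph = nx.from_numpy_array(absw)
    c = nx.clustering(graph, weight="weight")
    return np.array([c[i] for i in range(g.n_rois)], dtype=float)


def inter_network(g: ConnectomeGraph, atlas: AtlasMap, k: str, m: str) -> float:
    """Mean signed weight over all ROI pairs between networks k and m.

    For k == m the denominator is |N_k|^2 and the zero diagonal is included,
    per the literal block-average definition.
    """
    ik, im = atlas.indices(k), atlas.indices(m)
    block = g.weights[np.ix_(ik, im)]
    return float(block.sum() / (len(ik) * len(im)))


def intra_network(g: ConnectomeGraph, atlas: AtlasMap, k: str) -> float:
    """Mean signed weight over the unique within-network ROI pairs."""
    ik = atlas.indices(k)
    n = len(ik)
    if n < 2:
        raise ValidationError(f"network {k!r} has fewer than 2 ROIs")
    block = g.weights[np.ix_(ik, ik)]
    iu = np.triu_indices(n, k=1)
    return float(block[iu].sum() / (n * (n - 1) / 2))


def network_degree(inter_values: dict[str, float], k: str, networks: tuple[str, ...]) -> float:
    """Sum of a network's inter-network means over the other networks."""
    return float(sum(inter_values[pair_name(k, m)] for m in networks if m != k))


def network_averages(g: ConnectomeGraph, atlas: AtlasMap) -> pd.DataFrame:
    """Per-network mean nodal strength and mean clustering coefficient."""
    deg = nodal_strength(g)
    clust = local_clustering(g)
    rows = []
    for k in atlas.networks:
        idx = atlas.indices(k)
        rows.append(
            {"network": k, "mean_strength": float(deg[idx].mean()),
             "mean_clustering": float(clust[idx].mean())}
        )
    return pd.DataFrame(rows).set_index("network")


def _network_features(g: ConnectomeGraph, atlas: AtlasMap) -> dict[str, float]:
    nets = atlas.networks
    inter = {
        pair_name(k, m): inter_network(g, atlas, k, m)
        for k, m in combinations_with_replacement(nets, 2)
    }
    feats = dict(inter)
    for k in nets:
        feats[f"intra_{k}"] = intra_network(g, atlas, k)
    for k in nets:
        feats[f"degree_{k}"] = network_degree(inter, k, nets)
    return feats


def build_feature_table(
    graphs: list[ConnectomeGraph], atlas: AtlasMap, *, nodal: bool = True
) -> FeatureTable:
    """Assemble network-level (and nodal) feature tables from graphs."""
    atlas.require_min_sizes(2)
    cols = network_feature_columns(atlas.networks)
    seen: set[tuple[str, str]] = set()
    net_rows, deg_rows, clu_rows = [], [], []
    for g in graphs:
        key = (g.subject_id, g.condition)
        if key in seen:
            raise ValidationError(f"duplicate (subject, condition) pair {key}")
        seen.add(key)
        if g.n_rois != atlas.n_rois:
            raise ValidationError(
                f"graph {key} has {g.n_rois} ROIs but atlas has {atlas.n_rois}"
            )
        meta = {"subject_id": g.subject_id, "condition": g.condition, "group": g.group}
        net_rows.append({**meta, **_network_features(g, atlas)})
        if nodal:
            deg = nodal_strength(g)
            clu = local_clustering(g)
            deg_rows.append({**meta, **dict(zip(atlas.roi_labels, deg))})
            clu_rows.append({**meta, **dict(zip(atlas.roi_labels, clu))})
    network = pd.DataFrame(net_rows, columns=META_COLUMNS + cols)
    table = FeatureTable(network=network, feature_columns=cols)
    if nodal:
        roi_cols = META_COLUMNS + list(atlas.roi_labels)
        table.nodal_strength = pd.DataFrame(deg_rows, columns=roi_cols)
        table.nodal_clustering = pd.DataFrame(clu_rows, columns=roi_cols)
    return table
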