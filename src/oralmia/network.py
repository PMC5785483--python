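"""Co-occurrence networks over differentially abundant OTUs.

Edges connect OTU pairs whose Spearman correlation across the selected
samples exceeds a magnitude threshold (strictly); zero-variance OTUs are kept
as isolated nodes.  Being rank-based, the network is invariant to per-sample
depth rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .difftax import relative_abundance
from .io_tables import OtuTable, ValidationError

__all__ = ["CoocNetwork", "build_network", "network_stats"]

logger = logging.getLogger(__name__)


@dataclass
class CoocNetwork:
    """Undirected co-occurrence graph with node/edge attributes.

    Node attributes: ``mean_rel_abund``, ``genus``, ``direction``.
    Edge attributes: ``rho`` and ``sign`` ("positive"/"negative").
    """

    graph: nx.Graph
    threshold: float
    excluded: list[str] = field(default_factory=list)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


def _genus_of(lineage: str) -> str:
    parts = [p for p in lineage.split(";") if p]
    return parts[4] if len(parts) > 4 else (parts[-1] if parts else "")


def build_network(
    table: OtuTable,
    significant_otus,
    threshold: float = 0.5,
    directions: dict[str, str] | None = None,
) -> CoocNetwork:
    """Thresholded Spearman co-occurrence network over ``significant_otus``.

    Keeps an edge iff ``|rho| > threshold`` (strict).  OTUs with zero
    variance across the samples are excluded from edge computation but
    retained as isolated nodes (and logged).
    """
    otus = list(significant_otus)
    if len(otus) < 2:
        raise ValidationError("need >= 2 significant OTUs")
    if table.n_samples < 4:
        raise ValidationError("need >= 4 samples")
    if not 0 <= threshold <= 1:
        raise ValidationError("threshold must lie in [0, 1]")
    rel = relative_abundance(table).loc[otus]
    graph = nx.Graph()
    directions = directions or {}
    for otu in otus:
        graph.add_node(
            otu,
            mean_rel_abund=float(rel.loc[otu].mean()),
            genus=_genus_of(table.taxonomy.get(otu, "")),
            direction=directions.get(otu, ""),
        )
    variances = rel.var(axis=1)
    excluded = [o for o in otus if variances[o] == 0]
    if excluded:
        logger.warning("zero-variance OTUs kept as isolated nodes: %s", excluded)
    active = [o for o in otus if o not in set(excluded)]
    if len(active) >= 2:
        matrix = rel.loc[active].to_numpy(dtype=float)
        rho = np.asarray(stats.spearmanr(matrix, axis=1).statistic)
        if rho.ndim == 0:  # scipy returns a scalar for exactly two variables
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                r = float(rho[i, j])
                if abs(r) > threshold:
                    graph.add_edge(
                        active[i],
                        active[j],
                        rho=r,
                        sign="positive" if r > 0 else "negative",
                    )
    return CoocNetwork(graph, threshold, excluded)


def network_stats(net: CoocNetwork) -> dict:
    """Deterministic summaries: edge counts, degree sequence, components."""
    graph = net.graph
    degrees = sorted((d for _, d in graph.degree()), reverse=True)
    signs = [attrs["sign"] for _, _, attrs in graph.edges(data=True)]
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_positive_edges": signs.count("positive"),
        "n_negative_edges": signs.count("negative"),
        "degree_sequence": degrees,
        "n_components": nx.number_connected_components(graph),
        "component_sizes": sorted(
            (len(c) for c in nx.connected_components(graph)), reverse=True
        ),
    }
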