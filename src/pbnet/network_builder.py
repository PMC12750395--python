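"""Molecular-network assembly with FBMN topology rules.

Edges are pairwise modified-cosine scores that clear a cosine and
matched-peak threshold; the graph is then pruned with the GNPS topology
filters: mutual top-K neighbour rank, followed by iterative removal of the
weakest edge inside any connected component ("molecular family") larger
than the component-size cap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .spectral_similarity import ProcessedSpectrum, SimilarityParams, modified_cosine

__all__ = [
    "NetworkParams",
    "Edge",
    "MolecularNetwork",
    "NetworkStats",
    "build_edges",
    "apply_topk",
    "split_components",
    "build_network",
    "network_stats",
]


@dataclass(frozen=True)
class NetworkParams:
    """FBMN topology parameters (GNPS defaults)."""

    min_cosine: float = 0.7
    min_matched_peaks: int = 6
    top_k: int = 10
    max_component_size: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.min_cosine <= 1):
            raise ValueError("min_cosine must be in (0, 1]")
        if min(self.min_matched_peaks, self.top_k, self.max_component_size) <= 0:
            raise ValueError("all topology parameters must be positive")


@dataclass(frozen=True)
class Edge:
    """A retained similarity edge; node ids are stored sorted."""

    id_a: str
    id_b: str
    cosine: float
    matched_peaks: int
    delta_mz: float  # precursor m/z of id_b minus id_a (sorted order)

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass
class MolecularNetwork:
    """Nodes (feature attributes) plus cosine-weighted retained edges."""

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: dict[tuple[str, str], Edge] = field(default_factory=dict)

    def add_edge(self, edge: Edge) -> None:
        if edge.id_a == edge.id_b:
            raise ValueError("self-edges are not allowed")
        if edge.id_a not in self.nodes or edge.id_b not in self.nodes:
            raise ValueError("edge references unknown node")
        self.edges[edge.key] = edge

    def degree(self, node_id: str) -> int:
        return sum(1 for k in self.edges if node_id in k)

    def components(self) -> list[set[str]]:
        comps = nx.connected_components(self.to_networkx())
        return sorted((set(c) for c in comps), key=lambda c: sorted(c)[0])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for nid in sorted(self.nodes):
            g.add_node(nid, **self.nodes[nid])
        for key in sorted(self.edges):
            e = self.edges[key]
            g.add_edge(e.id_a, e.id_b, cosine=e.cosine, matched_peaks=e.matched_peaks, delta_mz=e.delta_mz)
        return g


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_singletons: int
    n_edges: int
    n_components: int
    largest_component: int


def build_edges(
    spectra: Iterable[ProcessedSpectrum],
    sim_params: SimilarityParams = SimilarityParams(),
    net_params: NetworkParams = NetworkParams(),
) -> list[Edge]:
    """Score all usable spectrum pairs and keep those clearing thresholds."""
    usable = [s for s in spectra if s.usable]
    edges: list[Edge] = []
    for a, b in itertools.combinations(usable, 2):
        result = modified_cosine(a, b, sim_params)
        if result.score >= net_params.min_cosine and result.n_matched >= net_params.min_matched_peaks:
            id_a, id_b = sorted((a.feature_id, b.feature_id))
            prec = {a.feature_id: a.precursor_mz, b.feature_id: b.precursor_mz}
            edges.append(
                Edge(
                    id_a=id_a,
                    id_b=id_b,
                    cosine=result.score,
                    matched_peaks=result.n_matched,
                    delta_mz=prec[id_b] - prec[id_a],
                )
            )
    return edges


def apply_topk(edges: list[Edge], top_k: int) -> list[Edge]:
    """Keep an edge only if each endpoint ranks the other in its top-K.

    Neighbour rank is by descending cosine; exact cosine ties are ranked by
    node id so the filter is deterministic.
    """
    by_node: dict[str, list[Edge]] = {}
    for e in edges:
        by_node.setdefault(e.id_a, []).append(e)
        by_node.setdefault(e.id_b, []).append(e)
    allowed: dict[str, set[tuple[str, str]]] = {}
    for nid, incident in by_node.items():
        ranked = sorted(incident, key=lambda e: (-e.cosine, e.key))
        allowed[nid] = {e.key for e in ranked[:top_k]}
    return [e for e in edges if e.key in allowed[e.id_a] and e.key in allowed[e.id_b]]


def split_components(network: MolecularNetwork, max_component_size: int) -> MolecularNetwork:
    """Iteratively drop the weakest edge of any oversized molecular family.

    Ties on cosine break toward the lexicographically smallest (id, id) pair,
    making the result deterministic.
    """
    net = MolecularNetwork(nodes=dict(network.nodes), edges=dict(network.edges))
    g = net.to_networkx()
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_component_size]
        if not oversized:
            break
        comp = min(oversized, key=lambda c: sorted(c)[0])
        worst = min(
            (net.edges[tuple(sorted((u, v)))] for u, v in g.subgraph(comp).edges),
            key=lambda e: (e.cosine, e.key),
        )
        g.remove_edge(*worst.key)
        del net.edges[worst.key]
    return net


def build_network(
    spectra: Iterable[ProcessedSpectrum],
    sim_params: SimilarityParams = SimilarityParams(),
    net_params: NetworkParams = NetworkParams(),
    node_attrs: Mapping[str, Mapping] | None = None,
) -> MolecularNetwork:
    """Full pipeline: pair scoring, top-K filter, component-size split."""
    spectra = list(spectra)
    edges = apply_topk(build_edges(spectra, sim_params, net_params), net_params.top_k)
    net = MolecularNetwork()
    for s in spectra:
        attrs = {"mz": s.precursor_mz, "rt": s.rt, "usable": s.usable}
        if node_attrs and s.feature_id in node_attrs:
            attrs.update(node_attrs[s.feature_id])
        net.nodes[s.feature_id] = attrs
    for e in edges:
        net.add_edge(e)
    return split_components(net, net_params.max_component_size)


def network_stats(network: MolecularNetwork) -> NetworkStats:
    """Node/singleton/edge/component counts; a singleton has degree zero."""
    degree: dict[str, int] = {nid: 0 for nid in network.nodes}
    for id_a, id_b in network.edges:
        degree[id_a] += 1
        degree[id_b] += 1
    comps = network.components()
    return NetworkStats(
        n_nodes=len(network.nodes),
        n_singletons=sum(1 for d in degree.values() if d == 0),
        n_edges=len(network.edges),
        n_components=len(comps),
        largest_component=max((len(c) for c in comps), default=0),
    )
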