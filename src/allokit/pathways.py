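"""Optimal and suboptimal signalling pathways on correlation networks.

Edges are weighted ``w_ij = -ln(r_MI)`` so that minimizing the total weight of
a residue-to-residue path maximizes the product of generalized correlations
along it.  The optimal path is found with Dijkstra's algorithm (multiple
sources are handled through a virtual zero-weight super-source; ranking is
global, not per-source) and the k suboptimal paths with Yen's loopless
k-shortest-paths scheme.  Merged path residues are classified as internal
(buried) or external (solvent-exposed) by their relative solvent accessibility
on the ensemble-mean structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import biotite.structure as struc

from .ensembles import Ensemble, Topology, to_atom_array
from .errors import NoPathError
from .network import CorrelationNetwork

__all__ = [
    "WeightedGraph",
    "PathSet",
    "edge_weights",
    "shortest_path",
    "k_suboptimal_paths",
    "relative_sasa",
    "classify_exposure",
    "MAX_SASA",
]

R_MI_FLOOR = 1e-8
R_MI_CEIL = 1.0 - 1e-12

#: theoretical maximum solvent accessibility per residue type (Å²),
#: Tien et al. 2013; used to normalize per-residue SASA
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class WeightedGraph:
    """Symmetric non-negative edge weights ``w = -ln(clamped r_MI)``."""

    nodes: list[str]
    weights: np.ndarray             # (N, N), >= 0
    clamped: np.ndarray | None = None   # bool mask of floor/ceiling-clamped edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        n = len(self.nodes)
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            w = float(self.weights[i, j])
            if np.isfinite(w):        # infinite weight means "no edge"
                g.add_edge(self.nodes[i], self.nodes[j], weight=w)
        return g


@dataclass
class PathSet:
    """Ranked loopless paths from a source set to a destination node."""

    paths: list[tuple[list[str], float]]    # (node sequence, total weight)
    sources: list[str]
    dest: str
    node_counts: dict[str, int] = field(default_factory=dict)
    exposure: dict[str, str] = field(default_factory=dict)  # node -> internal|external
    external_fraction: float | None = None
    rel_sasa_threshold: float | None = None

    def __post_init__(self):
        ws = [w for _, w in self.paths]
        if any(b < a - 1e-12 for a, b in zip(ws, ws[1:])):
            raise ValueError("paths must be sorted by non-decreasing total weight")
        if not self.node_counts:
            counts: dict[str, int] = {}
            for nodes, _ in self.paths:
                for n in nodes:
                    counts[n] = counts.get(n, 0) + 1
            self.node_counts = counts


def edge_weights(network: CorrelationNetwork,
                 threshold: float = 0.0) -> WeightedGraph:
    """Convert an r_MI adjacency into path weights ``-ln(r_MI)``.

    r_MI values are clamped to ``[1e-8, 1 - 1e-12]`` before the logarithm so
    uncorrelated pairs get a large-but-finite weight and perfectly correlated
    pairs a (near-)free edge; the clamp mask is recorded per edge.  An
    optional ``threshold`` treats r_MI values below it as no correlation at
    all (floored), which suppresses estimator-noise edges on finite
    ensembles.
    """
    a = network.matrix.copy()
    a[a < threshold] = 0.0
    clamped = (a < R_MI_FLOOR) | (a > R_MI_CEIL)
    np.fill_diagonal(clamped, False)
    w = -np.log(np.clip(a, R_MI_FLOOR, R_MI_CEIL))
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(nodes=list(network.nodes), weights=w, clamped=clamped)


_SUPER_SOURCE = "__source__"


def _multi_source_graph(graph: WeightedGraph, sources) -> nx.Graph:
    g = graph.to_networkx()
    missing = [s for s in sources if s not in g]
    if missing:
        raise KeyError(f"source nodes not in graph: {missing}")
    g.add_node(_SUPER_SOURCE)
    for s in sources:
        g.add_edge(_SUPER_SOURCE, s, weight=0.0)
    return g


def shortest_path(graph: WeightedGraph, sources, dest: str
                  ) -> tuple[list[str], float]:
    """Minimum-total-weight path from any source to ``dest`` (Dijkstra).

    The total weight equals ``-ln`` of the product of r_MI values along the
    path (up to clamping).
    """
    sources = [sources] if isinstance(sources, str) else list(sources)
    g = _multi_source_graph(graph, sources)
    if dest not in g:
        raise KeyError(f"destination {dest!r} not in graph")
    try:
        length, path = nx.single_source_dijkstra(g, _SUPER_SOURCE, dest)
    except nx.NetworkXNoPath:
        raise NoPathError(
            f"destination {dest!r} unreachable from sources {sources}") from None
    return path[1:], float(length)


def k_suboptimal_paths(graph: WeightedGraph, sources, dest: str, k: int = 50
                       ) -> PathSet:
    """The ``k`` cheapest loopless paths, globally ranked across all sources.

    Yen-style k-shortest simple paths; if fewer than ``k`` simple paths exist
    they are all returned.  The merged node multiset counts path membership
    per residue.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sources = [sources] if isinstance(sources, str) else list(sources)
    g = _multi_source_graph(graph, sources)
    if dest not in g:
        raise KeyError(f"destination {dest!r} not in graph")
    try:
        gen = nx.shortest_simple_paths(g, _SUPER_SOURCE, dest, weight="weight")
        ranked = []
        for path in gen:
            w = sum(g[a][b]["weight"] for a, b in zip(path, path[1:]))
            ranked.append((path[1:], float(w)))
            if len(ranked) >= k:
                break
    except nx.NetworkXNoPath:
        raise NoPathError(
            f"destination {dest!r} unreachable from sources {sources}") from None
    # shortest_simple_paths yields by non-decreasing weight already; keep a
    # stable heap-merge guard against floating-point ties
    ranked.sort(key=lambda pw: pw[1])
    return PathSet(paths=ranked, sources=sources, dest=dest)


def relative_sasa(topology: Topology, coords: np.ndarray,
                  probe_radius: float = 1.4, point_number: int = 300
                  ) -> np.ndarray:
    """Per-residue relative solvent accessibility of one structure.

    Atomic areas come from a rolling-probe (Shrake-Rupley) calculation over
    heavy atoms, summed per residue and divided by the residue type's
    theoretical maximum (unknown types fall back to the Gly maximum with a
    warning).
    """
    import warnings

    arr = to_atom_array(topology, coords)
    heavy = topology.heavy_mask
    areas = struc.sasa(arr, probe_radius=probe_radius, point_number=point_number,
                       vdw_radii="Single", atom_filter=heavy)
    areas = np.nan_to_num(areas, nan=0.0)
    per_res = np.zeros(topology.n_residues)
    np.add.at(per_res, topology.atom_residue, areas)
    maxima = np.empty(topology.n_residues)
    for i, name in enumerate(topology.res_names):
        if str(name) not in MAX_SASA:
            warnings.warn(f"no max-SASA entry for {name!r}; using Gly maximum")
        maxima[i] = MAX_SASA.get(str(name), MAX_SASA["GLY"])
    return per_res / maxima


def classify_exposure(ensemble: Ensemble, path_set: PathSet,
                      rel_sasa_threshold: float = 0.2) -> PathSet:
    """Label merged path residues internal/external by relative SASA.

    Accessibility is computed on the ensemble-mean structure; residues with
    relative SASA at or above the threshold are external (solvent-exposed), the rest
    internal (buried in the protein matrix).  The external fraction of the
    merged path node set is reported on the returned PathSet.
    """
    top = ensemble.topology
    rel = relative_sasa(top, ensemble.mean_structure())
    by_label = dict(zip(top.labels, rel))
    exposure = {}
    for node in path_set.node_counts:
        exposure[node] = "external" if by_label[node] >= rel_sasa_threshold \
            else "internal"
    # weight by path membership: residues on many paths dominate the fraction
    total = sum(path_set.node_counts.values())
    n_ext = sum(c for node, c in path_set.node_counts.items()
                if exposure[node] == "external")
    path_set.exposure = exposure
    path_set.external_fraction = n_ext / max(1, total)
    path_set.rel_sasa_threshold = rel_sasa_threshold
    return path_set
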