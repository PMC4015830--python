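"""Interactome assembly and global graph statistics.

An interactome here is an undirected simple :class:`networkx.Graph` over
uppercase gene symbols.  Every edge carries two attributes:

``sources``
    set of database tags recording where the interaction was reported
    (e.g. ``{"KEGG", "HPRD"}``); never empty.
``weight``
    nonnegative real, ``1.0`` until expression weighting is applied.

Interaction lists from different databases are read separately, then merged
with duplicate edges collapsed and provenance unioned; downstream analysis
runs on the largest connected component.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "GraphStats",
    "read_edge_list",
    "merge_networks",
    "largest_connected_component",
    "graph_stats",
    "write_edge_list",
    "write_graphml",
    "read_graphml",
]

log = logging.getLogger(__name__)


class EdgeListError(ValueError):
    """Malformed or empty interaction file."""


@dataclass
class GraphStats:
    """Global topology summary of an interactome.

    Betweenness values are unnormalized shortest-path counts; closeness is
    the reciprocal of mean shortest-path distance to all other vertices
    (both the standard conventions, recorded in ``conventions``).  When
    ``exact_paths`` is False the path-based fields are estimated from a
    sample of BFS source vertices and ``estimated`` is True.
    """

    n_nodes: int
    n_edges: int
    density: float
    avg_degree: float
    diameter: int
    avg_path_length: float
    global_clustering: float
    avg_node_betweenness: float
    avg_edge_betweenness: float
    avg_closeness: float
    estimated: bool = False
    n_path_sources: int | None = None
    conventions: dict = field(
        default_factory=lambda: {
            "betweenness": "unnormalized shortest-path counts",
            "closeness": "reciprocal of mean shortest-path distance",
            "global_clustering": "transitivity (3*triangles/triads)",
        }
    )

    def as_dict(self) -> dict:
        return asdict(self)


def _clean_symbol(token: str) -> str:
    return token.strip().upper()


def read_edge_list(path: str | Path, source_tag: str, dialect: str = "tsv") -> nx.Graph:
    """Read an interaction edge list into a simple undirected graph.

    Parameters
    ----------
    path
        File with one interaction per line.  ``dialect="sif"`` expects
        ``node<TAB>relation<TAB>node`` rows; ``dialect="tsv"`` expects two
        or three tab-separated columns ``node, node[, tag]`` where the
        optional third column adds a provenance tag.
    source_tag
        Provenance tag attached to every edge from this file.
    dialect
        ``"sif"`` or ``"tsv"``.

    Gene symbols are uppercased.  Self-loop rows are dropped (count
    logged); duplicate rows collapse to one edge.
    """
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'sif' or 'tsv'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    graph = nx.Graph()
    n_self_loops = 0
    n_rows = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if dialect == "sif":
                if len(fields) != 3:
                    raise EdgeListError(
                        f"{path}:{lineno}: SIF row needs 3 fields, got {len(fields)}"
                    )
                a, b = fields[0], fields[2]
                tags = {source_tag}
            else:
                if len(fields) not in (2, 3):
                    raise EdgeListError(
                        f"{path}:{lineno}: TSV row needs 2 or 3 fields, got {len(fields)}"
                    )
                a, b = fields[0], fields[1]
                tags = {source_tag}
                if len(fields) == 3 and fields[2].strip():
                    tags.add(fields[2].strip())
            a, b = _clean_symbol(a), _clean_symbol(b)
            if not a or not b:
                raise EdgeListError(f"{path}:{lineno}: empty gene symbol")
            n_rows += 1
            if a == b:
                n_self_loops += 1
                continue
            if graph.has_edge(a, b):
                graph.edges[a, b]["sources"] |= tags
            else:
                graph.add_edge(a, b, sources=set(tags), weight=1.0)
    if n_rows == 0:
        raise EdgeListError(f"{path}: no interaction rows")
    if n_self_loops:
        log.info("%s: dropped %d self-loop row(s)", path, n_self_loops)
    return graph


def merge_networks(nets: Sequence[nx.Graph]) -> nx.Graph:
    """Union of interactomes; shared edges get the union of provenance tags."""
    if not nets:
        raise ValueError("need at least one network to merge")
    merged = nx.Graph()
    for net in nets:
        merged.add_nodes_from(net.nodes)
        for u, v, data in net.edges(data=True):
            tags = set(data.get("sources", set()))
            if merged.has_edge(u, v):
                merged.edges[u, v]["sources"] |= tags
            else:
                merged.add_edge(u, v, sources=tags, weight=data.get("weight", 1.0))
    return merged


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Component with the most nodes; ties go to the one containing the
    lexicographically smallest symbol."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no connected component")
    components = sorted(
        nx.connected_components(net), key=lambda c: (-len(c), min(map(str, c)))
    )
    return net.subgraph(components[0]).copy()


def graph_stats(
    net: nx.Graph,
    exact_paths: bool = True,
    n_sources: int = 50,
    seed: int | None = None,
) -> GraphStats:
    """Compute global statistics of an interactome.

    With ``exact_paths=True`` (default) the network must be connected and
    path statistics are exact all-pairs values.  With ``exact_paths=False``
    path statistics are estimated from ``n_sources`` sampled BFS sources on
    the largest connected component (the diameter estimate is then a lower
    bound) and betweenness uses the same number of sampled pivots.
    """
    n = net.number_of_nodes()
    m = net.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    avg_degree = 2.0 * m / n
    clustering = nx.transitivity(net)

    connected = nx.is_connected(net)
    if exact_paths:
        if not connected:
            raise ValueError(
                "network is disconnected; extract the largest connected "
                "component first or pass exact_paths=False"
            )
        diameter = nx.diameter(net)
        avg_path = nx.average_shortest_path_length(net)
        btw = nx.betweenness_centrality(net, normalized=False)
        ebtw = nx.edge_betweenness_centrality(net, normalized=False)
        clo = nx.closeness_centrality(net)
        avg_btw = sum(btw.values()) / n
        avg_ebtw = sum(ebtw.values()) / m if m else 0.0
        avg_clo = sum(clo.values()) / n
        n_used = None
        estimated = False
    else:
        core = net if connected else largest_connected_component(net)
        rng = random.Random(seed)
        nodes = sorted(core.nodes)
        k = min(n_sources, len(nodes))
        sources = rng.sample(nodes, k)
        total, count, ecc_max = 0, 0, 0
        clo_sum = 0.0
        nc = core.number_of_nodes()
        for s in sources:
            dists = nx.single_source_shortest_path_length(core, s)
            far = sum(dists.values())
            total += far
            count += len(dists) - 1
            ecc_max = max(ecc_max, max(dists.values()))
            if far > 0:
                clo_sum += (len(dists) - 1) / far
        diameter = ecc_max
        avg_path = total / count if count else 0.0
        avg_clo = clo_sum / k
        btw = nx.betweenness_centrality(core, k=k, normalized=False, seed=seed)
        ebtw = nx.edge_betweenness_centrality(core, k=k, normalized=False, seed=seed)
        avg_btw = sum(btw.values()) / nc
        avg_ebtw = sum(ebtw.values()) / core.number_of_edges()
        n_used = k
        estimated = True

    return GraphStats(
        n_nodes=n,
        n_edges=m,
        density=density,
        avg_degree=avg_degree,
        diameter=diameter,
        avg_path_length=avg_path,
        global_clustering=clustering,
        avg_node_betweenness=avg_btw,
        avg_edge_betweenness=avg_ebtw,
        avg_closeness=avg_clo,
        estimated=estimated,
        n_path_sources=n_used,
    )


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write a TSV edge list preserving provenance and weight."""
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\tsources\tweight\n")
        for u, v in sorted(map(sorted, net.edges())):
            data = net.edges[u, v]
            tags = "|".join(sorted(data.get("sources", set())))
            fh.write(f"{u}\t{v}\t{tags}\t{data.get('weight', 1.0):.10g}\n")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML writer; provenance sets are serialized as '|'-joined strings."""
    out = nx.Graph()
    out.add_nodes_from(net.nodes)
    for u, v, data in net.edges(data=True):
        out.add_edge(
            u,
            v,
            sources="|".join(sorted(data.get("sources", set()))),
            weight=float(data.get("weight", 1.0)),
        )
    nx.write_graphml(out, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    """Inverse of :func:`write_graphml`."""
    raw = nx.read_graphml(str(path))
    net = nx.Graph()
    net.add_nodes_from(raw.nodes)
    for u, v, data in raw.edges(data=True):
        tags = set(str(data.get("sources", "")).split("|")) - {""}
        net.add_edge(u, v, sources=tags or {"unknown"}, weight=float(data.get("weight", 1.0)))
    return net
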