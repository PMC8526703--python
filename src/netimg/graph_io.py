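"""Reading PPI edge lists and extracting the maximum connected subnetwork.

A PPI network is an undirected simple graph on gene symbols. Edge lists are
tab-separated two-column files (extra columns ignored); self-loops and
duplicate pairs (in either orientation) are dropped at load time, and an
optional symbol-to-symbol map is applied before deduplication so that merged
identifiers collapse onto a single node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)


class PPIGraph(nx.Graph):
    """Undirected simple graph on gene symbols.

    Thin subclass of :class:`networkx.Graph`; the type exists so pipeline
    signatures name their domain object. Invariants (no self-loops, no
    duplicate edges) are maintained by the constructors in this module.
    """


@dataclass
class LoadReport:
    """Bookkeeping from :func:`load_edge_list`."""

    edges_read: int = 0
    duplicates: int = 0
    self_loops: int = 0
    malformed: int = 0
    unmapped: int = 0
    mapped: int = 0

    def log(self) -> None:
        logger.info(
            "edge list: %d records read, %d duplicates, %d self-loops, "
            "%d malformed lines, %d symbols mapped, %d left verbatim",
            self.edges_read,
            self.duplicates,
            self.self_loops,
            self.malformed,
            self.mapped,
            self.unmapped,
        )


_HEADER_TOKENS = {"genea", "gene_a", "gene1", "source", "protein1", "proteina"}


def _is_header(first: str) -> bool:
    return first.startswith("#") or first.strip().lower() in _HEADER_TOKENS


def load_edge_list(
    path: str | Path,
    id_map: Mapping[str, str] | None = None,
) -> tuple[PPIGraph, LoadReport]:
    """Read a tab-separated two-column edge list into a simple graph.

    Parameters
    ----------
    path
        TSV file with at least two columns of gene symbols. A header row is
        assumed only when the first token is ``geneA``-like or ``#``-prefixed.
    id_map
        Optional symbol -> symbol translation applied to both endpoints
        before canonicalisation; symbols absent from the map are kept
        verbatim (and counted in the report).

    Returns
    -------
    (graph, report)
        The deduplicated undirected graph and the load report. Self-loops
        (after mapping) and repeated pairs in either order are dropped.

    Raises
    ------
    ValueError
        If the file yields no edges at all.
    """
    path = Path(path)
    graph = PPIGraph()
    report = LoadReport()
    id_map = id_map or {}

    with path.open() as fh:
        for lineno, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if lineno == 0 and fields and _is_header(fields[0]):
                continue
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                report.malformed += 1
                logger.warning("skipping malformed edge-list line %d: %r", lineno + 1, line)
                continue
            a, b = fields[0].strip(), fields[1].strip()
            report.edges_read += 1
            for sym in (a, b):
                if sym in id_map:
                    report.mapped += 1
                else:
                    report.unmapped += 1
            a = id_map.get(a, a)
            b = id_map.get(b, b)
            if a == b:
                report.self_loops += 1
                continue
            if graph.has_edge(a, b):
                report.duplicates += 1
                continue
            graph.add_edge(a, b)

    if graph.number_of_edges() == 0:
        raise ValueError(f"no edges read from {path}")
    report.log()
    return graph, report


def max_subnetwork(graph: PPIGraph, genes: Iterable[str]) -> PPIGraph:
    """Largest connected component of the subgraph induced on ``genes``.

    Components are compared by node count; ties are broken by the
    lexicographically smallest member node so the result is deterministic.
    When the induced subgraph has no edges at all, the single
    lexicographically-smallest requested node that exists in the graph (or
    of the request itself if none do) is returned with a warning, so the
    pipeline degrades to a one-node network rather than failing.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("gene set is empty")
    induced = graph.subgraph(genes & set(graph.nodes))
    components = [c for c in nx.connected_components(induced) if len(c) > 1]
    if not components:
        logger.warning("induced subgraph has no edges; returning a single-node network")
        pool = set(induced.nodes) or genes
        best = {min(pool)}
    else:
        best_size = max(len(c) for c in components)
        # ties on size broken by lexicographically smallest member node
        best = min((c for c in components if len(c) == best_size), key=min)
    out = PPIGraph()
    out.add_nodes_from(best)
    out.add_edges_from((u, v) for u, v in induced.edges if u in best and v in best)
    return out
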