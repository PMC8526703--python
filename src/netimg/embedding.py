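"""Laplacian spectral embedding of a PPI network into a fixed 2D grid.

The combinatorial Laplacian L = D - A of the (connected) DEG subnetwork is
eigendecomposed; the eigenvectors of the two smallest non-zero eigenvalues
give each gene an (x, y) coordinate (the Fiedler vector and its successor),
which is min-max scaled per axis and binned into a G x G grid. The embedding
is computed once from the shared DEG subnetwork and reused for every sample
image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from netimg.graph_io import PPIGraph

logger = logging.getLogger(__name__)

__all__ = [
    "LaplacianSpec",
    "GridEmbedding",
    "build_laplacian",
    "fiedler_coords",
    "bin_to_grid",
    "embed_graph",
    "write_embedding",
    "read_embedding",
]

# beyond this many nodes, switch from dense eigh to shift-invert Lanczos
_DENSE_LIMIT = 2048


@dataclass
class LaplacianSpec:
    """Laplacian matrix with its deterministic node ordering."""

    node_order: list[str]
    L: scipy.sparse.csr_matrix

    @property
    def n(self) -> int:
        return len(self.node_order)


@dataclass
class GridEmbedding:
    """Node coordinates and grid-cell assignment for a G x G grid."""

    grid_size: int
    coords: dict[str, tuple[float, float]]
    cells: dict[str, tuple[int, int]]
    eigenvalues: tuple[float, float]

    def __post_init__(self) -> None:
        g = self.grid_size
        for node, (r, c) in self.cells.items():
            if not (0 <= r < g and 0 <= c < g):
                raise ValueError(f"cell {(r, c)} of {node!r} outside {g}x{g} grid")


def build_laplacian(graph: PPIGraph) -> LaplacianSpec:
    """L = D - A over lexicographically sorted gene symbols.

    D is the diagonal degree matrix and A the 0/1 adjacency; rows sum to
    zero and off-diagonals are 0 or -1. Sorting the node order makes the
    matrix (and everything downstream) independent of graph input order.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    node_order = sorted(graph.nodes)
    adjacency = scipy.sparse.csr_matrix(
        nx.to_scipy_sparse_array(graph, nodelist=node_order, dtype=np.int64, format="csr")
    )
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    lap = scipy.sparse.diags(degrees, format="csr", dtype=np.int64) - adjacency
    return LaplacianSpec(node_order=node_order, L=lap.tocsr())


def fiedler_coords(
    spec: LaplacianSpec,
) -> tuple[dict[str, tuple[float, float]], tuple[float, float]]:
    """Coordinates from the two smallest non-zero Laplacian eigenpairs.

    Eigenvalues below ``1e-8 * max_degree`` count as zero. A second
    numerically-zero eigenvalue means the graph is disconnected, which is an
    error: extract the maximum connected subnetwork first. Each selected
    eigenvector is unit-norm with its sign fixed so the largest-magnitude
    entry is positive (ties resolved to the earliest node in node order),
    making the coordinates reproducible.
    """
    n = spec.n
    if n < 3:
        raise ValueError("need at least 3 nodes for a 2D spectral embedding")
    max_degree = float(spec.L.diagonal().max())
    tol = 1e-8 * max(max_degree, 1.0)

    if n <= _DENSE_LIMIT:
        vals, vecs = scipy.linalg.eigh(spec.L.toarray().astype(float))
    else:
        k = min(n - 1, 8)
        # shift-invert around a negative sigma keeps the singular L factorable
        vals, vecs = scipy.sparse.linalg.eigsh(
            spec.L.astype(float), k=k, sigma=-1e-3, which="LM"
        )
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]

    nonzero = np.flatnonzero(vals > tol)
    n_zero = len(vals) - len(nonzero)
    if n_zero >= 2:
        raise ValueError(
            "Laplacian has multiple zero eigenvalues: the graph is "
            "disconnected; run max_subnetwork first"
        )
    if len(nonzero) < 2:
        raise ValueError("not enough non-zero eigenpairs for a 2D embedding")

    i1, i2 = nonzero[0], nonzero[1]
    lam = (float(vals[i1]), float(vals[i2]))
    axes = []
    for idx in (i1, i2):
        v = vecs[:, idx]
        v = v / np.linalg.norm(v)
        pivot = int(np.argmax(np.abs(v)))  # first max == earliest node
        if v[pivot] < 0:
            v = -v
        axes.append(v)
    coords = {
        node: (float(axes[0][i]), float(axes[1][i]))
        for i, node in enumerate(spec.node_order)
    }
    return coords, lam


def bin_to_grid(
    coords: dict[str, tuple[float, float]], grid_size: int = 100
) -> dict[str, tuple[int, int]]:
    """Min-max scale each axis to [0, 1] and bin into grid cells.

    Cell index per axis is ``min(floor(u * G), G - 1)``; a constant axis
    maps every node to index 0. Rows index the y axis, columns the x axis,
    both 0-based.
    """
    if not coords:
        raise ValueError("no coordinates to bin")
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    nodes = list(coords)
    xy = np.array([coords[n] for n in nodes], dtype=float)

    def _axis_bins(u: np.ndarray) -> np.ndarray:
        lo, hi = u.min(), u.max()
        if hi == lo:
            return np.zeros(len(u), dtype=int)
        scaled = (u - lo) / (hi - lo)
        return np.minimum((scaled * grid_size).astype(int), grid_size - 1)

    col = _axis_bins(xy[:, 0])
    row = _axis_bins(xy[:, 1])
    return {n: (int(row[i]), int(col[i])) for i, n in enumerate(nodes)}


def embed_graph(graph: PPIGraph, grid_size: int = 100) -> GridEmbedding:
    """Full embedding pipeline: Laplacian -> eigenpairs -> grid binning."""
    spec = build_laplacian(graph)
    coords, lam = fiedler_coords(spec)
    cells = bin_to_grid(coords, grid_size)
    occupied = len({c for c in cells.values()})
    logger.info(
        "embedded %d nodes into %dx%d grid (%d occupied cells; lambda1=%.6g, lambda2=%.6g)",
        len(cells), grid_size, grid_size, occupied, lam[0], lam[1],
    )
    return GridEmbedding(grid_size=grid_size, coords=coords, cells=cells, eigenvalues=lam)


def write_embedding(embedding: GridEmbedding, path: str | Path) -> None:
    """TSV export: `gene x y row col` with grid metadata in `#` comments."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# grid_size={embedding.grid_size}\n")
        fh.write(f"# lambda1={embedding.eigenvalues[0]!r}\n")
        fh.write(f"# lambda2={embedding.eigenvalues[1]!r}\n")
        fh.write("gene\tx\ty\trow\tcol\n")
        for gene in sorted(embedding.coords):
            x, y = embedding.coords[gene]
            r, c = embedding.cells[gene]
            fh.write(f"{gene}\t{x!r}\t{y!r}\t{r}\t{c}\n")


def read_embedding(path: str | Path) -> GridEmbedding:
    path = Path(path)
    meta: dict[str, float] = {}
    coords: dict[str, tuple[float, float]] = {}
    cells: dict[str, tuple[int, int]] = {}
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = float(value)
                continue
            if line.startswith("gene\t") or not line.strip():
                continue
            gene, x, y, r, c = line.split("\t")
            coords[gene] = (float(x), float(y))
            cells[gene] = (int(r), int(c))
    return GridEmbedding(
        grid_size=int(meta["grid_size"]),
        coords=coords,
        cells=cells,
        eigenvalues=(meta["lambda1"], meta["lambda2"]),
    )
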