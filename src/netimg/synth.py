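"""Synthetic PPI graphs, expression cohorts and clinical tables.

Emulates the statistical structure the pipeline assumes at toy scale: a
connected gene-interaction graph in which each tumor class's signature genes
form a community; per-gene lognormal baseline expression; class-specific
signatures shifted by a fixed log2 effect in that class's tumors (normals
unshifted) with Gaussian noise on the log scale; and a clinical table with
random vital status and survival times. Everything is a pure function of the
seed, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from netimg.graph_io import PPIGraph

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "gene_names", "signature_genes", "make_graph", "make_cohort", "write_cohort"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults sketch a small but realistic multi-class RNA-Seq design: a few
    hundred genes, three tumor classes with matched normals, 20-gene
    signatures shifted by 3 log2 units (an 8-fold change, typical of strong
    tumor markers), and biological noise of 0.5 sd on the log2 scale.
    ``shared_fraction`` > 0 makes classes 1 and 2 share that fraction of
    their signature genes, emulating confusable tumor pairs from the same
    tissue of origin.
    """

    n_genes: int = 300
    n_classes: int = 3
    samples_per_class: int = 16
    normals_per_class: int = 5
    signature_size: int = 20
    effect_log2fc: float = 3.0
    noise_sd: float = 0.5
    graph_model: str = "planted_partition"  # or erdos_renyi | scale_free
    edge_density: float = 0.02  # ER edge probability / partition background
    p_in: float = 0.3  # within-community density for planted_partition
    attachment: int = 3  # scale-free preferential-attachment edges
    death_rate: float = 0.3
    shared_fraction: float = 0.0
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes * self.signature_size > self.n_genes:
            raise ValueError("signatures need n_classes * signature_size <= n_genes")
        for name in ("edge_density", "p_in", "death_rate", "shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def class_labels(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_classes)]


def gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def signature_genes(config: SynthConfig) -> dict[str, list[str]]:
    """Deterministic class -> signature-gene assignment.

    Signatures occupy the first genes in name order, one block per class.
    With ``shared_fraction`` = f, class C2 replaces the first f of its block
    with the first f of C1's block, so the two classes differ only in the
    remaining (1 - f) of their signatures.
    """
    names = gene_names(config.n_genes)
    sigs: dict[str, list[str]] = {}
    for i, label in enumerate(config.class_labels):
        block = names[i * config.signature_size : (i + 1) * config.signature_size]
        sigs[label] = list(block)
    if config.shared_fraction > 0 and config.n_classes >= 2:
        n_shared = int(round(config.shared_fraction * config.signature_size))
        first, second = config.class_labels[0], config.class_labels[1]
        sigs[second] = sigs[first][:n_shared] + sigs[second][n_shared:]
    return sigs


def _ensure_connected(graph: nx.Graph) -> int:
    """Bridge components onto the largest one; returns edges added."""
    comps = sorted(nx.connected_components(graph), key=len, reverse=True)
    added = 0
    if len(comps) > 1:
        anchor = min(comps[0])
        for comp in comps[1:]:
            graph.add_edge(anchor, min(comp))
            added += 1
        logger.info("added %d bridging edges to connect the synthetic graph", added)
    return added


def make_graph(config: SynthConfig) -> PPIGraph:
    """Connected simple undirected graph on synthetic gene symbols.

    ``planted_partition`` places each class signature in its own dense
    community (within-density ``p_in``) over a sparse background
    (``edge_density``), mirroring the premise that functionally related
    genes cluster in the interaction network.
    """
    names = gene_names(config.n_genes)
    seed = int(config.seed) % (2**32)
    if config.graph_model == "erdos_renyi":
        g = nx.gnp_random_graph(config.n_genes, config.edge_density, seed=seed)
    elif config.graph_model == "scale_free":
        g = nx.barabasi_albert_graph(config.n_genes, config.attachment, seed=seed)
    elif config.graph_model == "planted_partition":
        sizes = [config.signature_size] * config.n_classes
        rest = config.n_genes - sum(sizes)
        if rest:
            sizes.append(rest)
        probs = [
            [config.p_in if i == j else config.edge_density for j in range(len(sizes))]
            for i in range(len(sizes))
        ]
        g = nx.stochastic_block_model(sizes, probs, seed=seed)
    else:
        raise ValueError(f"unknown graph_model {config.graph_model!r}")
    g = nx.Graph(g)  # drop block-model metadata, keep it simple
    g.remove_edges_from(nx.selfloop_edges(g))
    _ensure_connected(g)
    out = PPIGraph()
    out.add_nodes_from(names)
    out.add_edges_from((names[u], names[v]) for u, v in g.edges)
    return out


def make_cohort(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrix, sample metadata and clinical table.

    Per gene g a baseline log2 level mu_g ~ N(baseline_log2_mean,
    baseline_log2_sd) is drawn (a lognormal baseline on the raw scale, the
    skew typical of RNA-Seq quantifications). Sample s of class c observes

        log2(x_gs + 1) = mu_g + effect_log2fc * [g in signature(c), s tumor] + eps,
        eps ~ N(0, noise_sd),

    back-transformed and clipped at zero. Clinical: dead with probability
    ``death_rate``, survival days uniform on [0, 3650].
    """
    rng = np.random.default_rng(config.seed)
    names = gene_names(config.n_genes)
    sigs = signature_genes(config)
    sig_idx = {
        label: np.array([names.index(g) for g in genes])
        for label, genes in sigs.items()
    }

    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)

    sample_ids: list[str] = []
    meta_rows = []
    columns = {}
    for label in config.class_labels:
        for kind, count in (("normal", config.normals_per_class), ("tumor", config.samples_per_class)):
            for j in range(count):
                sid = f"{label}_{kind[0]}{j + 1:02d}"
                shift = np.zeros(config.n_genes)
                if kind == "tumor":
                    shift[sig_idx[label]] = config.effect_log2fc
                log2x = mu + shift + rng.normal(0.0, config.noise_sd, config.n_genes)
                columns[sid] = np.maximum(np.exp2(log2x) - 1.0, 0.0)
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "cancer": label, "status": kind})

    expression = pd.DataFrame(columns, index=pd.Index(names, name="gene"))
    metadata = pd.DataFrame(meta_rows)
    dead = rng.random(len(sample_ids)) < config.death_rate
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "vital_status": np.where(dead, "dead", "alive"),
            "survival_days": rng.integers(0, 3651, len(sample_ids)),
        }
    )
    return expression, metadata, clinical


def write_cohort(
    config: SynthConfig, outdir: str | Path
) -> dict[str, Path]:
    """Emit expression/metadata/clinical/edge-list TSVs into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expression, metadata, clinical = make_cohort(config)
    graph = make_graph(config)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "clinical": outdir / "clinical.tsv",
        "ppi": outdir / "ppi_edges.tsv",
    }
    expression.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    with paths["ppi"].open("w") as fh:
        fh.write("geneA\tgeneB\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")
    return paths
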