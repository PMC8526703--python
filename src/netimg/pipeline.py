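"""End-to-end orchestration: DEGs -> subnetwork -> embedding -> images -> CNN.

Ties the stage modules together for scripted runs, the CLI and the repeated
random-validation experiments. All randomness flows from one root seed:
experiment i uses root_seed + 7919 * i (a fixed odd prime stride keeps the
per-experiment streams distinct and lets any single experiment be reproduced
in isolation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from netimg import classifier, deg, embedding, evaluation, imaging
from netimg.graph_io import PPIGraph, max_subnetwork

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "experiment_seed", "select_genes", "run_pipeline"]

_SEED_STRIDE = 7919


def experiment_seed(root_seed: int, experiment: int) -> int:
    return (int(root_seed) + _SEED_STRIDE * int(experiment)) % (2**31)


@dataclass
class PipelineResult:
    deg_records: pd.DataFrame | None
    deg_genes: set[str]
    subnetwork: PPIGraph
    embedding: embedding.GridEmbedding
    images: list[imaging.NetworkImage]
    log: evaluation.PredictionLog
    curves: list[dict[str, list[float]]]
    validation_accuracy: list[float]  # multi-class, per experiment
    binary_accuracy: list[float]  # normal-vs-tumor, per experiment


def select_genes(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-cancer moderated-t table and the union DEG set."""
    records = deg.deg_table(expression, metadata)
    union = deg.deg_union(records, fc_threshold=fc_threshold, p_threshold=p_threshold)
    logger.info("DEG union: %d of %d genes", len(union), expression.shape[0])
    return records, union


def run_pipeline(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    graph: PPIGraph,
    grid_size: int = 100,
    gene_set: str = "deg",
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    epochs: int = 100,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    repeats: int = 1,
    tumor_per_normal: int = 3,
    normal_fraction: float = 0.5,
    seed: int = 0,
) -> PipelineResult:
    """Run the full classification pipeline on one cohort.

    ``gene_set`` selects the genes defining the shared network: ``"deg"``
    (the union DEG filter; the study design) or ``"all"`` (every gene in the
    graph — useful for null cohorts where the DEG union is empty). Each of
    ``repeats`` experiments draws a fresh training/validation split at the
    3:1 tumor:normal ratio, trains the CNN from scratch, and appends its
    train and validation predictions to the shared log.
    """
    if gene_set == "deg":
        records, genes = select_genes(expression, metadata, fc_threshold, p_threshold)
        if not genes:
            raise ValueError(
                "DEG union is empty; relax thresholds or use gene_set='all'"
            )
    elif gene_set == "all":
        records, genes = None, set(expression.index)
    else:
        raise ValueError(f"unknown gene_set {gene_set!r}")

    subnet = max_subnetwork(graph, genes)
    grid = embedding.embed_graph(subnet, grid_size)
    images = imaging.render_cohort(grid, expression, metadata)
    by_id = {img.sample_id: img for img in images}
    labels = sorted({img.label for img in images})

    log = evaluation.PredictionLog()
    curves_all: list[dict[str, list[float]]] = []
    val_acc: list[float] = []
    bin_acc: list[float] = []
    for i in range(repeats):
        eseed = experiment_seed(seed, i)
        train_ids, val_ids = evaluation.make_split(
            metadata,
            tumor_per_normal=tumor_per_normal,
            seed=eseed,
            normal_fraction=normal_fraction,
        )
        spec = classifier.CNNSpec(grid_size=grid_size, n_classes=len(labels))
        model = classifier.build_model(spec)
        config = classifier.TrainConfig(
            epochs=epochs, batch_size=batch_size, learning_rate=learning_rate, seed=eseed
        )
        model, curves = classifier.train(model, [by_id[s] for s in train_ids], config)
        curves_all.append(curves)
        for role, ids in (("train", train_ids), ("validation", val_ids)):
            imgs = [by_id[s] for s in ids]
            _, predicted = classifier.predict(model, imgs)
            log.append(i, ids, [im.label for im in imgs], predicted, role=role)
        counts = evaluation.confusion_matrix(log, i)
        bin_acc.append(evaluation.accuracy(counts))
        rec = log.records
        mask = (rec["experiment_id"] == str(i)) & (rec["role"] == "validation")
        val_acc.append(float((rec.loc[mask, "truth"] == rec.loc[mask, "predicted"]).mean()))
        logger.info(
            "experiment %d: multi-class validation accuracy %.3f, binary %.3f",
            i, val_acc[-1], bin_acc[-1],
        )

    return PipelineResult(
        deg_records=records,
        deg_genes=genes,
        subnetwork=subnet,
        embedding=grid,
        images=images,
        log=log,
        curves=curves_all,
        validation_accuracy=val_acc,
        binary_accuracy=bin_acc,
    )
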