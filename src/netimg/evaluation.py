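"""Splits, accuracy, confusion matrices, error frequencies, similarity.

The study design: per cancer type, a random subset of the normal tissues
(default: half, rounded up) plus three times as many random tumors form the
training cohort; everything else is validation. Repeating the experiment
with fresh random splits yields a prediction log from which per-sample
error-identification frequencies and the misjudged-into-normal survival
table are derived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "PredictionLog",
    "make_split",
    "accuracy",
    "confusion_matrix",
    "error_frequency",
    "class_similarity",
    "misjudged_similarity_table",
]

LOG_COLUMNS = ["experiment_id", "sample_id", "truth", "predicted", "role"]


@dataclass
class ConfusionCounts:
    """Multi-class confusion matrix plus its binary normal-vs-tumor collapse."""

    matrix: pd.DataFrame  # rows = truth, cols = predicted
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


class PredictionLog:
    """Accumulated (experiment, sample, truth, predicted, role) records."""

    def __init__(self, records: pd.DataFrame | None = None):
        if records is None:
            records = pd.DataFrame(columns=LOG_COLUMNS)
        missing = set(LOG_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"log missing columns {sorted(missing)}")
        self.records = records[LOG_COLUMNS].reset_index(drop=True)
        self._check_unique()

    def _check_unique(self) -> None:
        if self.records.duplicated(["experiment_id", "sample_id"]).any():
            raise ValueError("(experiment_id, sample_id) pairs must be unique")

    def append(
        self,
        experiment_id: str | int,
        sample_ids: Iterable[str],
        truths: Iterable[str],
        predictions: Iterable[str],
        role: str = "validation",
    ) -> None:
        new = pd.DataFrame(
            {
                "experiment_id": str(experiment_id),
                "sample_id": list(sample_ids),
                "truth": list(truths),
                "predicted": list(predictions),
                "role": role,
            }
        )
        self.records = pd.concat([self.records, new], ignore_index=True)
        self._check_unique()

    def experiments(self) -> list[str]:
        return sorted(self.records["experiment_id"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PredictionLog":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def make_split(
    metadata: pd.DataFrame,
    tumor_per_normal: int = 3,
    seed: int = 0,
    normal_fraction: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Random training/validation partition at the study's 3:1 tumor:normal ratio.

    Per cancer type, ``ceil(normal_fraction * n_normals)`` random normals and
    exactly ``tumor_per_normal`` times that many random tumors go to
    training; all remaining samples are validation. With 113 normals and the
    defaults this picks 57 normals and 171 tumors, the worked breast-cancer
    example. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    train: list[str] = []
    all_ids = metadata["sample_id"].tolist()
    for cancer in sorted(metadata["cancer"].unique()):
        grp = metadata[metadata["cancer"] == cancer]
        normals = sorted(grp.loc[grp["status"] == "normal", "sample_id"])
        tumors = sorted(grp.loc[grp["status"] == "tumor", "sample_id"])
        if not normals:
            raise ValueError(f"cancer {cancer!r} has no normal samples")
        n_norm = math.ceil(normal_fraction * len(normals))
        n_tum = tumor_per_normal * n_norm
        if len(tumors) < n_tum:
            raise ValueError(
                f"cancer {cancer!r} has {len(tumors)} tumors; needs >= {n_tum} "
                f"for {n_norm} training normals at {tumor_per_normal}:1"
            )
        train += list(rng.choice(normals, size=n_norm, replace=False))
        train += list(rng.choice(tumors, size=n_tum, replace=False))
    train_set = set(train)
    validation = [s for s in all_ids if s not in train_set]
    return sorted(train), validation


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN) on the binary normal-vs-tumor view."""
    if counts.total == 0:
        raise ValueError("no samples to score")
    return (counts.TP + counts.TN) / counts.total


def confusion_matrix(
    log: PredictionLog,
    experiment_id: str | int | None = None,
    role: str = "validation",
) -> ConfusionCounts:
    """Tally truth-vs-predicted counts for one experiment (or all pooled).

    The binary view treats every cancer label as ``tumor`` and ``normal`` as
    the negative class (tumor = positive), so a tumor called as any cancer
    type counts TP even when the cancer type itself is wrong.
    """
    rec = log.records[log.records["role"] == role]
    if experiment_id is not None:
        rec = rec[rec["experiment_id"] == str(experiment_id)]
        if rec.empty:
            raise ValueError(f"no records for experiment {experiment_id!r}")
    if rec.empty:
        raise ValueError("prediction log is empty")
    classes = sorted(set(rec["truth"]) | set(rec["predicted"]))
    matrix = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for truth, pred in zip(rec["truth"], rec["predicted"]):
        matrix.loc[truth, pred] += 1
    truth_tumor = rec["truth"] != "normal"
    pred_tumor = rec["predicted"] != "normal"
    return ConfusionCounts(
        matrix=matrix,
        TP=int((truth_tumor & pred_tumor).sum()),
        TN=int((~truth_tumor & ~pred_tumor).sum()),
        FP=int((~truth_tumor & pred_tumor).sum()),
        FN=int((truth_tumor & ~pred_tumor).sum()),
    )


def error_frequency(
    log: PredictionLog, sample_id: str
) -> tuple[int, int, float | None]:
    """(times selected as validation, times misjudged, percent misjudged).

    A sample selected 40 times and wrong every time scores 100.0. A sample
    never selected as validation has undefined frequency (percent = None).
    """
    rec = log.records
    sel = rec[(rec["sample_id"] == sample_id) & (rec["role"] == "validation")]
    times_selected = len(sel)
    if times_selected == 0:
        return 0, 0, None
    times_misjudged = int((sel["truth"] != sel["predicted"]).sum())
    return times_selected, times_misjudged, 100.0 * times_misjudged / times_selected


def class_similarity(
    profile: pd.Series,
    class_profiles: pd.DataFrame,
    exclude: str | None = None,
) -> float:
    """Mean Pearson r between one sample and every member of a class.

    ``class_profiles`` is genes x samples (DEG-restricted in the pipeline);
    ``exclude`` drops the sample's own column when it belongs to the class.
    Pairs where either vector has zero variance are skipped with a warning;
    returns NaN if nothing remains.
    """
    members = [c for c in class_profiles.columns if c != exclude]
    if not members:
        raise ValueError("class has no members to compare against")
    shared = profile.index.intersection(class_profiles.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared genes for a correlation")
    x = profile.loc[shared].to_numpy(dtype=float)
    if np.std(x) == 0:
        logger.warning("query profile has zero variance; similarity undefined")
        return float("nan")
    rs = []
    for m in members:
        y = class_profiles.loc[shared, m].to_numpy(dtype=float)
        if np.std(y) == 0:
            logger.warning("zero-variance member %r skipped in similarity", m)
            continue
        rs.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(rs)) if rs else float("nan")


def misjudged_similarity_table(
    log: PredictionLog,
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Expression-similarity analysis of misclassified tumor samples.

    For every tumor sample misjudged at least once, compute the mean Pearson
    r of its (DEG-restricted) profile to all tumors of its true class and to
    all tumors of its most frequent wrong predicted class. Columns:
    ``sample_id``, ``truth``, ``predicted``, ``r_truth``, ``r_predicted``,
    ``error_pct``, ``high_error`` (frequency >= 50%). Samples whose profiles
    are more similar to the predicted class fall below the r_truth =
    r_predicted diagonal.
    """
    expr = expression.loc[expression.index.intersection(genes)] if genes is not None else expression
    label = {
        row["sample_id"]: ("normal" if row["status"] == "normal" else str(row["cancer"]))
        for _, row in metadata.iterrows()
    }
    by_class: dict[str, list[str]] = {}
    for sid, lab in label.items():
        by_class.setdefault(lab, []).append(sid)

    rows = []
    rec = log.records[log.records["role"] == "validation"]
    wrong = rec[rec["truth"] != rec["predicted"]]
    for sid in sorted(wrong["sample_id"].unique()):
        truth = label[sid]
        if truth == "normal":
            continue
        sel, mis, pct = error_frequency(log, sid)
        pred = (
            wrong.loc[wrong["sample_id"] == sid, "predicted"].mode().sort_values().iloc[0]
        )
        if pred not in by_class:
            continue
        r_truth = class_similarity(expr[sid], expr[by_class[truth]], exclude=sid)
        r_pred = class_similarity(expr[sid], expr[by_class[pred]], exclude=sid)
        rows.append(
            {
                "sample_id": sid,
                "truth": truth,
                "predicted": pred,
                "r_truth": r_truth,
                "r_predicted": r_pred,
                "error_pct": pct,
                "high_error": bool(pct is not None and pct >= 50.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "truth", "predicted", "r_truth", "r_predicted", "error_pct", "high_error"],
    )
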