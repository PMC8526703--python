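"""Misjudged-into-normal frequency and its association with survival.

Across repeated experiments, tumors that the classifier ever calls "normal"
are compared with tumors always identified correctly: among the deceased
patients of each group, the fraction that nevertheless survived at least two
years (730 days) is computed, and their ratio

    ratio = (a / n_to_normal) / (b / n_correct)

summarises whether misjudged-into-normal tumors carry better prognosis. The
statistic is a ratio of proportions (risk ratio); the source study labels it
an odds ratio, but the printed values follow the proportion formula, which
is what this module computes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from netimg.evaluation import PredictionLog

__all__ = ["SurvivalRow", "misjudged_to_normal_freq", "survival_ratio", "build_table"]

TWO_YEARS_DAYS = 730


@dataclass
class SurvivalRow:
    """One cancer type's misjudgment/survival summary."""

    cancer: str
    n_error: int  # tumors with >=1 error identification
    n_to_normal: int  # of those, misjudged into normal at least once
    n_correct: int  # tumors always identified correctly
    dead_ge2y_misjudged: int | None  # a; None = no clinical data
    dead_ge2y_correct: int | None  # b
    freq_pct: float | None
    ratio: float | None


def misjudged_to_normal_freq(n_to_normal: int, n_error: int) -> float | None:
    """Percent of error-identified tumors that were misjudged into normal.

    Returns ``None`` (NA) when no tumor was ever misidentified.
    """
    if n_to_normal < 0 or n_error < 0 or n_to_normal > n_error:
        raise ValueError("need 0 <= n_to_normal <= n_error")
    if n_error == 0:
        return None
    return round(100.0 * n_to_normal / n_error, 2)


def survival_ratio(
    a: int, n_to_normal: int, b: int, n_correct: int
) -> float | None:
    """(a/n_to_normal) / (b/n_correct), the two groups' >=2-year-death-survivor ratio.

    ``a`` and ``b`` count deceased patients who lived at least two years
    among the misjudged-into-normal and correctly-identified tumors. Zero
    denominators give NA; ``a == 0`` with ``b > 0`` gives 0; ``b == 0`` with
    ``a > 0`` is NA (the paper prints NA for its no-death row).
    """
    for name, v in (("a", a), ("n_to_normal", n_to_normal), ("b", b), ("n_correct", n_correct)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if a > n_to_normal or b > n_correct:
        raise ValueError("death counts cannot exceed group sizes")
    if n_to_normal == 0 or n_correct == 0:
        return None
    if a == 0:
        return 0.0
    if b == 0:
        return None
    return (a / n_to_normal) / (b / n_correct)


def build_table(
    log: PredictionLog,
    clinical: pd.DataFrame,
    per_experiment: bool = False,
) -> pd.DataFrame:
    """Survival summary per cancer type from a repeated-experiment log.

    ``clinical`` needs columns ``sample_id``, ``vital_status``
    (``dead``/``alive``) and ``survival_days``; samples missing from it
    propagate NA. By default each tumor sample counts once across all
    experiments (``per_experiment=True`` counts sample-experiment events
    instead). Rows are sorted by misjudged-into-normal frequency,
    descending. Output columns mirror the summary-table layout; NA is
    rendered ``NA`` and absent clinical data ``no_clinical_data`` by the
    CSV writer.
    """
    rec = log.records[log.records["role"] == "validation"]
    rec = rec[rec["truth"] != "normal"]
    if rec.empty:
        raise ValueError("log holds no validation tumor records")
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical

    rows = []
    for cancer in sorted(rec["truth"].unique()):
        sub = rec[rec["truth"] == cancer]
        if per_experiment:
            key = sub["experiment_id"].astype(str) + "::" + sub["sample_id"].astype(str)
            sub = sub.assign(_unit=key)
        else:
            sub = sub.assign(_unit=sub["sample_id"])
        wrong = sub[sub["truth"] != sub["predicted"]]
        err_units = set(wrong["_unit"])
        to_normal_units = set(wrong.loc[wrong["predicted"] == "normal", "_unit"])
        correct_units = set(sub["_unit"]) - err_units

        def _dead_ge2y(units: set[str]) -> int | None:
            samples = {u.split("::")[-1] for u in units} if per_experiment else units
            known = [s for s in samples if s in clin.index]
            if not known:
                return None if samples else 0
            count = 0
            for s in known:
                row = clin.loc[s]
                if (
                    str(row["vital_status"]).lower() == "dead"
                    and float(row["survival_days"]) >= TWO_YEARS_DAYS
                ):
                    count += 1
            return count

        a = _dead_ge2y(to_normal_units)
        b = _dead_ge2y(correct_units)
        ratio = (
            None
            if a is None or b is None
            else survival_ratio(a, len(to_normal_units), b, len(correct_units))
        )
        rows.append(
            {
                "cancer": cancer,
                "freq_pct": misjudged_to_normal_freq(len(to_normal_units), len(err_units)),
                "n_error": len(err_units),
                "n_to_normal": len(to_normal_units),
                "n_correct": len(correct_units),
                "dead_ge2y_misjudged": a,
                "dead_ge2y_correct": b,
                "ratio": None if ratio is None else round(ratio, 3),
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values("freq_pct", ascending=False, na_position="last").reset_index(
        drop=True
    )


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV export with NA / no_clinical_data markers."""
    out = table.copy()
    for col in ("dead_ge2y_misjudged", "dead_ge2y_correct"):
        out[col] = out[col].map(lambda v: "no_clinical_data" if pd.isna(v) else int(v))
    out["ratio"] = out["ratio"].map(lambda v: "NA" if pd.isna(v) else v)
    out.to_csv(path, index=False)
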